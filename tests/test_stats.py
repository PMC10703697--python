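"""Exact statistics against independent oracles (scipy, enumeration)."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from ashmscan.stats import (
    IntensityMatrix,
    benjamini_hochberg,
    chi_squared_contingency,
    fisher_exact_2x2,
    ihc_h_score,
    proteome_shift_analysis,
    sv_allele_frequency,
    two_way_anova_per_feature,
    wilcoxon_signed_rank,
)
import pandas as pd


def random_tables(rng, n, max_cell=12):
    return [rng.integers(0, max_cell + 1, size=(2, 2)) for _ in range(n)]


class TestFisher:
    def test_reported_gain_table(self):
        # 9 FL samples with 0 gains vs 8 DHL samples with 6 gains
        p = fisher_exact_2x2([[0, 9], [6, 2]], "two-sided")
        assert round(p, 4) == 0.0023
        assert p == pytest.approx(
            sps.fisher_exact([[0, 9], [6, 2]]).pvalue, abs=1e-12
        )

    def test_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]], "two-sided") == 1.0

    def test_vs_scipy_on_random_tables(self, rng):
        for table in random_tables(rng, 120):
            if table.sum() == 0:
                continue
            for sided, alt in [
                ("two-sided", "two-sided"),
                ("greater", "greater"),
                ("less", "less"),
            ]:
                mine = fisher_exact_2x2(table.tolist(), sided)
                ref = sps.fisher_exact(table, alternative=alt).pvalue
                assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_transposition_invariance(self, rng):
        for table in random_tables(rng, 40):
            if table.sum() == 0:
                continue
            t = table.tolist()
            tt = table.T.tolist()
            assert fisher_exact_2x2(t, "two-sided") == pytest.approx(
                fisher_exact_2x2(tt, "two-sided"), abs=1e-12
            )

    def test_one_sided_never_exceeds_two_sided_wrongly(self, rng):
        for table in random_tables(rng, 40):
            if table.sum() == 0:
                continue
            two = fisher_exact_2x2(table.tolist(), "two-sided")
            assert min(
                fisher_exact_2x2(table.tolist(), "greater"),
                fisher_exact_2x2(table.tolist(), "less"),
            ) <= two + 1e-12

    def test_exhaustive_enumeration_oracle(self):
        # independent oracle: direct Fraction-based enumeration
        a, b, c, d = 2, 8, 7, 3
        n, r1, c1 = a + b + c + d, a + b, a + c
        probs = {
            k: Fraction(comb(c1, k) * comb(n - c1, r1 - k), comb(n, r1))
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        }
        expected = float(sum(p for p in probs.values() if p <= probs[a]))
        assert fisher_exact_2x2([[2, 8], [7, 3]], "two-sided") == pytest.approx(
            expected, abs=1e-15
        )

    def test_spec_aliases(self):
        t = [[1, 5], [4, 2]]
        assert fisher_exact_2x2(t, "two") == fisher_exact_2x2(t, "two-sided")
        assert fisher_exact_2x2(t, "one-greater") == fisher_exact_2x2(t, "greater")

    def test_rejects_nonsense(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])


def wilcoxon_enumeration_oracle(d, sided):
    """Full 2^n enumeration of sign assignments (discard-zero policy)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    total = len(stats)
    p_greater = sum(1 for w in stats if w >= w_obs - 1e-9) / total
    p_less = sum(1 for w in stats if w <= w_obs + 1e-9) / total
    if sided == "greater":
        return p_greater
    if sided == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestWilcoxon:
    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_n5_all_positive_one_sided(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5], sided="greater") == 1 / 32

    def test_paired_interface(self):
        x, y = [3, 5, 8], [1, 2, 3]
        assert wilcoxon_signed_rank(x, y, sided="greater") == wilcoxon_signed_rank(
            [2, 3, 5], sided="greater"
        )

    @pytest.mark.parametrize("sided", ["two-sided", "greater", "less"])
    def test_vs_enumeration_oracle(self, rng, sided):
        for _ in range(35):
            n = int(rng.integers(1, 13))
            d = rng.integers(-6, 7, size=n).astype(float)
            assert wilcoxon_signed_rank(d, sided=sided) == pytest.approx(
                wilcoxon_enumeration_oracle(d, sided), abs=1e-12
            )

    def test_vs_scipy_exact_no_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 15))
            d = rng.normal(size=n)
            ref = sps.wilcoxon(d, alternative="two-sided", mode="exact").pvalue
            assert wilcoxon_signed_rank(d) == pytest.approx(ref, abs=1e-10)

    def test_normal_approximation_branch(self, rng):
        d = rng.normal(0.3, 1.0, size=60)
        p_exact = wilcoxon_signed_rank(d, exact_threshold=100)
        p_approx = wilcoxon_signed_rank(d, exact_threshold=25)
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_pratt_policy(self):
        d = [0.0, 1.0, 2.0, 3.0]
        p_discard = wilcoxon_signed_rank(d, sided="greater")
        p_pratt = wilcoxon_signed_rank(d, sided="greater", zero_policy="pratt")
        assert p_discard == 1 / 8
        assert 0 < p_pratt <= 1


class TestChiSquared:
    def test_expected_equals_observed(self):
        stat, df, p = chi_squared_contingency([[10, 10], [10, 10]])
        assert stat == 0 and df == 1 and p == 1.0

    def test_hand_formula_2x2(self):
        table = np.array([[10, 20], [20, 10]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        stat, df, p = chi_squared_contingency(table)
        assert stat == pytest.approx(by_hand)
        assert p == pytest.approx(sps.chi2.sf(by_hand, 1))

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_squared_contingency([[0, 0], [1, 2]])


class TestBH:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]).tolist() == [0.03]

    def test_all_equal(self):
        out = benjamini_hochberg([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_vs_cummin_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            m = p.size
            order = np.argsort(p)
            # definitional oracle: adj[i] = min over j with p_j >= p_i of p_j*m/rank_j
            ranked = p[order] * m / np.arange(1, m + 1)
            adj_sorted = [min(ranked[i:]) for i in range(m)]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(benjamini_hochberg(p), expected)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=25)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_stable_under_input_order(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]))


class TestSmallScores:
    def test_sv_af(self):
        assert sv_allele_frequency(10, 20, 20) == 0.5
        assert sv_allele_frequency(0, 30, 10) == 0.0
        assert sv_allele_frequency(100, 20, 20) == 1.0  # clipped

    def test_sv_af_random_vs_formula(self, rng):
        for _ in range(50):
            s, c1, c2 = rng.integers(0, 50, 3)
            if c1 + c2 == 0:
                continue
            expected = min(1.0, s / ((c1 + c2) / 2))
            assert sv_allele_frequency(int(s), int(c1), int(c2)) == pytest.approx(
                expected
            )

    def test_h_score(self):
        assert ihc_h_score(100, 0, 0) == 300
        assert ihc_h_score(0, 0, 0) == 0
        assert ihc_h_score(20, 30, 50) == 170

    def test_h_score_validation(self):
        with pytest.raises(ValueError):
            ihc_h_score(80, 30, 0)


def make_matrix(values, n_rep=3, annotation=None):
    columns, genotype, label = [], [], []
    for g in ("WT", "ALT"):
        for l in ("OPP+", "OPP-"):
            for r in range(n_rep):
                columns.append(f"{g}.{l}.{r}")
                genotype.append(g)
                label.append(l)
    df = pd.DataFrame(values, columns=columns)
    df.index = [f"PR{i}" for i in range(len(df))]
    ann = None
    if annotation is not None:
        ann = pd.Series(annotation, index=df.index)
    return IntensityMatrix(
        values=df,
        genotype=pd.Series(genotype, index=columns),
        label=pd.Series(label, index=columns),
        annotation=ann,
    )


class TestAnova:
    def test_constant_protein_p_one(self):
        mat = make_matrix(np.full((1, 12), 5.0))
        res = two_way_anova_per_feature(mat)
        assert res.loc["PR0", "p_genotype"] == 1.0
        assert res.loc["PR0", "p_label"] == 1.0

    def test_hand_worked_table(self):
        # 2x2 with 2 replicates; textbook SS decomposition by hand
        cells = {
            ("WT", "OPP+"): [10.0, 12.0],
            ("WT", "OPP-"): [9.0, 11.0],
            ("ALT", "OPP+"): [15.0, 17.0],
            ("ALT", "OPP-"): [10.0, 12.0],
        }
        columns, genotype, label, vals = [], [], [], []
        for (g, l), xs in cells.items():
            for i, x in enumerate(xs):
                columns.append(f"{g}.{l}.{i}")
                genotype.append(g)
                label.append(l)
                vals.append(x)
        df = pd.DataFrame([vals], columns=columns, index=["PR0"])
        mat = IntensityMatrix(
            df,
            pd.Series(genotype, index=columns),
            pd.Series(label, index=columns),
        )
        res = two_way_anova_per_feature(mat)
        grand = np.mean(vals)
        m = {k: np.mean(v) for k, v in cells.items()}
        g_wt = (m[("WT", "OPP+")] + m[("WT", "OPP-")]) / 2
        g_alt = (m[("ALT", "OPP+")] + m[("ALT", "OPP-")]) / 2
        l_pos = (m[("WT", "OPP+")] + m[("ALT", "OPP+")]) / 2
        l_neg = (m[("WT", "OPP-")] + m[("ALT", "OPP-")]) / 2
        ss_a = 4 * ((g_wt - grand) ** 2 + (g_alt - grand) ** 2)
        ss_b = 4 * ((l_pos - grand) ** 2 + (l_neg - grand) ** 2)
        ss_ab = 2 * sum(
            (m[(g, l)] - {"WT": g_wt, "ALT": g_alt}[g] - {"OPP+": l_pos, "OPP-": l_neg}[l] + grand) ** 2
            for g in ("WT", "ALT")
            for l in ("OPP+", "OPP-")
        )
        ss_e = sum((x - m[k]) ** 2 for k, xs in cells.items() for x in xs)
        ms_e = ss_e / 4
        assert res.loc["PR0", "p_genotype"] == pytest.approx(sps.f.sf(ss_a / ms_e, 1, 4))
        assert res.loc["PR0", "p_label"] == pytest.approx(sps.f.sf(ss_b / ms_e, 1, 4))
        assert res.loc["PR0", "p_interaction"] == pytest.approx(
            sps.f.sf(ss_ab / ms_e, 1, 4)
        )

    def test_planted_genotype_effect(self, rng):
        vals = rng.normal(0, 0.3, size=(50, 12))
        vals[0, :3] += 4.0  # (WT? no:) columns 0-2 are WT.OPP+ ... plant on ALT side
        # plant a clean genotype+interaction effect on protein 1: ALT,OPP+ cols are 6..8
        vals[1, 6:9] += 4.0
        mat = make_matrix(vals)
        res = two_way_anova_per_feature(mat)
        assert res["p_genotype"].iloc[1] < 1e-4
        assert res["effect"].iloc[1] > 2.0
        null_p = res["p_genotype"].iloc[2:]
        assert sps.kstest(null_p, "uniform").pvalue > 1e-3

    def test_unbalanced_falls_back_with_warning(self, rng):
        mat = make_matrix(rng.normal(size=(5, 12)))
        dropped = mat.values.drop(columns=[mat.values.columns[0]])
        unbal = IntensityMatrix(
            dropped,
            mat.genotype.drop(mat.values.columns[0]),
            mat.label.drop(mat.values.columns[0]),
        )
        with pytest.warns(UserWarning, match="unbalanced"):
            res = two_way_anova_per_feature(unbal)
        assert ((res["p_genotype"] >= 0) & (res["p_genotype"] <= 1)).all()

    def test_type2_matches_balanced_when_balanced(self, rng):
        from ashmscan.stats import _anova_balanced, _anova_type2

        mat = make_matrix(rng.normal(size=(20, 12)))
        a, b = _anova_balanced(mat), _anova_type2(mat)
        for col in ("p_genotype", "p_label", "p_interaction"):
            assert np.allclose(a[col], b[col], atol=1e-8)

    def test_missing_values_refused(self):
        vals = np.full((2, 12), 1.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            make_matrix(vals)


class TestProteomeShift:
    def test_no_significant_proteins(self, rng):
        mat = make_matrix(rng.normal(size=(30, 12)))
        res = proteome_shift_analysis(mat)
        assert res.up == [] and res.down == []
        assert res.association_p is None and "skipped" in res.notice

    def test_annotation_free_skips_association(self, rng):
        vals = rng.normal(0, 0.2, size=(30, 12))
        vals[0, 6:9] += 5.0
        mat = make_matrix(vals)
        res = proteome_shift_analysis(mat)
        assert res.up and res.association_p is None
        assert "annotation" in res.notice

    def test_planted_tsp_down(self, rng):
        vals = rng.normal(0, 0.2, size=(60, 12))
        ann = ["none"] * 60
        for i in range(8):
            vals[i, 6:9] -= 5.0
            ann[i] = "TSP"
        for i in range(8, 12):
            vals[i, 6:9] += 5.0
            ann[i] = "oncoprotein"
        mat = make_matrix(vals, annotation=ann)
        res = proteome_shift_analysis(mat)
        assert set(res.down) >= {f"PR{i}" for i in range(8)}
        assert res.association_p < 0.05
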