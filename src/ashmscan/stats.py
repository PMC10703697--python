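"""Exact and asymptotic cohort statistics.

Fisher's exact test is computed by full hypergeometric enumeration in
exact integer arithmetic (minimum-likelihood two-sided rule). The Wilcoxon
signed-rank test uses the exact sign-assignment distribution (via a
generating-function convolution over doubled ranks, so tied average ranks
stay integral) for small n and a tie-corrected normal approximation above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact_2x2",
    "wilcoxon_signed_rank",
    "chi_squared_contingency",
    "benjamini_hochberg",
    "sv_allele_frequency",
    "ihc_h_score",
    "IntensityMatrix",
    "two_way_anova_per_feature",
    "proteome_shift_analysis",
    "ProteomeShiftResult",
]

_SIDED_ALIASES = {
    "two": "two-sided",
    "two-sided": "two-sided",
    "one-greater": "greater",
    "greater": "greater",
    "one-less": "less",
    "less": "less",
}


def _norm_sided(sided: str) -> str:
    try:
        return _SIDED_ALIASES[sided]
    except KeyError:
        raise ValueError(f"unknown sidedness {sided!r}") from None


def fisher_exact_2x2(table, sided: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]``.

    Enumerates every table with the observed margins in exact rational
    arithmetic. The two-sided p-value follows the minimum-likelihood rule:
    sum of probabilities of all tables no more probable than the observed
    one. ``sided`` accepts {two, one-greater, one-less} or the scipy names;
    'greater' tests for association in the direction of larger ``a``.
    """
    sided = _norm_sided(sided)
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("table cells must be nonnegative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table has no observations")
    r1, c1 = a + b, a + c
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, r1)
    weights = {k: comb(c1, k) * comb(n - c1, r1 - k) for k in range(k_min, k_max + 1)}
    obs = weights[a]
    if sided == "greater":
        num = sum(w for k, w in weights.items() if k >= a)
    elif sided == "less":
        num = sum(w for k, w in weights.items() if k <= a)
    else:
        num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, denom))


def _signed_rank_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Distribution of the positive-rank sum over all sign assignments.

    ``doubled_ranks`` are 2x the (possibly tied average) ranks, hence
    integers. Returns counts indexed by doubled rank-sum 0..sum(ranks).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x,
    y=None,
    sided: str = "two-sided",
    zero_policy: str = "discard",
    exact_threshold: int = 25,
) -> float:
    """Wilcoxon signed-rank test p-value for paired data.

    ``x`` may be the vector of paired differences, or ``y`` supplies the
    second member of each pair. Zeros are discarded by default
    (``zero_policy='pratt'`` ranks them first, then drops them from the
    statistic). Exact distribution for n <= ``exact_threshold`` nonzero
    pairs; tie-corrected normal approximation otherwise. 'greater' tests
    for positive differences. n = 0 after zero handling returns p = 1.
    """
    sided = _norm_sided(sided)
    if zero_policy not in ("discard", "pratt"):
        raise ValueError("zero_policy must be 'discard' or 'pratt'")
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.ndim != 1:
        raise ValueError("paired differences must be one-dimensional")
    if zero_policy == "discard":
        d = d[d != 0]
        if d.size == 0:
            return 1.0
        ranks = sps.rankdata(np.abs(d))
    else:
        if np.all(d == 0):
            return 1.0
        ranks_all = sps.rankdata(np.abs(d))
        nz = d != 0
        d, ranks = d[nz], ranks_all[nz]
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_threshold:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(doubled)
        total_assignments = counts.sum()
        w2 = int(round(2 * w_plus))
        p_greater = counts[w2:].sum() / total_assignments
        p_less = counts[: w2 + 1].sum() / total_assignments
    else:
        mu = ranks.sum() / 2.0
        sd = sqrt(float((ranks**2).sum()) / 4.0)
        z = (w_plus - mu) / sd
        p_greater = float(sps.norm.sf(z))
        p_less = float(sps.norm.cdf(z))
    if sided == "greater":
        return float(min(1.0, p_greater))
    if sided == "less":
        return float(min(1.0, p_less))
    return float(min(1.0, 2.0 * min(p_greater, p_less)))


def chi_squared_contingency(table, correction: bool = False):
    """Pearson chi-squared test of independence on an r x c table.

    Returns ``(statistic, df, p)``. No continuity correction by default.
    Raises on zero row/column margins.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(arr < 0):
        raise ValueError("table cells must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(arr, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def sv_allele_frequency(
    supporting_reads: int, coverage_locus1: float, coverage_locus2: float
) -> float:
    """Breakpoint-read allele frequency: supporting reads over the mean
    coverage of the two partner loci, clipped to [0, 1]."""
    if supporting_reads < 0 or coverage_locus1 < 0 or coverage_locus2 < 0:
        raise ValueError("read counts and coverages must be nonnegative")
    mean_cov = (coverage_locus1 + coverage_locus2) / 2.0
    if mean_cov == 0:
        raise ValueError("zero coverage at both loci")
    return float(min(1.0, max(0.0, supporting_reads / mean_cov)))


def ihc_h_score(pct_strong: float, pct_moderate: float, pct_weak: float) -> float:
    """Immunohistochemistry H-score: 3*%strong + 2*%moderate + 1*%weak."""
    pcts = (pct_strong, pct_moderate, pct_weak)
    if any(p < 0 for p in pcts):
        raise ValueError("percentages must be nonnegative")
    if sum(pcts) > 100 + 1e-9:
        raise ValueError("percentages sum to more than 100")
    return 3.0 * pct_strong + 2.0 * pct_moderate + 1.0 * pct_weak


@dataclass
class IntensityMatrix:
    """Protein log-intensities with a fully crossed 2x2 sample design."""

    values: pd.DataFrame  # proteins x samples
    genotype: pd.Series  # per sample, in {WT, ALT}
    label: pd.Series  # per sample, in {OPP+, OPP-}
    annotation: pd.Series | None = None  # per protein, {oncoprotein, TSP, none}

    def __post_init__(self) -> None:
        self.genotype = pd.Series(self.genotype, index=self.values.columns)
        self.label = pd.Series(self.label, index=self.values.columns)
        if self.values.isna().any().any():
            raise ValueError("missing intensities refused; impute upstream or drop")
        if set(self.genotype.unique()) - {"WT", "ALT"}:
            raise ValueError("genotype factor must be WT/ALT")
        if set(self.label.unique()) - {"OPP+", "OPP-"}:
            raise ValueError("label factor must be OPP+/OPP-")
        counts = {
            (g, l): int(((self.genotype == g) & (self.label == l)).sum())
            for g in ("WT", "ALT")
            for l in ("OPP+", "OPP-")
        }
        if any(c < 2 for c in counts.values()):
            raise ValueError("need >=2 replicates in every factor cell")
        self._cell_counts = counts

    @property
    def is_balanced(self) -> bool:
        return len(set(self._cell_counts.values())) == 1


def _anova_balanced(mat: IntensityMatrix) -> pd.DataFrame:
    vals = mat.values.to_numpy(dtype=float)
    masks = {
        (g, l): ((mat.genotype == g) & (mat.label == l)).to_numpy()
        for g in ("WT", "ALT")
        for l in ("OPP+", "OPP-")
    }
    r = next(iter(mat._cell_counts.values()))
    n_total = vals.shape[1]
    cell_means = {key: vals[:, m].mean(axis=1) for key, m in masks.items()}
    grand = vals.mean(axis=1)
    g_means = {
        g: (cell_means[(g, "OPP+")] + cell_means[(g, "OPP-")]) / 2 for g in ("WT", "ALT")
    }
    l_means = {
        l: (cell_means[("WT", l)] + cell_means[("ALT", l)]) / 2 for l in ("OPP+", "OPP-")
    }
    ss_a = 2 * r * sum((g_means[g] - grand) ** 2 for g in ("WT", "ALT"))
    ss_b = 2 * r * sum((l_means[l] - grand) ** 2 for l in ("OPP+", "OPP-"))
    ss_ab = r * sum(
        (cell_means[(g, l)] - g_means[g] - l_means[l] + grand) ** 2
        for g in ("WT", "ALT")
        for l in ("OPP+", "OPP-")
    )
    ss_e = np.zeros_like(grand)
    for key, m in masks.items():
        ss_e += ((vals[:, m] - cell_means[key][:, None]) ** 2).sum(axis=1)
    df_e = n_total - 4
    ms_e = ss_e / df_e

    def _p(ss_effect: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ms_e > 0, ss_effect / ms_e, np.inf)
        p = sps.f.sf(f, 1, df_e)
        # degenerate variance conventions: no residual and no effect -> p=1;
        # no residual but a real effect -> p=0
        zero_all = (ms_e == 0) & (ss_effect == 0)
        return np.where(zero_all, 1.0, np.where(ms_e == 0, 0.0, p))

    effect = cell_means[("ALT", "OPP+")] - cell_means[("WT", "OPP+")]
    return pd.DataFrame(
        {
            "p_genotype": _p(ss_a),
            "p_label": _p(ss_b),
            "p_interaction": _p(ss_ab),
            "effect": effect,
        },
        index=mat.values.index,
    )


def _anova_type2(mat: IntensityMatrix) -> pd.DataFrame:
    """Type-II sums of squares via successive least-squares fits."""
    g = (mat.genotype == "ALT").to_numpy(dtype=float)
    l = (mat.label == "OPP+").to_numpy(dtype=float)
    inter = g * l
    ones = np.ones_like(g)
    vals = mat.values.to_numpy(dtype=float)
    n = vals.shape[1]

    def rss(cols: list[np.ndarray]) -> np.ndarray:
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, vals.T, rcond=None)
        resid = vals.T - X @ beta
        return (resid**2).sum(axis=0)

    rss_full = rss([ones, g, l, inter])
    rss_main = rss([ones, g, l])
    rss_no_g = rss([ones, l])
    rss_no_l = rss([ones, g])
    df_e = n - 4
    ms_e = rss_full / df_e

    def _p(ss_effect: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ms_e > 0, ss_effect / ms_e, np.inf)
        p = sps.f.sf(f, 1, df_e)
        zero_all = (ms_e == 0) & (np.abs(ss_effect) < 1e-12)
        return np.where(zero_all, 1.0, np.where(ms_e == 0, 0.0, p))

    masks = {
        (gg, ll): ((mat.genotype == gg) & (mat.label == ll)).to_numpy()
        for gg in ("WT", "ALT")
        for ll in ("OPP+", "OPP-")
    }
    effect = vals[:, masks[("ALT", "OPP+")]].mean(axis=1) - vals[
        :, masks[("WT", "OPP+")]
    ].mean(axis=1)
    return pd.DataFrame(
        {
            "p_genotype": _p(rss_no_g - rss_main),
            "p_label": _p(rss_no_l - rss_main),
            "p_interaction": _p(rss_main - rss_full),
            "effect": effect,
        },
        index=mat.values.index,
    )


def two_way_anova_per_feature(mat: IntensityMatrix) -> pd.DataFrame:
    """Per-protein fixed-effects two-way ANOVA with interaction.

    Balanced designs use the classic sums-of-squares decomposition;
    unbalanced designs fall back to type-II SS with a warning. Adds
    BH-adjusted columns for both main factors.
    """
    if mat.is_balanced:
        out = _anova_balanced(mat)
    else:
        warnings.warn("unbalanced design: using type-II sums of squares")
        out = _anova_type2(mat)
    out["p_genotype_adj"] = benjamini_hochberg(out["p_genotype"].to_numpy())
    out["p_label_adj"] = benjamini_hochberg(out["p_label"].to_numpy())
    return out


@dataclass
class ProteomeShiftResult:
    anova: pd.DataFrame
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    association_table: list | None = None
    association_p: float | None = None
    notice: str | None = None


def proteome_shift_analysis(
    mat: IntensityMatrix, alpha: float = 0.01
) -> ProteomeShiftResult:
    """Select genotype-shifted proteins at BH-adjusted p < alpha, split by
    the sign of the (ALT, OPP+) minus (WT, OPP+) mean difference, and test
    the tumor-suppressor/downregulation association by Fisher's exact test."""
    anova = two_way_anova_per_feature(mat)
    sig = anova[anova["p_genotype_adj"] < alpha]
    up = sig.index[sig["effect"] > 0].tolist()
    down = sig.index[sig["effect"] < 0].tolist()
    result = ProteomeShiftResult(anova=anova, up=up, down=down)
    if not up and not down:
        result.notice = "no significant proteins; association test skipped"
        return result
    if mat.annotation is None:
        result.notice = "no protein annotation; association test skipped"
        return result
    ann = mat.annotation
    tsp_down = sum(ann.get(p) == "TSP" for p in down)
    tsp_up = sum(ann.get(p) == "TSP" for p in up)
    table = [[tsp_down, len(down) - tsp_down], [tsp_up, len(up) - tsp_up]]
    result.association_table = table
    result.association_p = fisher_exact_2x2(table, "two-sided")
    return result
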