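"""Density profiles, rainfall/kataegis, segment scan, per-peak and
compartment comparisons, indel summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from ashmscan.enrichment import (
    compartment_se_mutation_fractions,
    detect_kataegis,
    feature_density_profile,
    indel_class_summary,
    per_peak_overlap_comparison,
    rainfall,
    segment_binomial_p,
    segment_scan,
    tad_boundary_profile,
    tss_density_profile,
)
from ashmscan.annotation import partition_mark_regions
from ashmscan.genome import Gene
from ashmscan.intervals import Interval, find_overlaps
from ashmscan.variants import SampleMutationSet
from ashmscan.simulate import CohortConfig, filtered_cohort, simulate_cohort

from test_variants import make_variant


def sample_at(positions, stage="DHL", sample_id="S1", chrom="chr1", **kw):
    variants = [make_variant(pos=int(p), chrom=chrom, **kw) for p in positions]
    return SampleMutationSet("P1", stage, sample_id, variants)


GENES = [Gene("GA", "chr1", 100_000, "+", 99_999, 150_000)]


class TestTssProfile:
    def test_delta_at_tss(self):
        cohort = [sample_at([100_000] * 20)]
        profile = tss_density_profile(cohort, GENES, window=5000, bin_size=100)
        vec = profile.stage_mean["DHL"]
        zero_bin = np.searchsorted(profile.bin_edges, 0, side="right") - 1
        assert vec[zero_bin] == 1.0 and vec.sum() == 1.0

    def test_uniform_is_flat(self, rng):
        positions = rng.integers(95_001, 105_000, 4000)
        profile = tss_density_profile(
            [sample_at(positions)], GENES, window=5000, bin_size=1000
        )
        vec = profile.stage_mean["DHL"]
        assert vec.sum() == pytest.approx(1.0)
        # multinomial tolerance around 1/10 per bin
        assert np.all(np.abs(vec - 0.1) < 5 * np.sqrt(0.1 * 0.9 / 4000))

    def test_conserves_counts(self, rng):
        positions = rng.integers(90_000, 110_000, 500)
        profile = tss_density_profile(
            [sample_at(positions)], GENES, window=5000, bin_size=100, mode="per_mb"
        )
        in_window = np.sum(np.abs(positions - 100_000) <= 5000) - np.sum(
            positions - 100_000 == 5000
        )
        counts = profile.per_sample["DHL"].to_numpy() * (100 / 1e6)
        assert int(round(counts.sum())) == in_window

    def test_order_invariance(self, rng):
        positions = rng.integers(95_001, 105_000, 200)
        p1 = tss_density_profile([sample_at(positions)], GENES)
        p2 = tss_density_profile([sample_at(positions[::-1])], GENES)
        assert np.allclose(p1.stage_mean["DHL"], p2.stage_mean["DHL"])

    def test_strand_awareness(self):
        minus_gene = [Gene("GB", "chr1", 100_000, "-", 50_000, 100_000)]
        profile = tss_density_profile(
            [sample_at([100_500] * 5)], minus_gene, window=5000, bin_size=100
        )
        center = profile.bin_centers[np.argmax(profile.stage_mean["DHL"])]
        assert center == -450.0  # downstream position is upstream of a - TSS

    def test_sample_without_in_window_mutations_skipped(self):
        far = sample_at([4_000_000], sample_id="far")
        near = sample_at([100_000], sample_id="near")
        with pytest.warns(UserWarning, match="far"):
            profile = tss_density_profile([near, far], GENES)
        assert profile.skipped_samples == ["far"]

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            tss_density_profile([], GENES)


class TestFeatureProfile:
    def test_central_mass(self):
        anchors = [Interval("chr1", 99_000, 101_000)]
        profile = feature_density_profile(
            [sample_at([100_001] * 10)], anchors, window=5000, bin_size=100
        )
        vec = profile.stage_mean["DHL"]
        assert vec[np.searchsorted(profile.bin_edges, 0, side="right") - 1] == 1.0

    def test_symmetric_placement(self):
        anchors = [Interval("chr1", 99_000, 101_000)]  # midpoint 100,000
        offsets = [-2500, -1500, 1500, 2500]  # half-bin offsets: mirror bins
        cohort = [sample_at([100_000 + o + 1 for o in offsets])]
        profile = feature_density_profile(cohort, anchors, window=5000, bin_size=1000)
        vec = profile.stage_mean["DHL"]
        assert np.allclose(vec, vec[::-1])


class TestTadBoundaryProfile:
    TADS = [Interval("chr1", 100_000, 300_000)]

    def test_boundary_center_zero_bin(self):
        profile = tad_boundary_profile(
            [sample_at([100_001])], self.TADS, window=10_000, bin_size=1000
        )
        vec = profile.stage_mean["DHL"]
        assert vec[np.searchsorted(profile.bin_edges, 0, side="right") - 1] == 1.0

    def test_inside_is_negative(self):
        profile = tad_boundary_profile(
            [sample_at([103_001, 297_001])], self.TADS, window=10_000, bin_size=1000
        )
        centers = profile.bin_centers
        vec = profile.stage_mean["DHL"]
        assert vec[centers < 0].sum() == pytest.approx(1.0)

    def test_outside_is_positive(self):
        profile = tad_boundary_profile(
            [sample_at([95_001, 304_001])], self.TADS, window=10_000, bin_size=1000
        )
        assert profile.stage_mean["DHL"][profile.bin_centers > 0].sum() == 1.0


class TestRainfall:
    def test_example(self):
        df = rainfall(sample_at([100, 200, 1200]))
        assert df["imd"].tolist() == [100, 1000]
        assert df["pos"].tolist() == [200, 1200]

    def test_single_mutation_empty(self):
        assert rainfall(sample_at([100])).empty

    def test_shuffle_invariance(self, rng):
        positions = rng.integers(1, 1_000_000, 50)
        a = rainfall(sample_at(positions))
        b = rainfall(sample_at(rng.permutation(positions)))
        assert a.equals(b)


class TestKataegis:
    def test_six_spaced_500(self):
        positions = [10_000 + 500 * i for i in range(6)]
        clusters = detect_kataegis(sample_at(positions))
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (9_999, 12_500)

    def test_five_is_not_enough(self):
        positions = [10_000 + 500 * i for i in range(5)]
        assert detect_kataegis(sample_at(positions)) == []

    def test_gap_breaks_run(self):
        positions = [10_000 + 500 * i for i in range(6)]
        positions += [50_000 + 500 * i for i in range(6)]
        assert len(detect_kataegis(sample_at(positions))) == 2

    def test_planted_exact_recovery(self, enriched_sim, enriched_cohort):
        # every planted cluster must be recovered with its exact interval;
        # the detector may additionally find genuine clusters arising from
        # the planted footprint enrichment itself
        for sample in enriched_cohort:
            planted = {
                tuple(x) for x in enriched_sim.truth["kataegis"][sample.sample_id]
            }
            detected = {
                (iv.chrom, iv.start, iv.end) for iv in detect_kataegis(sample)
            }
            assert planted <= detected

    def test_planted_exact_recovery_null_background(self, null_sim, null_cohort):
        # without footprint enrichment the detected set matches planted exactly
        for sample in null_cohort:
            planted = sorted(
                tuple(x) for x in null_sim.truth["kataegis"][sample.sample_id]
            )
            detected = sorted(
                (iv.chrom, iv.start, iv.end) for iv in detect_kataegis(sample)
            )
            assert detected == planted


class TestSegmentScan:
    def test_closed_form_binomial(self):
        assert segment_binomial_p(5, 5, 0.5) == pytest.approx(0.03125)

    def test_scan_reproduces_closed_form(self):
        # one segment with FL=0, DHL=5 while overall proportion is 1/2
        fl = sample_at([1_000_000 + i for i in range(5)], stage="FL", sample_id="F")
        dhl = sample_at([2_000_000 + i for i in range(5)], stage="DHL", sample_id="D")
        res = segment_scan([fl, dhl], [("chr1", 4_000_000)])
        assert res.p0 == 0.5
        dhl_seg = res.table[res.table["dhl_count"] == 5]
        assert dhl_seg["p"].iloc[0] == pytest.approx(0.03125)

    def test_requires_both_stages(self):
        with pytest.raises(ValueError):
            segment_scan([sample_at([100])], [("chr1", 1_000_000)])

    def test_no_qualifying_segments_is_empty(self):
        fl = sample_at([100], stage="FL", sample_id="F")
        dhl = sample_at([200_000], stage="DHL", sample_id="D")
        res = segment_scan([fl, dhl], [("chr1", 1_000_000)])
        assert len(res.table) == 0

    def test_planted_recovery(self, enriched_sim, enriched_cohort, toy_genome):
        res = segment_scan(
            enriched_cohort, toy_genome.chromosomes, tracks=toy_genome.tracks
        )
        planted = [Interval(c, s, e) for c, s, e in enriched_sim.truth["enriched_regions"]]
        sig = res.significant_intervals()
        recovered = {j for _, j in find_overlaps(sig, planted)}
        assert len(recovered) / len(planted) >= 0.8

    def test_annotation_flags(self, enriched_cohort, toy_genome):
        from ashmscan.annotation import call_superenhancers, stitch_enhancers

        tracks = toy_genome.tracks
        tracks.superenhancers = call_superenhancers(
            stitch_enhancers(tracks.k27ac, toy_genome.genes)
        ).superenhancers
        res = segment_scan(enriched_cohort, toy_genome.chromosomes, tracks=tracks)
        sig = res.significant
        # planted enrichment sits in SE-promoter footprints
        assert sig["overlaps_enhancer"].any()

    def test_permuted_labels_superuniform(self, small_genome):
        # calibration: permuting stage labels kills the signal
        rejections = 0
        tested = 0
        for seed in range(6):
            config = CohortConfig(
                n_patients=4, se_promoter_enrichment=6.0, seed=100 + seed
            )
            cohort = filtered_cohort(simulate_cohort(small_genome, config))
            # swap stage labels within each patient
            flipped = [
                SampleMutationSet(
                    s.patient_id,
                    "FL" if s.stage == "DHL" else "DHL",
                    s.sample_id,
                    s.variants,
                )
                for s in cohort
            ]
            res = segment_scan(flipped, small_genome.chromosomes)
            tested += len(res.table)
            rejections += int(res.table["significant"].sum())
        assert tested > 50
        # enrichment now points the wrong way; BH should reject ~nothing
        assert rejections / tested <= 0.05


class TestPerPeak:
    PEAKS = [Interval("chr1", 0, 1000), Interval("chr1", 5000, 6000)]

    def test_identical_stages_p_one(self):
        fl = sample_at([500, 5500], stage="FL", sample_id="F")
        dhl = sample_at([500, 5500], stage="DHL", sample_id="D")
        res = per_peak_overlap_comparison([fl, dhl], self.PEAKS)
        assert res["p"] == 1.0
        assert np.allclose(res["table"]["fl_pct"], res["table"]["dhl_pct"])

    def test_single_peak_tops_ranking(self):
        fl = sample_at([100_000], stage="FL", sample_id="F")
        dhl = sample_at([500] * 10, stage="DHL", sample_id="D")
        res = per_peak_overlap_comparison([fl, dhl], self.PEAKS)
        assert res["top"].iloc[0]["start"] == 0
        assert res["top"].iloc[0]["dhl_pct"] == 100.0

    def test_random_vs_recount(self, rng):
        peaks = [Interval("chr1", int(s), int(s) + 500) for s in range(0, 50_000, 1000)]
        fl = sample_at(rng.integers(1, 50_000, 200), stage="FL", sample_id="F")
        dhl = sample_at(rng.integers(1, 50_000, 300), stage="DHL", sample_id="D")
        res = per_peak_overlap_comparison([fl, dhl], peaks)
        for stage, sample, col in (("FL", fl, "fl_pct"), ("DHL", dhl, "dhl_pct")):
            for i, peak in enumerate(peaks):
                n = sum(1 for v in sample.variants if peak.contains_point(v.pos))
                expected = n / sample.n_variants * 100
                assert res["table"][col].iloc[i] == pytest.approx(expected)
        # disjoint peaks: percentages sum to <= 100
        assert res["table"]["fl_pct"].sum() <= 100 + 1e-9


class TestCompartmentFractions:
    COMPS = [
        Interval("chr1", 0, 500_000, label="A"),
        Interval("chr1", 500_000, 1_000_000, label="B"),
    ]
    SES = [Interval("chr1", 100_000, 110_000), Interval("chr1", 600_000, 610_000)]

    def test_all_se_in_a(self):
        ses = [Interval("chr1", 100_000, 110_000)]
        s = sample_at([100_500, 105_000])
        res = compartment_se_mutation_fractions([s], ses, self.COMPS)
        assert res["table"]["frac_a"].tolist() == [1.0]

    def test_sample_without_se_mutations_excluded(self):
        s = sample_at([900_000], sample_id="empty")
        with pytest.warns(UserWarning, match="empty"):
            res = compartment_se_mutation_fractions([s], self.SES, self.COMPS)
        assert res["excluded"] == ["empty"] and res["table"].empty

    def test_random_vs_recount(self, rng):
        positions = rng.integers(1, 1_000_000, 400)
        s = sample_at(positions)
        res = compartment_se_mutation_fractions([s], self.SES, self.COMPS)
        in_se = [
            p for p in positions if any(se.contains_point(int(p)) for se in self.SES)
        ]
        n_a = sum(1 for p in in_se if p <= 500_000)
        row = res["table"].iloc[0]
        assert row["frac_a"] == pytest.approx(n_a / len(in_se))
        assert row["frac_a"] + row["frac_b"] == pytest.approx(1.0)


class TestIndels:
    def test_all_snvs(self):
        df = indel_class_summary([sample_at([100, 200, 300])])
        assert (df["micro_insertion_frac"] == 0).all()
        assert (df["micro_deletion_frac"] == 0).all()

    def test_one_insertion_in_ten(self):
        variants = [make_variant(pos=100 + i) for i in range(9)]
        variants.append(make_variant(pos=500, ref="A", alt="ATTT"))
        s = SampleMutationSet("P1", "DHL", "S", variants)
        df = indel_class_summary([s])
        row = df[df["stage"] == "DHL"].iloc[0]
        assert row["micro_insertion_frac"] == pytest.approx(0.1)

    def test_mix_vs_recount(self, rng):
        variants = []
        for i in range(60):
            kind = rng.choice(["snv", "ins", "del"], p=[0.7, 0.15, 0.15])
            if kind == "snv":
                variants.append(make_variant(pos=1000 + i * 10))
            elif kind == "ins":
                variants.append(make_variant(pos=1000 + i * 10, ref="A", alt="AGG"))
            else:
                variants.append(make_variant(pos=1000 + i * 10, ref="AGG", alt="A"))
        s = SampleMutationSet("P1", "FL", "S", variants)
        parts = partition_mark_regions(
            [Interval("chr1", 1000, 1200)], [Interval("chr1", 1100, 1400)]
        )
        df = indel_class_summary([s], parts)
        row = df[df["stage"] == "FL"].iloc[0]
        n_ins = sum(1 for v in variants if len(v.alt) > len(v.ref))
        n_del = sum(1 for v in variants if len(v.ref) > len(v.alt))
        assert row["micro_insertion_frac"] == pytest.approx(n_ins / 60)
        assert row["micro_deletion_frac"] == pytest.approx(n_del / 60)
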