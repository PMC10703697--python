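"""Cohort mutation-enrichment analyses.

Anchored density profiles (TSS, mark regions, TAD boundaries), rainfall /
kataegis detection, the fixed-size differential segment scan, per-peak
paired overlap comparisons, compartment fractions of super-enhancer
mutations and micro-indel summaries.

Profiles assign each in-window mutation to its nearest anchor, bin the
signed distance, normalize each sample's vector to a proportion (so load
differences between stages drop out) and average within stage. A
mutations-per-megabase mode is available for absolute comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import nearest_tss_distance
from .genome import Gene, TrackBundle
from .intervals import Interval, find_overlaps, merge
from .stats import benjamini_hochberg, wilcoxon_signed_rank
from .variants import SampleMutationSet

__all__ = [
    "DensityProfile",
    "tss_density_profile",
    "feature_density_profile",
    "tad_boundary_profile",
    "rainfall",
    "detect_kataegis",
    "segment_binomial_p",
    "SegmentScanResult",
    "segment_scan",
    "per_peak_overlap_comparison",
    "compartment_se_mutation_fractions",
    "indel_class_summary",
]

STAGES = ("FL", "DHL")


@dataclass
class DensityProfile:
    anchor_class: str
    bin_edges: np.ndarray  # signed bp, uniform widths
    stage_mean: dict[str, np.ndarray]
    per_sample: dict[str, pd.DataFrame]  # stage -> samples x bins
    mode: str  # 'proportion' or 'per_mb'
    skipped_samples: list[str] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"center": self.bin_centers})
        for stage, vec in self.stage_mean.items():
            df[stage] = vec
        return df


def _signed_distances(
    sample: SampleMutationSet, distance_fn: Callable[[str, int], int | None]
) -> np.ndarray:
    ds = []
    for v in sample.variants:
        d = distance_fn(v.chrom, v.pos)
        if d is not None:
            ds.append(d)
    return np.asarray(ds, dtype=float)


def _profile(
    cohort: Iterable[SampleMutationSet],
    distance_fn: Callable[[str, int], int | None],
    anchor_class: str,
    window: int,
    bin_size: int,
    mode: str = "proportion",
) -> DensityProfile:
    if mode not in ("proportion", "per_mb"):
        raise ValueError("mode must be 'proportion' or 'per_mb'")
    if window <= 0 or bin_size <= 0 or window % bin_size:
        raise ValueError("window must be a positive multiple of bin size")
    edges = np.arange(-window, window + bin_size, bin_size, dtype=float)
    per_sample: dict[str, dict[str, np.ndarray]] = {s: {} for s in STAGES}
    skipped: list[str] = []
    for sample in cohort:
        d = _signed_distances(sample, distance_fn)
        d = d[(d >= -window) & (d < window)]
        if d.size == 0:
            skipped.append(sample.sample_id)
            warnings.warn(
                f"sample {sample.sample_id} has no in-window mutations; skipped"
            )
            continue
        counts, _ = np.histogram(d, bins=edges)
        if mode == "proportion":
            vec = counts / counts.sum()
        else:
            vec = counts / (bin_size / 1e6)
        per_sample[sample.stage][sample.sample_id] = vec
    frames = {
        stage: pd.DataFrame.from_dict(vals, orient="index", columns=edges[:-1])
        for stage, vals in per_sample.items()
        if vals
    }
    stage_mean = {
        stage: frame.to_numpy().mean(axis=0) for stage, frame in frames.items()
    }
    return DensityProfile(
        anchor_class=anchor_class,
        bin_edges=edges,
        stage_mean=stage_mean,
        per_sample=frames,
        mode=mode,
        skipped_samples=skipped,
    )


def tss_density_profile(
    cohort: Sequence[SampleMutationSet],
    genes: Sequence[Gene],
    window: int = 5000,
    bin_size: int = 100,
    mode: str = "proportion",
) -> DensityProfile:
    """Strand-aware mutation density around gene TSSs, per stage."""
    stages = {s.stage for s in cohort}
    if not stages:
        raise ValueError("empty cohort")
    chroms = {g.chrom for g in genes}

    def dist(chrom: str, pos: int) -> int | None:
        if chrom not in chroms:
            return None
        return nearest_tss_distance(chrom, pos, genes)

    return _profile(cohort, dist, "TSS", window, bin_size, mode)


def _midpoint_distance_fn(anchors: Sequence[Interval]):
    mids: dict[str, np.ndarray] = {}
    for iv in anchors:
        mids.setdefault(iv.chrom, [])
    for iv in anchors:
        mids[iv.chrom].append((iv.start + iv.end) // 2)
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}

    def dist(chrom: str, pos: int) -> int | None:
        arr = mids.get(chrom)
        if arr is None or arr.size == 0:
            return None
        pos0 = pos - 1
        i = int(np.searchsorted(arr, pos0))
        best = None
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                d = pos0 - int(arr[j])
                if best is None or abs(d) < abs(best):
                    best = d
        return best

    return dist


def feature_density_profile(
    cohort: Sequence[SampleMutationSet],
    anchors: Sequence[Interval],
    anchor_class: str = "feature",
    window: int = 5000,
    bin_size: int = 100,
    mode: str = "proportion",
) -> DensityProfile:
    """Mutation density around anchor-interval midpoints, per stage."""
    if not anchors:
        raise ValueError("empty anchor set")
    return _profile(
        cohort, _midpoint_distance_fn(anchors), anchor_class, window, bin_size, mode
    )


def tad_boundary_profile(
    cohort: Sequence[SampleMutationSet],
    tads: Sequence[Interval],
    window: int = 100_000,
    bin_size: int = 5000,
    mode: str = "proportion",
) -> DensityProfile:
    """Density around outermost TAD boundaries; negative = inside the TAD.

    Each mutation is assigned to its nearest boundary; only top-level
    (outermost) TAD edges are used.
    """
    if not tads:
        raise ValueError("no TADs supplied")
    tops = merge(tads)  # outermost extents; drops nested/intra-TAD boundaries
    # boundary -> signed distance with inside-of-TAD negative
    bounds: dict[str, list[tuple[int, int]]] = {}
    for iv in tops:
        bounds.setdefault(iv.chrom, []).append((iv.start, +1))  # inside is to the right
        bounds[iv.chrom].append((iv.end, -1))  # inside is to the left

    def dist(chrom: str, pos: int) -> int | None:
        items = bounds.get(chrom)
        if not items:
            return None
        pos0 = pos - 1
        best = None
        for b, inside_sign in items:
            # raw distance pointing away from the TAD interior
            d = (pos0 - b) * -inside_sign
            if best is None or abs(d) < abs(best[0]):
                best = (d, b)
        return best[0]

    return _profile(cohort, dist, "TAD-boundary", window, bin_size, mode)


def rainfall(sample: SampleMutationSet) -> pd.DataFrame:
    """Per-mutation intermutation distance to the previous mutation on the
    same chromosome. The first mutation per chromosome is omitted."""
    rows = []
    for chrom, positions in sorted(sample.positions().items()):
        for prev, cur in zip(positions, positions[1:]):
            rows.append((chrom, cur, cur - prev))
    return pd.DataFrame(rows, columns=["chrom", "pos", "imd"])


def detect_kataegis(
    sample: SampleMutationSet, min_cluster: int = 6, max_imd: int = 1000
) -> list[Interval]:
    """Maximal runs of >= ``min_cluster`` mutations whose consecutive
    intermutation distances are all <= ``max_imd``."""
    clusters: list[Interval] = []
    for chrom, positions in sorted(sample.positions().items()):
        run_start = 0
        for i in range(1, len(positions) + 1):
            end_of_run = (
                i == len(positions) or positions[i] - positions[i - 1] > max_imd
            )
            if end_of_run:
                if i - run_start >= min_cluster:
                    clusters.append(
                        Interval(chrom, positions[run_start] - 1, positions[i - 1])
                    )
                run_start = i
    return clusters


def segment_binomial_p(dhl_count: int, total: int, p0: float) -> float:
    """One-sided binomial p-value for a DHL excess in one segment."""
    if not (0 <= dhl_count <= total):
        raise ValueError("need 0 <= dhl_count <= total")
    return float(sps.binom.sf(dhl_count - 1, total, p0))


@dataclass
class SegmentScanResult:
    table: pd.DataFrame  # tested segments only
    segment_size: int
    p0: float  # genome-wide DHL proportion
    totals: dict[str, int]

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def significant_intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end), score=float(r.p_adj))
            for r in self.significant.itertuples()
        ]


def segment_scan(
    cohort: Sequence[SampleMutationSet],
    chromosomes: Sequence[tuple[str, int]],
    segment_size: int = 3000,
    min_total: int = 5,
    alpha: float = 0.05,
    tracks: TrackBundle | None = None,
) -> SegmentScanResult:
    """Tile the genome into fixed segments and test each high-load segment
    for a DHL excess.

    Pooled cohort counts per segment; segments with FL+DHL >= ``min_total``
    get a one-sided binomial test of the DHL count against the genome-wide
    DHL proportion, BH-adjusted at ``alpha``. Significant segments are
    annotated for super-enhancer / enhancer overlap when ``tracks`` is
    given.
    """
    stages = {s.stage for s in cohort}
    if not {"FL", "DHL"} <= stages:
        raise ValueError("cohort must contain both FL and DHL samples")
    lengths = dict(chromosomes)
    counts: dict[str, dict[int, np.ndarray]] = {s: {} for s in STAGES}
    totals = {s: 0 for s in STAGES}
    for sample in cohort:
        stage = sample.stage
        for chrom, positions in sample.positions().items():
            if chrom not in lengths:
                raise ValueError(f"mutation on unknown chromosome {chrom}")
            n_seg = -(-lengths[chrom] // segment_size)
            seg_counts = counts[stage].setdefault(chrom, np.zeros(n_seg, dtype=int))
            for pos in positions:
                seg_counts[(pos - 1) // segment_size] += 1
            totals[stage] += len(positions)
    grand_total = totals["FL"] + totals["DHL"]
    if grand_total == 0:
        raise ValueError("cohort contains no mutations")
    p0 = totals["DHL"] / grand_total
    rows = []
    for chrom, length in chromosomes:
        fl = counts["FL"].get(chrom)
        dhl = counts["DHL"].get(chrom)
        n_seg = -(-length // segment_size)
        fl = fl if fl is not None else np.zeros(n_seg, dtype=int)
        dhl = dhl if dhl is not None else np.zeros(n_seg, dtype=int)
        tot = fl + dhl
        for i in np.nonzero(tot >= min_total)[0]:
            start = int(i) * segment_size
            rows.append(
                (
                    chrom,
                    start,
                    min(start + segment_size, length),
                    int(fl[i]),
                    int(dhl[i]),
                    segment_binomial_p(int(dhl[i]), int(tot[i]), p0),
                )
            )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fl_count", "dhl_count", "p"]
    )
    if len(table):
        table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = table["p_adj"] <= alpha
    else:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    table["overlaps_se"] = False
    table["overlaps_enhancer"] = False
    if tracks is not None and len(table):
        segs = [
            Interval(r.chrom, int(r.start), int(r.end)) for r in table.itertuples()
        ]
        for col, track in (
            ("overlaps_se", tracks.superenhancers),
            ("overlaps_enhancer", tracks.k27ac),
        ):
            if track:
                hit_idx = {i for i, _ in find_overlaps(segs, track)}
                table[col] = [i in hit_idx for i in range(len(segs))]
    return SegmentScanResult(
        table=table, segment_size=segment_size, p0=p0, totals=totals
    )


def _stage_totals(cohort: Sequence[SampleMutationSet]) -> dict[str, int]:
    totals = {s: 0 for s in STAGES}
    for sample in cohort:
        totals[sample.stage] += sample.n_variants
    return totals


def per_peak_overlap_comparison(
    cohort: Sequence[SampleMutationSet],
    peaks: Sequence[Interval],
    genes: Sequence[Gene] = (),
    top_k: int = 15,
) -> dict:
    """Per-peak percentage of stage mutations overlapping each peak plus a
    paired two-sided Wilcoxon signed-rank test across peaks."""
    if not peaks:
        raise ValueError("empty peak set")
    totals = _stage_totals(cohort)
    if totals["FL"] == 0 or totals["DHL"] == 0:
        raise ValueError("both stages need at least one mutation")
    counts = {s: np.zeros(len(peaks), dtype=int) for s in STAGES}
    for sample in cohort:
        muts = [Interval(v.chrom, v.pos - 1, v.pos) for v in sample.variants]
        for _, j in find_overlaps(muts, list(peaks)):
            counts[sample.stage][j] += 1
    table = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "fl_pct": counts["FL"] / totals["FL"] * 100.0,
            "dhl_pct": counts["DHL"] / totals["DHL"] * 100.0,
        }
    )
    if genes:
        table["nearest_gene"] = [
            min(
                (g for g in genes if g.chrom == p.chrom),
                key=lambda g: min(
                    abs((p.start + p.end) // 2 + 1 - g.tss), abs(p.start + 1 - g.tss)
                ),
                default=None,
            ).gene_id
            if any(g.chrom == p.chrom for g in genes)
            else ""
            for p in peaks
        ]
    p_value = wilcoxon_signed_rank(
        table["dhl_pct"].to_numpy(), table["fl_pct"].to_numpy(), sided="two-sided"
    )
    order = (table["fl_pct"] + table["dhl_pct"]).to_numpy()
    top = table.iloc[np.argsort(-order, kind="mergesort")[:top_k]].reset_index(
        drop=True
    )
    return {"table": table, "p": p_value, "top": top}


def compartment_se_mutation_fractions(
    cohort: Sequence[SampleMutationSet],
    superenhancers: Sequence[Interval],
    compartments: Sequence[Interval],
) -> dict:
    """Per-sample fractions of super-enhancer mutations in compartment A
    versus B, with per-stage paired two-sided Wilcoxon tests."""
    if not superenhancers:
        raise ValueError("empty super-enhancer set")
    comp_by_label = {
        label: [iv for iv in compartments if iv.label == label] for label in ("A", "B")
    }
    rows = []
    excluded: list[str] = []
    for sample in cohort:
        se_muts = [
            v
            for v in sample.variants
            if any(
                iv.chrom == v.chrom and iv.contains_point(v.pos)
                for iv in superenhancers
            )
        ]
        if not se_muts:
            excluded.append(sample.sample_id)
            warnings.warn(
                f"sample {sample.sample_id} has no super-enhancer mutations; excluded"
            )
            continue
        n = {"A": 0, "B": 0, "unlabelled": 0}
        for v in se_muts:
            for label in ("A", "B"):
                if any(
                    iv.chrom == v.chrom and iv.contains_point(v.pos)
                    for iv in comp_by_label[label]
                ):
                    n[label] += 1
                    break
            else:
                n["unlabelled"] += 1
        labelled = n["A"] + n["B"]
        rows.append(
            (
                sample.sample_id,
                sample.stage,
                n["A"] / labelled if labelled else np.nan,
                n["B"] / labelled if labelled else np.nan,
                n["unlabelled"],
            )
        )
    table = pd.DataFrame(
        rows, columns=["sample_id", "stage", "frac_a", "frac_b", "n_unlabelled"]
    )
    p_by_stage = {}
    for stage in STAGES:
        sub = table[(table["stage"] == stage) & table["frac_a"].notna()]
        if len(sub):
            p_by_stage[stage] = wilcoxon_signed_rank(
                sub["frac_a"].to_numpy(), sub["frac_b"].to_numpy(), sided="two-sided"
            )
    return {"table": table, "p_by_stage": p_by_stage, "excluded": excluded}


def indel_class_summary(
    cohort: Sequence[SampleMutationSet],
    partitions: dict[str, list[Interval]] | None = None,
    max_len: int = 20,
) -> pd.DataFrame:
    """Micro-insertion / microdeletion fractions per stage and, when mark
    partitions are given, the fraction of each class inside the
    K27ac∩K4me3 intersection."""
    intersection = (partitions or {}).get("intersection", [])
    rows = []
    for stage in STAGES:
        variants = [v for s in cohort if s.stage == stage for v in s.variants]
        total = len(variants)
        ins = [
            v
            for v in variants
            if len(v.alt) > len(v.ref) and len(v.alt) - len(v.ref) <= max_len
        ]
        dels = [
            v
            for v in variants
            if len(v.ref) > len(v.alt) and len(v.ref) - len(v.alt) <= max_len
        ]

        def frac_in_intersection(subset) -> float:
            if not subset or not intersection:
                return np.nan
            hits = sum(
                1
                for v in subset
                if any(
                    iv.chrom == v.chrom and iv.contains_point(v.pos)
                    for iv in intersection
                )
            )
            return hits / len(subset)

        rows.append(
            (
                stage,
                total,
                len(ins) / total if total else 0.0,
                len(dels) / total if total else 0.0,
                frac_in_intersection(ins),
                frac_in_intersection(dels),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stage",
            "n_variants",
            "micro_insertion_frac",
            "micro_deletion_frac",
            "insertion_in_intersection_frac",
            "deletion_in_intersection_frac",
        ],
    )
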