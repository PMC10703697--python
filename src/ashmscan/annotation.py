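"""Regulatory annotation: enhancer stitching, super-enhancer calling,
mark-region partitioning, compartment fractions and TSS distances.

Super-enhancers are called with the classic rank-signal geometry: stitch
H3K27ac peaks within 12.5 kb (optionally dropping peaks fully inside a
±2.5 kb TSS window first), sort stitched regions by aggregate signal,
rescale both axes to [0, 1] and cut where the discrete tangent of the
signal-vs-rank curve first exceeds 1.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import Gene
from .intervals import Interval, intersect, merge, subtract, sort_intervals

__all__ = [
    "stitch_enhancers",
    "SuperEnhancerSet",
    "call_superenhancers",
    "partition_mark_regions",
    "compartment_fractions",
    "nearest_tss_distance",
]

STITCH_DISTANCE = 12_500
TSS_EXCLUSION = 2_500


def _peak_signal(peak: Interval) -> float:
    # length stands in for aggregate signal when no score is attached
    return peak.score if peak.score is not None else float(len(peak))


def stitch_enhancers(
    peaks: Iterable[Interval],
    genes: Sequence[Gene] = (),
    stitch_distance: int = STITCH_DISTANCE,
    tss_exclusion: int = TSS_EXCLUSION,
    exclude_tss: bool = True,
) -> list[Interval]:
    """Stitch enhancer peaks whose gaps are below ``stitch_distance``.

    Peaks lying fully inside ±``tss_exclusion`` bp of any TSS are dropped
    before stitching when ``exclude_tss`` is set. The stitched interval's
    score is the summed signal of its member peaks.
    """
    peaks = sort_intervals(peaks)
    if exclude_tss and genes:
        tss_by_chrom: dict[str, list[int]] = {}
        for g in genes:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss - 1)  # 0-based
        for v in tss_by_chrom.values():
            v.sort()

        def excluded(peak: Interval) -> bool:
            sites = tss_by_chrom.get(peak.chrom)
            if not sites:
                return False
            lo = bisect.bisect_left(sites, peak.start - tss_exclusion)
            hi = bisect.bisect_right(sites, peak.end + tss_exclusion)
            for t in sites[lo:hi]:
                if peak.start >= t - tss_exclusion and peak.end <= t + tss_exclusion + 1:
                    return True
            return False

        peaks = [p for p in peaks if not excluded(p)]
    if not peaks:
        return []
    out: list[Interval] = []
    cur = peaks[0]
    cur_signal = _peak_signal(cur)
    cur_start, cur_end = cur.start, cur.end
    for peak in peaks[1:]:
        if peak.chrom == cur.chrom and peak.start - cur_end < stitch_distance:
            cur_end = max(cur_end, peak.end)
            cur_signal += _peak_signal(peak)
        else:
            out.append(Interval(cur.chrom, cur_start, cur_end, score=cur_signal))
            cur = peak
            cur_start, cur_end = peak.start, peak.end
            cur_signal = _peak_signal(peak)
    out.append(Interval(cur.chrom, cur_start, cur_end, score=cur_signal))
    return out


@dataclass
class SuperEnhancerSet:
    """Stitched regions ranked by aggregate signal with a super flag."""

    intervals: list[Interval]  # ascending signal order
    signals: np.ndarray
    is_super: np.ndarray
    cutoff: float

    @property
    def superenhancers(self) -> list[Interval]:
        return [iv for iv, s in zip(self.intervals, self.is_super) if s]

    @property
    def typical(self) -> list[Interval]:
        return [iv for iv, s in zip(self.intervals, self.is_super) if not s]

    def rank_table(self) -> "np.ndarray":
        """(rank, signal, is_super) rows for plotting the rank curve."""
        n = len(self.intervals)
        return np.column_stack(
            [np.arange(1, n + 1), self.signals, self.is_super.astype(int)]
        )


def call_superenhancers(stitched: Sequence[Interval]) -> SuperEnhancerSet:
    """Flag stitched regions above the rank-curve elbow as super-enhancers.

    Signals are sorted ascending; both rank and signal are min-max rescaled
    to [0, 1]; the cutoff is the signal at the first point where the
    width-1 secant slope of the rescaled curve exceeds 1. A curve that
    never exceeds unit slope (e.g. perfectly linear signals) yields an
    infinite cutoff and no super-enhancers.
    """
    if len(stitched) < 3:
        raise ValueError("need at least 3 stitched regions to locate an elbow")
    order = np.argsort([_peak_signal(iv) for iv in stitched], kind="mergesort")
    intervals = [stitched[i] for i in order]
    signals = np.array([_peak_signal(iv) for iv in intervals], dtype=float)
    n = len(signals)
    span = signals[-1] - signals[0]
    if span == 0:
        # flat curve: no elbow, nothing is super
        return SuperEnhancerSet(
            intervals, signals, np.zeros(n, dtype=bool), float("inf")
        )
    y = (signals - signals[0]) / span
    slopes = np.diff(y) * (n - 1)  # x spacing is 1/(n-1) after rescaling
    above = np.nonzero(slopes > 1.0 + 1e-9)[0]  # tolerance: exactly-unit slopes stay below
    if above.size == 0:
        return SuperEnhancerSet(
            intervals, signals, np.zeros(n, dtype=bool), float("inf")
        )
    cutoff = float(signals[above[0] + 1])
    is_super = signals >= cutoff
    return SuperEnhancerSet(intervals, signals, is_super, cutoff)


def partition_mark_regions(
    k27ac: Iterable[Interval], k4me3: Iterable[Interval]
) -> dict[str, list[Interval]]:
    """Split two mark tracks into exclusive and intersection regions.

    Returns ``{'k27ac_only', 'k4me3_only', 'intersection'}``; the three
    sets are pairwise disjoint and union to k27ac ∪ k4me3.
    """
    a, b = list(k27ac), list(k4me3)
    return {
        "k27ac_only": subtract(a, b),
        "k4me3_only": subtract(b, a),
        "intersection": intersect(a, b),
    }


def compartment_fractions(
    features: Iterable[Interval], compartments: Iterable[Interval]
) -> dict:
    """Base pairs and fractions of a feature set per compartment label.

    Fractions are over labelled (covered) bases only; bases outside any
    compartment are reported under ``uncovered_bp``.
    """
    features = merge(features) if features else []
    comps = list(compartments)
    labels = sorted({iv.label for iv in comps if iv.label is not None})
    bp: dict[str, int] = {}
    for label in labels:
        sel = [iv for iv in comps if iv.label == label]
        bp[label] = sum(len(iv) for iv in intersect(features, sel))
    covered = sum(bp.values())
    total = sum(len(iv) for iv in features)
    fractions = {
        label: (bp[label] / covered if covered else 0.0) for label in labels
    }
    return {"bp": bp, "fractions": fractions, "uncovered_bp": total - covered}


def nearest_tss_distance(chrom: str, pos: int, genes: Sequence[Gene]) -> int:
    """Signed strand-aware distance from a 1-based point to the nearest TSS.

    Negative means upstream of the gene (5' of the TSS on the gene's
    strand). Ties in absolute distance resolve to the earlier gene in
    (chrom, tss, id) order.
    """
    candidates = sorted(
        (g for g in genes if g.chrom == chrom),
        key=lambda g: (g.tss, g.gene_id),
    )
    if not candidates:
        raise ValueError(f"no genes on chromosome {chrom}")
    best: int | None = None
    for g in candidates:
        d = pos - g.tss if g.strand == "+" else g.tss - pos
        if best is None or abs(d) < abs(best):
            best = d
    return int(best)
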