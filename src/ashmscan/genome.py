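"""Shared genome data model: genes, track bundles, genome container.

Coordinate conventions: gene bodies, exons and UTRs are 0-based half-open;
the TSS is a 1-based point position. On the + strand the TSS is the first
body base (``start + 1``); on the − strand it is the last (``end``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import Interval

__all__ = ["Gene", "TrackBundle", "GenomeModel"]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int  # 1-based point
    strand: str  # '+' or '-'
    start: int  # 0-based half-open body
    end: int
    exons: tuple[tuple[int, int], ...] = ()  # coding exons, 0-based half-open
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid body interval")
        if not (self.start < self.tss <= self.end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")

    @property
    def body(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, label=self.gene_id)


@dataclass
class TrackBundle:
    """Epigenomic tracks on one coordinate system."""

    k27ac: list[Interval] = field(default_factory=list)
    k4me3: list[Interval] = field(default_factory=list)
    k4me1: list[Interval] = field(default_factory=list)
    tads: list[Interval] = field(default_factory=list)
    compartments: list[Interval] = field(default_factory=list)  # label in {A,B}
    superenhancers: list[Interval] = field(default_factory=list)


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]]
    genes: list[Gene]
    tracks: TrackBundle
    se_gene_ids: list[str] = field(default_factory=list)

    def chrom_length(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(name)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def genes_by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        lengths = dict(self.chromosomes)
        for gene in self.genes:
            if gene.chrom not in lengths:
                raise ValueError(f"gene {gene.gene_id} on unknown chromosome")
            if gene.end > lengths[gene.chrom]:
                raise ValueError(f"gene {gene.gene_id} exceeds chromosome bounds")
        for name in ("k27ac", "k4me3", "k4me1", "tads", "compartments"):
            for iv in getattr(self.tracks, name):
                if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
                    raise ValueError(
                        f"{name} interval {iv.chrom}:{iv.start}-{iv.end} "
                        "exceeds chromosome bounds"
                    )
        # TADs non-overlapping per chromosome
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.tracks.tads:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for prev, nxt in zip(ivs, ivs[1:]):
                if nxt.start < prev.end:
                    raise ValueError("overlapping TADs on one chromosome")
        # compartments partition each chromosome with A/B labels
        comp_by: dict[str, list[Interval]] = {}
        for iv in self.tracks.compartments:
            if iv.label not in ("A", "B"):
                raise ValueError("compartment label must be 'A' or 'B'")
            comp_by.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in comp_by.items():
            ivs.sort(key=lambda iv: iv.start)
            if ivs[0].start != 0 or ivs[-1].end != lengths[chrom]:
                raise ValueError(f"compartments do not span {chrom}")
            for prev, nxt in zip(ivs, ivs[1:]):
                if nxt.start != prev.end:
                    raise ValueError(f"compartment gap/overlap on {chrom}")
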