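"""Synthetic toy genome, paired FL/DHL cohorts and omics matrices.

Everything downstream of raw sequencing is emulated here with planted,
ledgered effects: a toy genome with genes, histone-mark peaks, TADs and
A/B compartments; paired tumor cohorts whose DHL samples carry extra
mutations inside H3K4me3∩H3K27ac footprints, kataegis clusters and
copy-gain events; an expression matrix with a planted correlated TAD gene
pair; and a two-factor proteome intensity design. All randomness flows
from a single seed, and identical configurations reproduce byte-identical
fixture bundles.

Read-level evidence is simulated directly as summaries (the filter
cascade consumes nothing else), and a configurable fraction of candidate
variants is deliberately generated to violate exactly one filter each so
the cascade's ledger can be checked against planted truth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Gene, GenomeModel, TrackBundle
from .intervals import Interval, intersect, merge
from .stats import IntensityMatrix
from .variants import (
    CandidateVariant,
    FilterConfig,
    SampleMutationSet,
    filter_somatic_variants,
)

__all__ = [
    "SizingError",
    "ConfigurationError",
    "KataegisConfig",
    "ReadModel",
    "CohortConfig",
    "build_toy_genome",
    "SimulatedSample",
    "CNVCall",
    "SVCall",
    "SimulatedCohort",
    "simulate_cohort",
    "filtered_cohort",
    "simulate_expression_matrix",
    "simulate_proteome",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


class SizingError(ValueError):
    """A chromosome is too small to host the requested feature counts."""


class ConfigurationError(ValueError):
    """The cohort configuration is inconsistent with the genome."""


MARGIN = 50_000  # gene-free buffer at chromosome ends
_MIN_SLOT = 20_000


def _allocate(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` items over weights."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="mergesort")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def build_toy_genome(
    chromosomes: Sequence[tuple[str, int]] = (("chr1", 10_000_000),),
    n_genes: int = 50,
    n_se_genes: int = 5,
    seed: int = 0,
    tss_peak_fraction: float = 0.6,
    tad_size: int = 1_000_000,
    tad_boundary_gap: int = 20_000,
    compartment_size: int = 1_000_000,
) -> GenomeModel:
    """Build a deterministic toy genome.

    Genes are laid out in per-chromosome slots. H3K4me3 peaks are centered
    on a subset of TSSs (always including the designated super-enhancer
    genes); each SE gene gets a stitchable cluster of high-signal H3K27ac
    peaks overlapping its promoter, while some other genes get weak lone
    K27ac peaks. TADs tile each chromosome with boundary gaps and
    compartments alternate A/B labels partitioning the chromosome.
    """
    chromosomes = [(str(c), int(l)) for c, l in chromosomes]
    if not chromosomes:
        raise SizingError("need at least one chromosome")
    for chrom, length in chromosomes:
        if length < 1_000_000:
            raise SizingError(f"{chrom}: length {length} < 1 Mb")
    if not (0 <= n_se_genes <= n_genes):
        raise ValueError("need 0 <= n_se_genes <= n_genes")
    rng = np.random.default_rng(seed)
    lengths = [l for _, l in chromosomes]
    per_chrom = _allocate(n_genes, lengths) if n_genes else [0] * len(chromosomes)
    genes: list[Gene] = []
    for (chrom, length), n_c in zip(chromosomes, per_chrom):
        if n_c == 0:
            continue
        usable = length - 2 * MARGIN
        slot = usable // n_c
        if slot < _MIN_SLOT:
            raise SizingError(
                f"{chrom}: {n_c} genes need {n_c * _MIN_SLOT} bp, only {usable} usable"
            )
        for i in range(n_c):
            slot_start = MARGIN + i * slot
            start = slot_start + int(rng.integers(0, slot // 8 + 1))
            body_len = int(rng.integers(5_000, max(5_001, min(40_000, slot // 2))))
            end = min(start + body_len, slot_start + slot - 1_000)
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start + 1 if strand == "+" else end
            utr = 200
            if strand == "+":
                utr5, utr3 = (start, start + utr), (end - utr, end)
            else:
                utr5, utr3 = (end - utr, end), (start, start + utr)
            cs, ce = start + utr, end - utr
            span = ce - cs
            exon_len = min(300, max(1, span // 6))
            offsets = [0, (span - exon_len) // 2, span - exon_len]
            exons = tuple(
                (cs + off, cs + off + exon_len) for off in sorted(set(offsets))
            )
            genes.append(
                Gene(
                    gene_id=f"G{len(genes) + 1:04d}",
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    se_idx = (
        sorted(rng.choice(len(genes), size=n_se_genes, replace=False).tolist())
        if n_se_genes and genes
        else []
    )
    se_gene_ids = [genes[i].gene_id for i in se_idx]
    se_set = set(se_gene_ids)
    chrom_len = dict(chromosomes)

    def clip(chrom: str, s: int, e: int) -> tuple[int, int]:
        return max(0, s), min(chrom_len[chrom], e)

    k4me3: list[Interval] = []
    k27ac: list[Interval] = []
    k4me1: list[Interval] = []
    for g in genes:
        t0 = g.tss - 1
        if g.gene_id in se_set:
            # broad promoter mark so the K4me3∩K27ac footprint spans >= 6 kb
            half = int(rng.integers(3_000, 4_000))
            s, e = clip(g.chrom, t0 - half, t0 + half)
            k4me3.append(Interval(g.chrom, s, e))
        elif rng.random() < tss_peak_fraction:
            half = int(rng.integers(400, 1_200))
            s, e = clip(g.chrom, t0 - half, t0 + half)
            k4me3.append(Interval(g.chrom, s, e))
        if g.gene_id in se_set:
            # promoter-overlapping high-signal peak + stitchable flank peaks
            s, e = clip(g.chrom, t0 - 3_000, t0 + int(rng.integers(3_000, 4_000)))
            k27ac.append(Interval(g.chrom, s, e, score=float(rng.uniform(60, 100))))
            cursor = e
            for _ in range(3):
                cursor += int(rng.integers(2_000, 9_000))
                width = int(rng.integers(1_000, 3_000))
                s2, e2 = clip(g.chrom, cursor, cursor + width)
                if e2 - s2 > 100:
                    k27ac.append(
                        Interval(g.chrom, s2, e2, score=float(rng.uniform(30, 80)))
                    )
                cursor += width
        elif rng.random() < 0.4:
            off = int(rng.integers(3_000, 8_000))
            width = int(rng.integers(800, 1_500))
            s, e = clip(g.chrom, t0 + off, t0 + off + width)
            if e - s > 100:
                k27ac.append(Interval(g.chrom, s, e, score=float(rng.uniform(1, 6))))
    for peak in k27ac:
        off = int(rng.integers(500, 1_500))
        s, e = clip(peak.chrom, peak.end + off, peak.end + off + 1_000)
        if e - s > 100:
            k4me1.append(Interval(peak.chrom, s, e))
    tads: list[Interval] = []
    compartments: list[Interval] = []
    for chrom, length in chromosomes:
        n_tads = max(1, length // tad_size)
        size = length // n_tads
        for k in range(n_tads):
            s = k * size + tad_boundary_gap
            e = min((k + 1) * size - tad_boundary_gap, length)
            if e > s:
                tads.append(Interval(chrom, s, e))
        n_blocks = max(2, -(-length // compartment_size))
        block = -(-length // n_blocks)
        for k in range(n_blocks):
            s, e = k * block, min((k + 1) * block, length)
            if e > s:
                compartments.append(
                    Interval(chrom, s, e, label="A" if k % 2 == 0 else "B")
                )
    genome = GenomeModel(
        chromosomes=chromosomes,
        genes=genes,
        tracks=TrackBundle(
            k27ac=k27ac,
            k4me3=k4me3,
            k4me1=k4me1,
            tads=tads,
            compartments=compartments,
        ),
        se_gene_ids=se_gene_ids,
    )
    genome.validate()
    return genome


@dataclass(frozen=True)
class KataegisConfig:
    n_clusters: int = 2
    cluster_size: int = 8
    max_imd: int = 800


@dataclass(frozen=True)
class ReadModel:
    read_length: int = 150
    depth_mean: float = 60.0


@dataclass
class CohortConfig:
    n_patients: int = 8
    samples_per_patient: tuple[str, ...] = ("FL", "DHL")
    background_rate: float = 150.0  # mutations per Mb
    se_promoter_enrichment: float = 1.0  # fold, applied to DHL in footprints
    dhl_load_multiplier: float = 1.1
    kataegis: KataegisConfig = field(default_factory=KataegisConfig)
    kataegis_stages: tuple[str, ...] = ("DHL",)
    af_model: dict = field(
        default_factory=lambda: {"FL": (0.35, 0.06), "DHL": (0.45, 0.06)}
    )
    sv_af_model: dict = field(
        default_factory=lambda: {"FL": (0.15, 0.04), "DHL": (0.45, 0.06)}
    )
    gain_probability_dhl: float = 0.0
    read_model: ReadModel = field(default_factory=ReadModel)
    violation_fraction: float = 0.10
    insertion_fraction: float = 0.04
    deletion_fraction: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.background_rate < 0 or self.se_promoter_enrichment < 1:
            raise ValueError("rates must be >= 0 and enrichment >= 1")
        if not (0 <= self.gain_probability_dhl <= 1):
            raise ValueError("gain_probability_dhl must lie in [0, 1]")
        if not (0 <= self.violation_fraction < 1):
            raise ValueError("violation_fraction must lie in [0, 1)")
        for stage in self.samples_per_patient:
            if stage not in ("FL", "DHL"):
                raise ValueError(f"unknown stage {stage!r}")


@dataclass
class SimulatedSample:
    patient_id: str
    stage: str
    sample_id: str
    candidates: list[CandidateVariant]
    has_matched_normal: bool = True


@dataclass(frozen=True)
class CNVCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str  # 'gain' or 'loss'


@dataclass(frozen=True)
class SVCall:
    sample_id: str
    patient_id: str
    stage: str
    name: str
    supporting_reads: int
    coverage_locus1: int
    coverage_locus2: int


@dataclass
class SimulatedCohort:
    samples: list[SimulatedSample]
    cnv_calls: list[CNVCall]
    sv_calls: list[SVCall]
    low_complexity_mask: list[Interval]
    truth: dict

    def filter_config(self, **overrides) -> FilterConfig:
        return FilterConfig(low_complexity_mask=self.low_complexity_mask, **overrides)


_VIOLATION_KINDS = (
    "posterior",
    "normal_alt",
    "low_complexity",
    "hq_support",
    "strand_bias",
    "allele_frequency",
    "normal_depth",
    "read_edge",
)

_BASES = "ACGT"


def _in_any(pos: int, regions: Sequence[tuple[str, int, int]], chrom: str) -> bool:
    return any(c == chrom and s <= pos - 1 < e for c, s, e in regions)


def _draw_alleles(rng, kind: str) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    if kind == "snv":
        alt = _BASES[rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
        return ref, alt
    length = int(rng.integers(1, 11))
    extra = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    if kind == "ins":
        return ref, ref + extra
    return ref + extra, ref


def _clean_evidence(rng, stage: str, cfg: CohortConfig) -> dict:
    """Evidence summaries guaranteed to pass every cascade filter."""
    depth = max(30, int(rng.poisson(cfg.read_model.depth_mean)))
    mu, sd = cfg.af_model[stage]
    af = float(np.clip(rng.normal(mu, sd), 0.25, 0.95))
    alt = max(6, int(round(af * depth)))
    alt = min(alt, depth)
    af = alt / depth
    while True:
        plus = int(rng.binomial(alt, 0.5))
        if max(plus, alt - plus) / alt < 0.95:
            break
    edges = rng.uniform(0.0, 0.5, size=alt)
    if np.all(edges < 0.3):
        edges[int(rng.integers(0, alt))] = float(rng.uniform(0.3, 0.5))
    return dict(
        tumor_depth=depth,
        tumor_alt=alt,
        tumor_alt_hq=alt,
        alt_plus=plus,
        alt_minus=alt - plus,
        edge_fractions=tuple(np.round(edges, 4)),
        af=af,
        normal_depth=max(20, int(rng.poisson(cfg.read_model.depth_mean))),
        normal_alt=int(rng.random() < 0.1),
        posterior_p=float(10.0 ** -rng.uniform(6.5, 12.0)),
    )


def _violated_evidence(rng, stage: str, cfg: CohortConfig, kind: str) -> dict:
    ev = _clean_evidence(rng, stage, cfg)
    if kind == "posterior":
        ev["posterior_p"] = float(rng.uniform(1e-5, 1e-2))
    elif kind == "normal_alt":
        ev["normal_alt"] = int(rng.integers(2, 6))
    elif kind == "hq_support":
        ev["tumor_alt_hq"] = int(rng.integers(0, 5))
    elif kind == "strand_bias":
        alt = max(10, ev["tumor_alt"])
        ev.update(
            tumor_depth=max(alt, ev["tumor_depth"]),
            tumor_alt=alt,
            tumor_alt_hq=alt,
            alt_plus=alt,
            alt_minus=0,
        )
        ev["af"] = ev["tumor_alt"] / ev["tumor_depth"]
        edges = rng.uniform(0.0, 0.5, size=alt)
        edges[0] = 0.45
        ev["edge_fractions"] = tuple(np.round(edges, 4))
    elif kind == "allele_frequency":
        depth = 60
        alt = int(rng.integers(7, 11))  # af in (0.116, 0.167): below default cut
        while True:
            plus = int(rng.binomial(alt, 0.5))
            if max(plus, alt - plus) / alt < 0.95:
                break
        edges = rng.uniform(0.0, 0.5, size=alt)
        edges[0] = 0.45
        ev.update(
            tumor_depth=depth,
            tumor_alt=alt,
            tumor_alt_hq=alt,
            alt_plus=plus,
            alt_minus=alt - plus,
            af=alt / depth,
            edge_fractions=tuple(np.round(edges, 4)),
        )
    elif kind == "normal_depth":
        ev["normal_depth"] = int(rng.integers(0, 15))
    elif kind == "read_edge":
        edges = rng.uniform(0.0, 0.24, size=ev["tumor_alt"])
        ev["edge_fractions"] = tuple(np.round(edges, 4))
    elif kind == "low_complexity":
        pass  # position carries the violation
    else:
        raise ValueError(kind)
    return ev


def simulate_cohort(genome: GenomeModel, config: CohortConfig) -> SimulatedCohort:
    """Simulate candidate variant calls, CNV and SV calls for a paired
    FL/DHL cohort, with a complete planted-truth ledger."""
    rng = np.random.default_rng(config.seed)
    tracks = genome.tracks
    footprints = intersect(tracks.k4me3, tracks.k27ac)
    if config.se_promoter_enrichment > 1 and not footprints:
        raise ConfigurationError(
            "se_promoter_enrichment > 1 but the genome has no "
            "H3K4me3∩H3K27ac footprints"
        )
    footprint_tuples = [(iv.chrom, iv.start, iv.end) for iv in footprints]
    mask = [
        Interval(chrom, 10_000, 15_000)
        for chrom, length in genome.chromosomes
        if length > 40_000
    ]
    mask_tuples = [(iv.chrom, iv.start, iv.end) for iv in mask]
    buffer = max(1_500, 2 * config.kataegis.max_imd)
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lens = np.array([l for _, l in genome.chromosomes], dtype=float)
    chrom_weights = chrom_lens / chrom_lens.sum()

    # gain locus: the TAD hosting the first SE gene, else the first TAD
    gain_locus: tuple[str, int, int] | None = None
    if tracks.tads:
        anchor = None
        if genome.se_gene_ids:
            anchor = genome.genes_by_id()[genome.se_gene_ids[0]]
        for tad in tracks.tads:
            if anchor is None or (
                tad.chrom == anchor.chrom and tad.contains_point(anchor.tss)
            ):
                gain_locus = (tad.chrom, tad.start, tad.end)
                break
        if gain_locus is None:
            tad = tracks.tads[0]
            gain_locus = (tad.chrom, tad.start, tad.end)

    samples: list[SimulatedSample] = []
    cnv_calls: list[CNVCall] = []
    sv_calls: list[SVCall] = []
    truth: dict = {
        "enriched_regions": [list(t) for t in footprint_tuples],
        "kataegis": {},
        "violations": {},
        "gain_samples": [],
        "gain_locus": list(gain_locus) if gain_locus else None,
        "sv_af": {},
    }

    def sample_ids(patient: str) -> list[str]:
        ids, seen = [], {}
        for stage in config.samples_per_patient:
            seen[stage] = seen.get(stage, 0) + 1
            suffix = string.ascii_uppercase[seen[stage] - 1] if seen[stage] > 1 else ""
            ids.append(f"{patient}{suffix}-{stage}")
        return ids

    for p in range(1, config.n_patients + 1):
        patient = f"P{p}"
        ids = sample_ids(patient)
        for stage, sample_id in zip(config.samples_per_patient, ids):
            rate_bp = config.background_rate / 1e6
            if stage == "DHL":
                rate_bp *= config.dhl_load_multiplier
            positions: list[tuple[str, int]] = []
            for (chrom, length) in genome.chromosomes:
                n_bg = rng.poisson(rate_bp * length)
                pos = rng.integers(1, length + 1, size=n_bg)
                positions.extend((chrom, int(x)) for x in pos)
            if stage == "DHL" and config.se_promoter_enrichment > 1:
                extra_rate = (config.se_promoter_enrichment - 1) * rate_bp
                for chrom, s, e in footprint_tuples:
                    n_extra = rng.poisson(extra_rate * (e - s))
                    pos = rng.integers(s + 1, e + 1, size=n_extra)
                    positions.extend((chrom, int(x)) for x in pos)
            # planted kataegis clusters, with an exclusion buffer so that
            # downstream detection recovers the planted interval exactly
            cluster_regions: list[tuple[str, int, int]] = []
            clusters: list[list[tuple[str, int]]] = []
            if stage in config.kataegis_stages and config.kataegis.n_clusters:
                kat = config.kataegis
                span_max = kat.cluster_size * kat.max_imd
                for _ in range(kat.n_clusters):
                    for _try in range(200):
                        ci = rng.choice(len(chrom_names), p=chrom_weights)
                        chrom = chrom_names[ci]
                        length = genome.chromosomes[ci][1]
                        lo = MARGIN + buffer
                        hi = length - MARGIN - span_max - buffer
                        if hi <= lo:
                            continue
                        first = int(rng.integers(lo, hi))
                        gaps = rng.integers(50, kat.max_imd + 1, size=kat.cluster_size - 1)
                        pos = [first]
                        for gp in gaps:
                            pos.append(pos[-1] + int(gp))
                        region = (chrom, pos[0] - buffer, pos[-1] + buffer)
                        near_other = any(
                            c == chrom and s < region[2] and region[1] < e
                            for c, s, e in cluster_regions
                        )
                        near_footprint = any(
                            c == chrom
                            and s - buffer < region[2]
                            and region[1] < e + buffer
                            for c, s, e in footprint_tuples
                        )
                        in_mask = any(
                            c == chrom and s < region[2] and region[1] < e
                            for c, s, e in mask_tuples
                        )
                        if not (near_other or near_footprint or in_mask):
                            cluster_regions.append(region)
                            clusters.append([(chrom, x) for x in pos])
                            break
                    else:
                        raise ConfigurationError(
                            "could not place a kataegis cluster; genome too crowded"
                        )
            # scrub background from cluster buffers and the mask
            positions = [
                (c, x)
                for c, x in positions
                if not _in_any(x, cluster_regions, c) and not _in_any(x, mask_tuples, c)
            ]
            for cluster in clusters:
                positions.extend(cluster)
            truth["kataegis"][sample_id] = [
                [cl[0][0], cl[0][1] - 1, cl[-1][1]] for cl in clusters
            ]
            # clean candidates
            candidates = [
                CandidateVariant(
                    chrom=c,
                    pos=x,
                    **dict(
                        zip(
                            ("ref", "alt"),
                            _draw_alleles(
                                rng,
                                "ins"
                                if (u := rng.random()) < config.insertion_fraction
                                else "del"
                                if u < config.insertion_fraction + config.deletion_fraction
                                else "snv",
                            ),
                        )
                    ),
                    **_clean_evidence(rng, stage, config),
                )
                for c, x in positions
            ]
            # planted filter violations (one target filter each)
            n_viol = int(round(config.violation_fraction * len(candidates)))
            kinds = [
                k
                for k in _VIOLATION_KINDS
                if k != "low_complexity" or mask_tuples
            ]
            viol_counts: dict[str, int] = {}
            for v_idx in range(n_viol):
                kind = kinds[v_idx % len(kinds)]
                if kind == "low_complexity":
                    chrom, s, e = mask_tuples[int(rng.integers(0, len(mask_tuples)))]
                    pos_v = int(rng.integers(s + 1, e + 1))
                else:
                    while True:
                        ci = rng.choice(len(chrom_names), p=chrom_weights)
                        chrom = chrom_names[ci]
                        length = genome.chromosomes[ci][1]
                        pos_v = int(rng.integers(1, length + 1))
                        if not _in_any(pos_v, mask_tuples, chrom) and not _in_any(
                            pos_v, cluster_regions, chrom
                        ):
                            break
                ref, alt = _draw_alleles(rng, "snv")
                candidates.append(
                    CandidateVariant(
                        chrom=chrom,
                        pos=pos_v,
                        ref=ref,
                        alt=alt,
                        **_violated_evidence(rng, stage, config, kind),
                    )
                )
                viol_counts[kind] = viol_counts.get(kind, 0) + 1
            truth["violations"][sample_id] = viol_counts
            candidates.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
            samples.append(
                SimulatedSample(
                    patient_id=patient,
                    stage=stage,
                    sample_id=sample_id,
                    candidates=candidates,
                )
            )
            # CNV gain: DHL-only planted event
            if (
                stage == "DHL"
                and gain_locus is not None
                and rng.random() < config.gain_probability_dhl
            ):
                cnv_calls.append(CNVCall(sample_id, *gain_locus, kind="gain"))
                truth["gain_samples"].append(sample_id)
            # one SV per sample with stage-dependent allele frequency
            mu, sd = config.sv_af_model[stage]
            af = float(np.clip(rng.normal(mu, sd), 0.02, 0.95))
            cov1 = max(10, int(rng.poisson(config.read_model.depth_mean)))
            cov2 = max(10, int(rng.poisson(config.read_model.depth_mean)))
            support = max(1, int(round(af * (cov1 + cov2) / 2)))
            sv_calls.append(
                SVCall(sample_id, patient, stage, "BCL2-IGH", support, cov1, cov2)
            )
            truth["sv_af"][sample_id] = support / ((cov1 + cov2) / 2)
    return SimulatedCohort(
        samples=samples,
        cnv_calls=cnv_calls,
        sv_calls=sv_calls,
        low_complexity_mask=mask,
        truth=truth,
    )


def filtered_cohort(
    sim: SimulatedCohort, filter_config: FilterConfig | None = None
) -> list[SampleMutationSet]:
    """Run the filter cascade on every simulated sample."""
    config = filter_config or FilterConfig(
        low_complexity_mask=sim.low_complexity_mask
    )
    out = []
    for sample in sim.samples:
        ledger = filter_somatic_variants(
            sample.candidates,
            config,
            has_matched_normal=sample.has_matched_normal,
            sample_id=sample.sample_id,
        )
        out.append(
            SampleMutationSet(
                patient_id=sample.patient_id,
                stage=sample.stage,
                sample_id=sample.sample_id,
                variants=ledger.kept,
            )
        )
    return out


def simulate_expression_matrix(
    genome: GenomeModel,
    n_cell_lines: int = 11,
    planted_pair: tuple[str, str] | None = None,
    rho_target: float = -0.9,
    seed: int = 0,
    noise_sd: float = 1.0,
    tolerance: float = 0.12,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Gene x cell-line expression with an optionally planted correlated
    pair whose empirical Spearman lands within ``tolerance`` of target and
    whose mean expression sits in the top quartile."""
    if not -1 <= rho_target <= 1:
        raise ValueError("rho_target must lie in [-1, 1]")
    gene_ids = [g.gene_id for g in genome.genes]
    if planted_pair is not None:
        for gid in planted_pair:
            if gid not in gene_ids:
                raise KeyError(f"planted gene {gid} not in genome")
    rng = np.random.default_rng(seed)
    cells = [f"CL{i + 1:02d}" for i in range(n_cell_lines)]
    means = rng.uniform(2.0, 10.0, size=len(gene_ids))
    values = means[:, None] + rng.normal(0.0, noise_sd, size=(len(gene_ids), n_cell_lines))
    df = pd.DataFrame(values, index=gene_ids, columns=cells)
    if planted_pair is not None:
        a, b = planted_pair
        pearson = 2.0 * np.sin(np.pi * rho_target / 6.0)
        cov = np.array([[1.0, pearson], [pearson, 1.0]])
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        for _ in range(max_tries):
            z = chol @ rng.normal(size=(2, n_cell_lines))
            rho_hat = float(sps.spearmanr(z[0], z[1]).statistic)
            if abs(rho_hat - rho_target) <= tolerance:
                break
        else:
            raise RuntimeError("could not hit the Spearman target; widen tolerance")
        planted_means = rng.uniform(11.0, 12.0, size=2)
        df.loc[a] = planted_means[0] + noise_sd * z[0]
        df.loc[b] = planted_means[1] + noise_sd * z[1]
    return df


def simulate_proteome(
    n_proteins: int = 200,
    n_replicates: int = 3,
    effect_set: dict | None = None,
    seed: int = 0,
    baseline: tuple[float, float] = (20.0, 2.0),
    noise_sd: float = 0.3,
) -> IntensityMatrix:
    """Two-factor (genotype x OPP label) proteome intensities.

    ``effect_set`` maps protein id -> (direction, magnitude); effect
    proteins shift by direction*magnitude only in the (ALT, OPP+) cell.
    Annotation labels direction −1 proteins TSP and +1 oncoprotein, with a
    sprinkling of both classes over null proteins.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per factor cell")
    effect_set = effect_set or {}
    rng = np.random.default_rng(seed)
    proteins = [f"PR{i + 1:04d}" for i in range(n_proteins)]
    unknown = set(effect_set) - set(proteins)
    if unknown:
        raise KeyError(f"effect proteins not simulated: {sorted(unknown)[:5]}")
    columns, genotype, label = [], [], []
    for g in ("WT", "ALT"):
        for l in ("OPP+", "OPP-"):
            for r in range(1, n_replicates + 1):
                columns.append(f"{g}.{l}.{r}")
                genotype.append(g)
                label.append(l)
    base = rng.normal(baseline[0], baseline[1], size=n_proteins)
    values = base[:, None] + rng.normal(0.0, noise_sd, size=(n_proteins, len(columns)))
    df = pd.DataFrame(values, index=proteins, columns=columns)
    alt_opp = [
        c for c, g, l in zip(columns, genotype, label) if g == "ALT" and l == "OPP+"
    ]
    for protein, (direction, magnitude) in effect_set.items():
        df.loc[protein, alt_opp] += direction * magnitude
    annotation = pd.Series("none", index=proteins)
    for protein, (direction, _) in effect_set.items():
        annotation[protein] = "TSP" if direction < 0 else "oncoprotein"
    nulls = [p for p in proteins if p not in effect_set]
    for i, protein in enumerate(nulls):
        if i % 10 == 0:
            annotation[protein] = "TSP"
        elif i % 10 == 5:
            annotation[protein] = "oncoprotein"
    return IntensityMatrix(
        values=df,
        genotype=pd.Series(genotype, index=columns),
        label=pd.Series(label, index=columns),
        annotation=annotation,
    )


def write_fixture_bundle(
    outdir,
    genome: GenomeModel,
    cohort: SimulatedCohort | None = None,
    expression: pd.DataFrame | None = None,
    proteome: IntensityMatrix | None = None,
) -> list[str]:
    """Write the genome/cohort/matrices as a plain-text fixture bundle.

    Returns the list of file names written. All writers are deterministic,
    so equal inputs produce byte-identical bundles.
    """
    from . import io as aio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def mark(name: str) -> Path:
        written.append(name)
        return outdir / name

    with open(mark("chromosomes.tsv"), "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
    aio.write_genes_tsv(mark("genome.tsv"), genome.genes)
    aio.write_bed(mark("h3k27ac.bed"), genome.tracks.k27ac, columns=6)
    aio.write_bed(mark("h3k4me3.bed"), genome.tracks.k4me3, columns=3)
    aio.write_bed(mark("h3k4me1.bed"), genome.tracks.k4me1, columns=3)
    aio.write_bed(mark("tads.bed"), genome.tracks.tads, columns=3)
    aio.write_bed(mark("compartments.bed"), genome.tracks.compartments, columns=4)
    with open(mark("se_genes.txt"), "w") as fh:
        for gid in genome.se_gene_ids:
            fh.write(gid + "\n")
    if cohort is not None:
        aio.write_bed(mark("low_complexity_mask.bed"), cohort.low_complexity_mask)
        with open(mark("samples.tsv"), "w") as fh:
            fh.write("sample_id\tpatient_id\tstage\thas_matched_normal\n")
            for s in cohort.samples:
                fh.write(
                    f"{s.sample_id}\t{s.patient_id}\t{s.stage}\t"
                    f"{int(s.has_matched_normal)}\n"
                )
        for s in cohort.samples:
            aio.write_variants_tsv(mark(f"variants.{s.sample_id}.tsv"), s.candidates)
        with open(mark("cnv_calls.tsv"), "w") as fh:
            fh.write("sample_id\tchrom\tstart\tend\tkind\n")
            for c in cohort.cnv_calls:
                fh.write(f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\n")
        with open(mark("sv_calls.tsv"), "w") as fh:
            fh.write(
                "sample_id\tpatient_id\tstage\tname\tsupporting_reads\t"
                "coverage_locus1\tcoverage_locus2\n"
            )
            for v in cohort.sv_calls:
                fh.write(
                    f"{v.sample_id}\t{v.patient_id}\t{v.stage}\t{v.name}\t"
                    f"{v.supporting_reads}\t{v.coverage_locus1}\t{v.coverage_locus2}\n"
                )
        aio.write_truth_json(mark("planted_truth.json"), cohort.truth)
    if expression is not None:
        aio.write_expression_tsv(mark("expression.tsv"), expression)
    if proteome is not None:
        aio.write_proteome_tsv(mark("proteome.tsv"), proteome)
    return written


def read_fixture_bundle(outdir):
    """Reconstruct (genome, cohort, expression, proteome) from a bundle.

    Missing optional pieces come back as None. Peak scores survive via the
    BED6 k27ac track; k4me3 TSS-subset membership is implicit in the file.
    """
    from . import io as aio

    outdir = Path(outdir)
    chroms: list[tuple[str, int]] = []
    with open(outdir / "chromosomes.tsv") as fh:
        next(fh)
        for line in fh:
            chrom, length = line.rstrip("\n").split("\t")
            chroms.append((chrom, int(length)))
    genes = aio.read_genes_tsv(outdir / "genome.tsv")
    se_gene_ids = []
    if (outdir / "se_genes.txt").exists():
        se_gene_ids = (outdir / "se_genes.txt").read_text().split()
    tracks = TrackBundle(
        k27ac=aio.read_bed(outdir / "h3k27ac.bed"),
        k4me3=aio.read_bed(outdir / "h3k4me3.bed"),
        k4me1=aio.read_bed(outdir / "h3k4me1.bed"),
        tads=aio.read_bed(outdir / "tads.bed"),
        compartments=aio.read_bed(outdir / "compartments.bed"),
    )
    genome = GenomeModel(
        chromosomes=chroms, genes=genes, tracks=tracks, se_gene_ids=se_gene_ids
    )
    cohort = None
    if (outdir / "samples.tsv").exists():
        samples = []
        with open(outdir / "samples.tsv") as fh:
            next(fh)
            for line in fh:
                sample_id, patient_id, stage, matched = line.rstrip("\n").split("\t")
                samples.append(
                    SimulatedSample(
                        patient_id=patient_id,
                        stage=stage,
                        sample_id=sample_id,
                        candidates=aio.read_variants_tsv(
                            outdir / f"variants.{sample_id}.tsv"
                        ),
                        has_matched_normal=bool(int(matched)),
                    )
                )
        cnv_calls = []
        with open(outdir / "cnv_calls.tsv") as fh:
            next(fh)
            for line in fh:
                sample_id, chrom, start, end, kind = line.rstrip("\n").split("\t")
                cnv_calls.append(CNVCall(sample_id, chrom, int(start), int(end), kind))
        sv_calls = []
        with open(outdir / "sv_calls.tsv") as fh:
            next(fh)
            for line in fh:
                sid, pid, stage, name, sup, c1, c2 = line.rstrip("\n").split("\t")
                sv_calls.append(SVCall(sid, pid, stage, name, int(sup), int(c1), int(c2)))
        cohort = SimulatedCohort(
            samples=samples,
            cnv_calls=cnv_calls,
            sv_calls=sv_calls,
            low_complexity_mask=aio.read_bed(outdir / "low_complexity_mask.bed"),
            truth=aio.read_truth_json(outdir / "planted_truth.json"),
        )
    expression = (
        aio.read_expression_tsv(outdir / "expression.tsv")
        if (outdir / "expression.tsv").exists()
        else None
    )
    proteome = (
        aio.read_proteome_tsv(outdir / "proteome.tsv")
        if (outdir / "proteome.tsv").exists()
        else None
    )
    return genome, cohort, expression, proteome
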