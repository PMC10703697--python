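"""Enhancer-retargeting candidate prediction.

Enumerates gene pairs whose promoters share a TAD, scores each pair on
three ranked lists (mean expression of gene A, mean expression of gene B,
Spearman correlation between them) and aggregates the ranks into a
central-limit z / p per pair: for average rank R over m lists of size n,

    z = (R - (n + 1) / 2) / sqrt((n^2 - 1) / (12 m)),   p = Phi(z)

so small p flags pairs ranked consistently strongly. The default
orientation looks for highly expressed, negatively correlated pairs; a
positive-correlation and a two-sided mode are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Gene
from .intervals import Interval

__all__ = [
    "enumerate_tad_gene_pairs",
    "spearman_rho",
    "rank_lists",
    "rank_aggregation_pvalue",
    "annotate_hypermutated_pairs",
    "rank_er_candidates",
]


def enumerate_tad_gene_pairs(
    genes: Sequence[Gene], tads: Sequence[Interval]
) -> list[tuple[str, str, int]]:
    """All unordered gene pairs whose promoters (TSSs) share a TAD.

    Returns ``(gene_a, gene_b, tad_index)`` with A before B in
    (chrom, tss, id) order; genes outside every TAD are dropped.
    """
    pairs: list[tuple[str, str, int]] = []
    for t_idx, tad in enumerate(tads):
        members = sorted(
            (
                g
                for g in genes
                if g.chrom == tad.chrom and tad.contains_point(g.tss)
            ),
            key=lambda g: (g.chrom, g.tss, g.gene_id),
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i].gene_id, members[j].gene_id, t_idx))
    return pairs


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_lists(values: np.ndarray, directions: Sequence[str]) -> np.ndarray:
    """Convert an items x lists value matrix to 1..n ranks per list.

    ``directions[j]`` is 'high' (large value = rank 1) or 'low' (small
    value = rank 1). Ties receive average ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(directions):
        raise ValueError("values must be items x lists with one direction per list")
    ranks = np.empty_like(values)
    for j, direction in enumerate(directions):
        col = values[:, j]
        if direction == "high":
            ranks[:, j] = sps.rankdata(-col)
        elif direction == "low":
            ranks[:, j] = sps.rankdata(col)
        else:
            raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")
    return ranks


def rank_aggregation_pvalue(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-limit aggregation of an items x lists rank matrix.

    Ranks run 1..n with 1 the strongest in each list's direction. Returns
    per-item ``(z, p)`` with ``p = Phi(z)``: small p means consistently
    strong ranks.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim != 2:
        raise ValueError("ranks must be an items x lists matrix")
    n, m = ranks.shape
    if n < 2 or m < 1:
        raise ValueError("need >= 2 items and >= 1 list")
    mean_rank = ranks.mean(axis=1)
    sd = np.sqrt((n**2 - 1) / (12.0 * m))
    z = (mean_rank - (n + 1) / 2.0) / sd
    return z, sps.norm.cdf(z)


def annotate_hypermutated_pairs(
    pairs: Sequence[tuple[str, str, int]],
    genes_by_id: dict[str, Gene],
    hypermutated_loci: Iterable[Interval],
    promoter_window: int = 2000,
) -> list[bool]:
    """Flag pairs where either gene's promoter window or body overlaps a
    hypermutated locus."""
    loci = list(hypermutated_loci)

    def gene_hit(gene: Gene) -> bool:
        prom_start = max(0, gene.tss - 1 - promoter_window)
        prom_end = gene.tss + promoter_window
        for locus in loci:
            if locus.chrom != gene.chrom:
                continue
            if locus.start < prom_end and prom_start < locus.end:
                return True
            if locus.start < gene.end and gene.start < locus.end:
                return True
        return False

    hit_cache = {gid: gene_hit(g) for gid, g in genes_by_id.items()}
    return [hit_cache[a] or hit_cache[b] for a, b, _ in pairs]


@dataclass
class ERCandidateTable:
    table: pd.DataFrame  # all pairs, sorted by aggregate p ascending

    @property
    def hypermutated(self) -> pd.DataFrame:
        return self.table[self.table["hypermutated"]]


def rank_er_candidates(
    pairs: Sequence[tuple[str, str, int]],
    expression: pd.DataFrame,
    genes_by_id: dict[str, Gene],
    hypermutated_loci: Iterable[Interval] = (),
    correlation_direction: str = "negative",
    promoter_window: int = 2000,
) -> ERCandidateTable:
    """Score and rank TAD gene pairs as enhancer-retargeting candidates.

    ``expression`` is a genes x cell-lines matrix (already normalized;
    missing values are refused). Genes with zero expression variance are
    excluded from the pair universe. Lists: mean expression of A and B
    (high = strong) and Spearman rho oriented by
    ``correlation_direction`` in {'negative', 'positive', 'two-sided'}
    ('two-sided' ranks by |rho|, largest first).
    """
    if expression.isna().any().any():
        raise ValueError("missing expression values refused; no imputation")
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 cell lines for correlation")
    variances = expression.var(axis=1)
    expressed = set(variances.index[variances > 0])
    usable = [
        (a, b, t)
        for a, b, t in pairs
        if a in expressed and b in expressed
    ]
    missing = {
        g for a, b, _ in pairs for g in (a, b) if g not in expression.index
    }
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]}")
    if not usable:
        raise ValueError("no scoreable pairs (all genes constant or outside TADs)")
    mean_expr = expression.mean(axis=1)
    rows = []
    for a, b, t in usable:
        rho = spearman_rho(expression.loc[a].to_numpy(), expression.loc[b].to_numpy())
        rows.append((a, b, t, float(mean_expr[a]), float(mean_expr[b]), rho))
    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "tad", "mean_a", "mean_b", "rho"]
    )
    if correlation_direction == "negative":
        rho_col, rho_dir = table["rho"].to_numpy(), "low"
    elif correlation_direction == "positive":
        rho_col, rho_dir = table["rho"].to_numpy(), "high"
    elif correlation_direction == "two-sided":
        rho_col, rho_dir = np.abs(table["rho"].to_numpy()), "high"
    else:
        raise ValueError("correlation_direction must be negative/positive/two-sided")
    values = np.column_stack(
        [table["mean_a"].to_numpy(), table["mean_b"].to_numpy(), rho_col]
    )
    ranks = rank_lists(values, ["high", "high", rho_dir])
    if len(usable) == 1:
        # a lone pair has no ranking information: central z by convention
        z, p = np.zeros(1), np.full(1, 0.5)
    else:
        z, p = rank_aggregation_pvalue(ranks)
    table["rank_a"], table["rank_b"], table["rank_rho"] = (
        ranks[:, 0],
        ranks[:, 1],
        ranks[:, 2],
    )
    table["z"], table["p"] = z, p
    table["hypermutated"] = annotate_hypermutated_pairs(
        usable, genes_by_id, hypermutated_loci, promoter_window
    )
    table = table.sort_values(
        ["p", "gene_a", "gene_b"], kind="mergesort"
    ).reset_index(drop=True)
    return ERCandidateTable(table=table)
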