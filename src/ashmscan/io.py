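"""Plain-text readers and writers for the fixture-bundle dialects.

All writers emit canonical formatting (tab-separated, ``%.6g`` floats) so
that write -> read -> write round-trips are byte-identical. BED files are
0-based half-open; point positions in TSV files are 1-based.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import Gene
from .intervals import Interval
from .stats import IntensityMatrix
from .variants import CandidateVariant

__all__ = [
    "write_bed",
    "read_bed",
    "write_genes_tsv",
    "read_genes_tsv",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_proteome_tsv",
    "read_proteome_tsv",
    "read_vcf_candidates",
]


def _fmt(x: float) -> str:
    # repr is the shortest exactly round-tripping decimal form
    return repr(float(x))


def write_bed(path, intervals: Iterable[Interval], columns: int = 3) -> None:
    """Write BED3 (coords), BED4 (+name) or BED6 (+name, score, strand)."""
    if columns not in (3, 4, 6):
        raise ValueError("columns must be 3, 4 or 6")
    with open(path, "w", newline="") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if columns >= 4:
                fields.append(iv.label if iv.label is not None else ".")
            if columns == 6:
                fields.append(_fmt(iv.score) if iv.score is not None else "0")
                fields.append(".")
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = (
                float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            )
            out.append(Interval(chrom, start, end, score=score, label=label))
    return out


_GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "tss",
    "strand",
    "start",
    "end",
    "exons",
    "utr5",
    "utr3",
]


def _iv_pair_str(iv: tuple[int, int] | None) -> str:
    return f"{iv[0]}-{iv[1]}" if iv is not None else "."


def _parse_iv_pair(text: str) -> tuple[int, int] | None:
    if text == ".":
        return None
    a, b = text.split("-")
    return int(a), int(b)


def write_genes_tsv(path, genes: Sequence[Gene]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons) or "."
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.chrom,
                        str(g.tss),
                        g.strand,
                        str(g.start),
                        str(g.end),
                        exons,
                        _iv_pair_str(g.utr5),
                        _iv_pair_str(g.utr3),
                    ]
                )
                + "\n"
            )


def read_genes_tsv(path) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            exons = (
                tuple(
                    (int(a), int(b))
                    for a, b in (p.split("-") for p in row["exons"].split(","))
                )
                if row.get("exons") and row["exons"] != "."
                else ()
            )
            genes.append(
                Gene(
                    gene_id=row["gene_id"],
                    chrom=row["chrom"],
                    tss=int(row["tss"]),
                    strand=row["strand"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    exons=exons,
                    utr5=_parse_iv_pair(row.get("utr5", ".")),
                    utr3=_parse_iv_pair(row.get("utr3", ".")),
                )
            )
    return genes


_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "t_depth",
    "t_alt",
    "t_alt_hq",
    "alt_plus",
    "alt_minus",
    "edge_fracs",
    "af",
    "n_depth",
    "n_alt",
    "posterior_p",
]


def write_variants_tsv(path, variants: Iterable[CandidateVariant]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        str(v.tumor_depth),
                        str(v.tumor_alt),
                        str(v.tumor_alt_hq),
                        str(v.alt_plus),
                        str(v.alt_minus),
                        ",".join(format(f, ".4f") for f in v.edge_fractions) or ".",
                        _fmt(v.af),
                        str(v.normal_depth) if v.normal_depth is not None else ".",
                        str(v.normal_alt) if v.normal_alt is not None else ".",
                        _fmt(v.posterior_p) if v.posterior_p is not None else ".",
                    ]
                )
                + "\n"
            )


def read_variants_tsv(path) -> list[CandidateVariant]:
    out: list[CandidateVariant] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_VARIANT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        for row in reader:
            edges = (
                tuple(float(f) for f in row["edge_fracs"].split(","))
                if row["edge_fracs"] != "."
                else ()
            )
            out.append(
                CandidateVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    tumor_depth=int(row["t_depth"]),
                    tumor_alt=int(row["t_alt"]),
                    tumor_alt_hq=int(row["t_alt_hq"]),
                    alt_plus=int(row["alt_plus"]),
                    alt_minus=int(row["alt_minus"]),
                    edge_fractions=edges,
                    af=float(row["af"]),
                    normal_depth=int(row["n_depth"]) if row["n_depth"] != "." else None,
                    normal_alt=int(row["n_alt"]) if row["n_alt"] != "." else None,
                    posterior_p=float(row["posterior_p"])
                    if row["posterior_p"] != "."
                    else None,
                )
            )
    return out


def write_expression_tsv(path, expression: pd.DataFrame) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("gene\t" + "\t".join(map(str, expression.columns)) + "\n")
        for gene, row in expression.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(format(x, ".6f") for x in row) + "\n")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return df


def write_proteome_tsv(path, matrix: IntensityMatrix) -> None:
    """Proteins x samples with '#genotype'/'#label' factor header rows and
    an optional '#annotation' trailing column block."""
    cols = list(matrix.values.columns)
    with open(path, "w", newline="") as fh:
        fh.write("#genotype\t" + "\t".join(matrix.genotype[c] for c in cols) + "\n")
        fh.write("#label\t" + "\t".join(matrix.label[c] for c in cols) + "\n")
        header = "protein\t" + "\t".join(map(str, cols))
        if matrix.annotation is not None:
            header += "\tannotation"
        fh.write(header + "\n")
        for protein, row in matrix.values.iterrows():
            line = str(protein) + "\t" + "\t".join(format(x, ".6f") for x in row)
            if matrix.annotation is not None:
                line += "\t" + str(matrix.annotation.get(protein, "none"))
            fh.write(line + "\n")


def read_proteome_tsv(path) -> IntensityMatrix:
    with open(path) as fh:
        genotype_line = fh.readline().rstrip("\n").split("\t")
        label_line = fh.readline().rstrip("\n").split("\t")
        if genotype_line[0] != "#genotype" or label_line[0] != "#label":
            raise ValueError("proteome file lacks factor header rows")
        body = pd.read_csv(fh, sep="\t", index_col=0)
    annotation = None
    if "annotation" in body.columns:
        annotation = body["annotation"]
        body = body.drop(columns=["annotation"])
    return IntensityMatrix(
        values=body.astype(float),
        genotype=pd.Series(genotype_line[1:], index=body.columns),
        label=pd.Series(label_line[1:], index=body.columns),
        annotation=annotation,
    )


def read_vcf_candidates(path) -> list[CandidateVariant]:
    """Minimal single-tumor-sample VCF reader.

    Maps standard fields where possible (DP, AD, AF, plus the nonstandard
    evidence keys HQALT, ADF, ADR, EDGE, PP this package writes) and fails
    loudly when a required evidence field is absent.
    """
    out: list[CandidateVariant] = []
    sample_cols: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_cols = line.split("\t")[9:]
                if not sample_cols:
                    raise ValueError("VCF has no sample columns")
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[0], int(fields[1]), *fields[2:5]
            fmt_keys = fields[8].split(":")
            values = dict(zip(fmt_keys, fields[9].split(":")))
            required = ("DP", "AD", "HQALT", "ADF", "ADR", "EDGE")
            missing = [k for k in required if k not in values]
            if missing:
                raise ValueError(
                    f"VCF record {chrom}:{pos} missing evidence fields {missing}"
                )
            ad = values["AD"].split(",")
            depth, t_alt = int(values["DP"]), int(ad[1])
            edges = tuple(float(x) for x in values["EDGE"].split(",")) if values[
                "EDGE"
            ] != "." else ()
            n_depth = n_alt = None
            if len(sample_cols) > 1 and len(fields) > 10:
                n_values = dict(zip(fmt_keys, fields[10].split(":")))
                if "DP" in n_values and "AD" in n_values:
                    n_depth = int(n_values["DP"])
                    n_alt = int(n_values["AD"].split(",")[1])
            out.append(
                CandidateVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    tumor_depth=depth,
                    tumor_alt=t_alt,
                    tumor_alt_hq=int(values["HQALT"]),
                    alt_plus=int(values["ADF"]),
                    alt_minus=int(values["ADR"]),
                    edge_fractions=edges,
                    af=float(values.get("AF", t_alt / depth if depth else 0.0)),
                    normal_depth=n_depth,
                    normal_alt=n_alt,
                    posterior_p=float(values["PP"]) if "PP" in values else None,
                )
            )
    return out


def write_truth_json(path, truth: dict) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> dict:
    import json

    with open(path) as fh:
        return json.load(fh)
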