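"""Readers and writers for the pipeline's plain-text formats.

Formats: expression TSV (genes as rows, header = sample ids), sample-table
TSV, gene-annotation TSV, GMT gene-set collections, FASTA sequence sets
(via Biopython), two-column ranked lists (RNK-style) and JSON manifests.
All writers round-trip through the corresponding reader.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .attribution import GeneScoreRanking
from .datatypes import ExpressionMatrix, GeneAnnotation, SampleTable
from .enrichment import GeneSetCollection

FLOAT_FMT = "%.10g"


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        scale=scale,
    )


def write_samples(table: SampleTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    kwargs = {}
    if "time" in df.columns and "event" in df.columns:
        kwargs = {"time": df["time"].to_numpy(), "event": df["event"].to_numpy()}
    return SampleTable(
        sample_id=[str(s) for s in df["sample_id"]],
        sex=list(df["sex"]),
        cohort_id=[str(c) for c in df["cohort_id"]] if "cohort_id" in df.columns else None,
        **kwargs,
    )


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GeneAnnotation(
        gene_id=list(df["gene_id"]),
        chromosome=list(df["chromosome"]),
        gene_class=list(df["gene_class"]),
        tss=[int(t) for t in df["tss"]],
        strand=list(df["strand"]),
    )


def read_genesets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_genesets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    """FASTA reader; lowercase bases are accepted and uppercased."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_sequences(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_ranking(ranking: GeneScoreRanking, path: str | Path) -> None:
    """Two-column RNK-style ranked list, descending score."""
    ranking.scores.to_csv(path, sep="\t", header=False, float_format=FLOAT_FMT)


def read_ranking(path: str | Path) -> GeneScoreRanking:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in ranked list {path}")
    return GeneScoreRanking(pd.Series(df["score"].to_numpy(float),
                                      index=[str(g) for g in df["gene"]]))


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
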