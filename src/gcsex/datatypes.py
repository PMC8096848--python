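"""Core in-memory containers shared across pipeline stages.

Expression data is held gene-by-sample (genes as rows), mirroring the TSV
layout the pipeline reads and writes. Estimators that follow the sklearn
sample-by-feature convention transpose at their boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
GENE_CLASSES = ("mRNA", "miRNA", "lncRNA")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale tag.

    scale is "counts" (nonnegative, raw) or "log2" (log-intensity or
    log-CPM). All operations validate the scale they require.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "counts" and (self.values < 0).any():
            raise ValueError("count matrix contains negative values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def samples_by_genes(self) -> np.ndarray:
        """Transpose into the sklearn (n_samples, n_features) convention."""
        return self.values.T.copy()


@dataclass
class SampleTable:
    """Per-sample metadata: sex, cohort, optional right-censored survival."""

    sample_id: list[str]
    sex: list[str]
    cohort_id: list[str] | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_id)
        if len(self.sex) != n:
            raise ValueError("sex column length mismatch")
        bad = set(self.sex) - {"male", "female"}
        if bad:
            raise ValueError(f"sex must be male/female, got {sorted(bad)}")
        if self.cohort_id is None:
            self.cohort_id = ["cohort0"] * n
        if (self.time is None) != (self.event is None):
            raise ValueError("time and event must be provided together")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if len(self.time) != n or len(self.event) != n:
                raise ValueError("survival column length mismatch")
            if (self.time <= 0).any():
                raise ValueError("survival times must be > 0")
            if not set(np.unique(self.event)) <= {0, 1}:
                raise ValueError("event must be 0/1")

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def is_male(self) -> np.ndarray:
        return np.asarray([s == "male" for s in self.sex])

    def to_frame(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_id, "sex": self.sex, "cohort_id": self.cohort_id}
        if self.time is not None:
            d["time"] = self.time
            d["event"] = self.event
        return pd.DataFrame(d)


@dataclass
class GeneAnnotation:
    """Chromosome / class / TSS annotation, one row per gene."""

    gene_id: list[str]
    chromosome: list[str]
    gene_class: list[str]
    tss: list[int] = field(default_factory=list)
    strand: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_id)
        if len(set(self.gene_id)) != n:
            raise ValueError("duplicate gene ids in annotation")
        bad = set(self.chromosome) - set(VALID_CHROMOSOMES)
        if bad:
            raise ValueError(f"invalid chromosomes {sorted(bad)}")
        bad = set(self.gene_class) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"invalid gene classes {sorted(bad)}")
        if not self.tss:
            self.tss = [0] * n
        if not self.strand:
            self.strand = ["+"] * n
        if not (len(self.chromosome) == len(self.gene_class) == len(self.tss) == len(self.strand) == n):
            raise ValueError("annotation column length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "chromosome": self.chromosome,
                "gene_class": self.gene_class,
                "tss": self.tss,
                "strand": self.strand,
            }
        )


@dataclass
class ScaledMatrix:
    """Per-gene standardized expression plus the statistics used.

    Retained rows have mean 0 and sd 1 across samples; zero-variance genes
    are dropped (their ids recorded) because scaling divides by the sd.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    gene_means: np.ndarray
    gene_sds: np.ndarray
    dropped_genes: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_by_genes(self) -> np.ndarray:
        return self.values.T.copy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "ScaledMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ScaledMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            sample_ids=list(sample_ids),
            gene_means=self.gene_means,
            gene_sds=self.gene_sds,
            dropped_genes=self.dropped_genes,
        )
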