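"""Core domain containers shared by all pipeline stages.

Coordinates are 0-based half-open throughout; GTF input is shifted on read.
Expression containers carry a ``kind`` tag so downstream stages can refuse
matrices on the wrong scale (raw RPKM vs log vs block-centred values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cohort -> developmental stage; stage is a deterministic function of cohort.
COHORT_STAGE = {
    "GRO_iPSC": "GRO",
    "GRO_PGC": "GRO",
    "GRO_invivo": "GRO",
    "FGO_iPSC": "FGO",
    "FGO_PGC": "FGO",
    "FGO_6dpp": "FGO",
    "FGO_invivo": "FGO",
}

COHORTS = tuple(COHORT_STAGE)

#: culture-stage effects estimable at each oocyte stage.
STAGE_EFFECTS = {"GRO": ("IVP", "IVD"), "FGO": ("IVP", "IVD", "IVG")}

SPIKEIN_PREFIX = "ERCC-"


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample library sizes.

    ``library_size`` defaults to column sums over non-spike-in genes; spike-in
    rows (ids starting with ``ERCC-``) are retained in ``spikeins`` but never
    enter normalisation or testing.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) int64
    library_size: np.ndarray  # (n_samples,) positive
    spikeins: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self.library_size = np.asarray(self.library_size, dtype=float)
        if self.library_size.shape != (len(self.sample_ids),):
            raise ValueError("library_size length does not match samples")
        if np.any(self.library_size <= 0):
            raise ValueError("library sizes must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(
            list(gene_ids), list(self.sample_ids), self.counts[rows],
            self.library_size.copy(), self.spikeins,
        )

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return CountMatrix(
            list(self.gene_ids), list(sample_ids), self.counts[:, cols],
            self.library_size[cols],
            self.spikeins.iloc[:, cols] if self.spikeins is not None else None,
        )


@dataclass
class SampleTable:
    """Per-oocyte metadata: cohort, developmental stage and diameter (um)."""

    table: pd.DataFrame  # columns: sample_id, cohort, stage, diameter_um

    def __post_init__(self) -> None:
        req = {"sample_id", "cohort", "stage", "diameter_um"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"sample table must have columns {sorted(req)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        bad = ~self.table["cohort"].isin(COHORT_STAGE)
        if bad.any():
            raise ValueError(f"unknown cohorts: {sorted(self.table.loc[bad, 'cohort'].unique())}")
        expect = self.table["cohort"].map(COHORT_STAGE)
        if (expect != self.table["stage"]).any():
            rows = self.table.loc[expect != self.table["stage"], "sample_id"].tolist()
            raise ValueError(f"stage inconsistent with cohort for samples {rows[:5]}")
        if (self.table["diameter_um"] <= 0).any():
            raise ValueError("diameters must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def of_stage(self, stage: str) -> "SampleTable":
        return SampleTable(self.table[self.table["stage"] == stage].reset_index(drop=True))


@dataclass
class GeneModel:
    """One transcript model per gene: TSS, strand and merged exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        merged: list[tuple[int, int]] = []
        for a, b in exons:
            if a >= b:
                raise ValueError(f"empty exon in {self.gene_id}")
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.exons = merged

    @property
    def exonic_length_bp(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ReadIntervalSet:
    """Aligned-read intervals for one chromatin mark at one stage."""

    mark_name: str
    stage_label: str
    intervals: np.ndarray  # structured-ish: list of (chrom, start, end)
    chroms: list[str]
    total_mapped: int

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if len(self.chroms) != len(self.intervals):
            raise ValueError("chroms and intervals length mismatch")
        if np.any(self.intervals[:, 0] >= self.intervals[:, 1]):
            raise ValueError("read intervals must satisfy start < end")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T (counts or weights, not yet probabilities)."""

    motif_id: str
    matrix: np.ndarray  # (4, L)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be 4 x L")
        if self.matrix.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: motif length must be >= 1")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.motif_id}: negative weights")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValueError(f"{self.motif_id}: all-zero column")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass
class OutcomeTable:
    """Developmental-outcome counts: numerator/denominator per condition and transition."""

    table: pd.DataFrame  # columns: condition, transition, numerator, denominator

    def __post_init__(self) -> None:
        req = {"condition", "transition", "numerator", "denominator"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"outcome table must have columns {sorted(req)}")
        t = self.table
        if (t["numerator"] < 0).any() or (t["denominator"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (t["numerator"] > t["denominator"]).any():
            bad = t[t["numerator"] > t["denominator"]]
            raise ValueError(
                "numerator exceeds denominator for "
                + ", ".join(bad["condition"] + ":" + bad["transition"])
            )


@dataclass
class PromoterRecord:
    """A non-overlapping promoter window around a TSS with CpG statistics."""

    gene_id: str
    chrom: str
    start: int
    end: int
    sequence: str | None = None
    cpg_obs_exp: float | None = None
    cgi: bool | None = None
    posterior_cgi: float | None = None

    @property
    def window(self) -> tuple[str, int, int]:
        return self.chrom, self.start, self.end
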