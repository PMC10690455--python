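"""Expression normalisation, filtering, relative expression and PCA.

RPKM normalises counts to exonic length (kb) and library size (millions of
exonic reads); the log transform uses log2(RPKM + psc) - log2(psc) with
psc = 0.1 so that zero counts map to exactly 0. Relative expression subtracts
the per-gene mean within each sample block (e.g. GRO and FGO separately),
and PCA runs on those gene-centred values without unit-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CountMatrix, GeneModel


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str  # RPKM | logRPKM | CPM | relative

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def rpkm(counts: CountMatrix, models: list[GeneModel]) -> ExpressionMatrix:
    """Reads per kilobase of exon per million library reads."""
    lengths = {m.gene_id: m.exonic_length_bp for m in models}
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise KeyError(f"no gene model for: {missing[:10]}")
    L = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    if np.any(L <= 0):
        raise ValueError("exonic lengths must be positive")
    vals = counts.counts / (L[:, None] / 1e3) / (counts.library_size[None, :] / 1e6)
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), vals, "RPKM")


def log2_psc(expr: ExpressionMatrix, psc: float = 0.1) -> ExpressionMatrix:
    """log2(RPKM + psc) - log2(psc); maps RPKM 0 to exactly 0."""
    if psc <= 0:
        raise ValueError("psc must be positive")
    if np.any(expr.values < 0):
        raise ValueError("negative expression values")
    vals = np.log2(expr.values + psc) - np.log2(psc)
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), vals, "logRPKM")


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    vals = counts.counts / (counts.library_size[None, :] / 1e6)
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), vals, "CPM")


def filter_expressed(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> list[str]:
    """Genes with CPM strictly above ``min_cpm`` in at least ``min_samples`` samples."""
    c = cpm(counts).values
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def relative_expression(
    logexpr: ExpressionMatrix, partition: dict[str, str]
) -> ExpressionMatrix:
    """Subtract the per-gene mean within each partition block of samples."""
    blocks: dict[str, list[int]] = {}
    for i, s in enumerate(logexpr.sample_ids):
        if s not in partition:
            raise KeyError(f"sample {s!r} not assigned to a block")
        blocks.setdefault(partition[s], []).append(i)
    vals = np.array(logexpr.values, dtype=float)
    for name, cols in blocks.items():
        if not cols:
            raise ValueError(f"empty block {name!r}")
        vals[:, cols] -= vals[:, cols].mean(axis=1, keepdims=True)
    return ExpressionMatrix(list(logexpr.gene_ids), list(logexpr.sample_ids), vals, "relative")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray


def pca(expr: ExpressionMatrix) -> PCAResult:
    """PCA of samples in gene space: genes are variables, centred, unscaled."""
    X = expr.values.T  # samples x genes
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    k = len(S)
    comps = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(U * S, index=expr.sample_ids, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=expr.gene_ids, columns=comps)
    return PCAResult(scores, loadings, frac)
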