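"""In vivo expression-dynamics groups and k-means response clustering.

Genes are classified from the in vivo GRO-vs-FGO contrast into UP
(up-regulated during oocyte growth), DN (down-regulated), LS (low stable)
and HS (high stable). Affected genes are then sub-clustered by their
5-dimensional culture-stage response profile (log2 effects for IVP@GRO,
IVD@GRO, IVP@FGO, IVD@FGO, IVG@FGO) with seeded k-means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

GROUPS = ("LS", "UP", "DN", "HS")


def classify_dynamics(
    de_invivo: pd.DataFrame,
    mean_log_gro: pd.Series,
    mean_log_fgo: pd.Series,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    low_expr_max: float = 2.0,
    quantile_mode: bool = False,
) -> pd.Series:
    """Assign each tested gene one dynamics label.

    ``de_invivo`` is the two-group DE table of in vivo FGO vs in vivo GRO
    (positive beta_log2 = higher in FGO). Non-differential genes split into
    LS/HS by mean logRPKM in both in vivo cohorts, either against a fixed
    ``low_expr_max`` cutoff (default) or against its median (quantile mode).
    """
    genes = de_invivo.index
    missing = genes.difference(mean_log_gro.index).union(genes.difference(mean_log_fgo.index))
    if len(missing):
        raise KeyError(f"genes missing expression summaries: {list(missing[:5])}")
    sig = de_invivo["fdr"] <= fdr_max
    up = sig & (de_invivo["beta_log2"] >= lfc_min)
    dn = sig & (de_invivo["beta_log2"] <= -lfc_min)
    gro = mean_log_gro.loc[genes]
    fgo = mean_log_fgo.loc[genes]
    if quantile_mode:
        rest = ~(up | dn)
        pooled = pd.concat([gro[rest], fgo[rest]])
        cutoff = float(pooled.median())
    else:
        cutoff = low_expr_max
    low = (gro <= cutoff) & (fgo <= cutoff)
    labels = pd.Series(np.where(up, "UP", np.where(dn, "DN", np.where(low, "LS", "HS"))),
                       index=genes, name="group")
    return labels


def kmeans_responses(
    responses: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """Seeded Lloyd k-means on raw log2 response vectors.

    Best of ``n_restarts`` by within-cluster sum of squares; clusters are
    relabelled 1..k by descending mean IVD@GRO centroid component (falling
    back to the first column when absent) so names are stable across runs.

    Returns (gene -> cluster label (1-based), centroid table).
    """
    X = responses.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("responses must be finite")
    if k > len(responses):
        raise ValueError(f"k={k} exceeds number of genes ({len(responses)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    centroids = km.cluster_centers_
    sort_col = (
        list(responses.columns).index("IVD@GRO")
        if "IVD@GRO" in responses.columns
        else 0
    )
    order = np.argsort(-centroids[:, sort_col], kind="mergesort")
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=responses.index, name="cluster")
    cent = pd.DataFrame(
        centroids[order], index=range(1, k + 1), columns=responses.columns
    )
    cent.index.name = "cluster"
    cent.attrs["inertia"] = float(km.inertia_)
    return labels, cent
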