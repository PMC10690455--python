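"""Additive culture-stage effect model for single-oocyte expression.

Each oocyte cohort is encoded by the set of in vitro culture steps it passed
through (IVP: PGC specification in vitro; IVD: oocyte differentiation in
reconstituted ovaries; IVG: in vitro growth), relative to fully in vivo
development. Per gene, counts follow a negative binomial GLM with log link,

    log mu_gs = beta0_g + sum_e beta_eg * x_es + log(lib_size_s),

with NB2 variance mu + phi * mu^2. Each stage effect is tested by a
likelihood-ratio test (chi^2, 1 df) between the full model and the model
with that effect column dropped, holding the gene's dispersion fixed;
Benjamini-Hochberg correction is applied per effect. A gene is called
"affected" by a step when FDR <= 5% and |log2 fold-change| >= 2
(threshold 1 for the curated display variant).

Dispersion is estimated by maximising the Cox-Reid adjusted profile
likelihood on a fixed log-spaced grid and shrinking the per-gene maximiser
toward the common (all-gene) maximiser on the log scale with weight
prior_df / (prior_df + residual_df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .multitest import benjamini_hochberg
from .types import CountMatrix, SampleTable, STAGE_EFFECTS

LN2 = np.log(2.0)
_ETA_CLIP = 30.0

#: cohort -> indicator values for the estimable effects of its stage.
_DESIGN_ROWS = {
    "GRO_iPSC": {"IVP": 1, "IVD": 1},
    "GRO_PGC": {"IVP": 0, "IVD": 1},
    "GRO_invivo": {"IVP": 0, "IVD": 0},
    "FGO_iPSC": {"IVP": 1, "IVD": 1, "IVG": 1},
    "FGO_PGC": {"IVP": 0, "IVD": 1, "IVG": 1},
    "FGO_6dpp": {"IVP": 0, "IVD": 0, "IVG": 1},
    "FGO_invivo": {"IVP": 0, "IVD": 0, "IVG": 0},
}


def build_design(samples: SampleTable, stage: str) -> pd.DataFrame:
    """Exposure design matrix (intercept + effect indicators) for one stage."""
    if stage not in STAGE_EFFECTS:
        raise ValueError(f"unknown stage {stage!r}")
    effects = STAGE_EFFECTS[stage]
    tab = samples.table
    bad = tab[tab["stage"] != stage]
    if len(bad):
        raise ValueError(
            f"samples not of stage {stage}: {bad['sample_id'].tolist()[:5]}"
        )
    rows = []
    for _, r in tab.iterrows():
        spec_row = _DESIGN_ROWS[r["cohort"]]
        rows.append([1] + [spec_row[e] for e in effects])
    return pd.DataFrame(
        rows, index=tab["sample_id"].tolist(), columns=["intercept", *effects]
    )


# ---------------------------------------------------------------------------
# vectorised NB2 IRLS over genes sharing one design


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB2 deviance (rows genes); Poisson branch for phi ~ 0."""
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    phi = np.asarray(phi, float).reshape(-1, 1)
    small = phi < 1e-12
    inv = 1.0 / np.where(small, 1.0, phi)
    t2_nb = (y + inv) * np.log((y + inv) / (mu + inv))
    t2_pois = y - mu
    t2 = np.where(small, t2_pois, t2_nb)
    return 2.0 * (t1 - t2).sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB2 log-likelihood; Poisson limit for phi ~ 0."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-12)
    phi = np.asarray(phi, float).reshape(-1, 1)
    small = (phi < 1e-12) * np.ones_like(mu, dtype=bool)
    phi_s = np.where(phi < 1e-12, 1.0, phi)
    inv = 1.0 / phi_s
    ll_nb = (
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(phi_s * mu / (1 + phi_s * mu))
        - inv * np.log1p(phi_s * mu)
    )
    ll_pois = y * np.log(mu) - mu - gammaln(y + 1)
    return np.where(small, ll_pois, ll_nb).sum(axis=1)


def irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB2 log-link GLMs for many genes sharing a design.

    Parameters
    ----------
    y : (G, N) counts; X : (N, P) design; offset : (N,) or (G, N) natural-log
    offsets; phi : (G,) dispersions (0 allowed -> Poisson).

    Returns (beta (G, P) natural-log scale, deviance (G,), converged (G,)).
    """
    y = np.asarray(y, float)
    G, N = y.shape
    X = np.asarray(X, float)
    P = X.shape[1]
    if np.linalg.matrix_rank(X) < P:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    off = np.broadcast_to(np.asarray(offset, float), (G, N))
    phi = np.asarray(phi, float).reshape(G)

    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.zeros((G, P))
    dev = _nb_deviance(y, np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)), phi)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = mu / (1.0 + phi[:, None] * mu)  # (G, N)
        z = (eta - off) + (y - mu) / mu
        # normal equations per gene: (X' W X) beta = X' W z
        Xw = X[None, :, :] * w[:, :, None]  # (G, N, P)
        XtWX = np.einsum("np,gnq->gpq", X, Xw)
        XtWz = np.einsum("gnp,gn->gp", Xw, z)
        XtWX += 1e-10 * np.eye(P)[None, :, :]
        beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        eta = beta @ X.T + off
        new_dev = _nb_deviance(y, np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)), phi)
        delta = np.abs(new_dev - dev) / (np.abs(new_dev) + 0.1)
        converged |= delta < tol
        dev = new_dev
        if converged.all():
            break
    return beta, dev, converged


def fit_nb_glm(
    counts_g: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    offsets: np.ndarray,
    phi: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, bool]:
    """Single-gene NB GLM; coefficients on the natural-log scale."""
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    beta, dev, conv = irls_nb(
        np.asarray(counts_g, float)[None, :], X, offsets, np.array([phi]),
        tol=tol, max_iter=max_iter,
    )
    return beta[0], float(dev[0]), bool(conv[0])


# ---------------------------------------------------------------------------
# dispersion

def _apl(y, X, off, phi_val, beta=None):
    """Cox-Reid adjusted profile log-likelihood at a common phi for all genes."""
    G = y.shape[0]
    phi = np.full(G, phi_val)
    beta, _, _ = irls_nb(y, X, off, phi, tol=1e-6, max_iter=50)
    eta = beta @ X.T + np.broadcast_to(off, y.shape)
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    ll = nb_loglik(y, mu, phi)
    w = mu / (1.0 + phi_val * mu)
    Xw = X[None, :, :] * w[:, :, None]
    XtWX = np.einsum("np,gnq->gpq", X, Xw) + 1e-10 * np.eye(X.shape[1])[None]
    sign, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet


def estimate_dispersion(
    counts: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    offsets: np.ndarray,
    grid: np.ndarray | None = None,
    prior_df: float = 10.0,
    floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene shrunken dispersion estimates.

    Maximises the adjusted profile likelihood over a log-spaced grid per gene,
    then shrinks toward the all-gene maximiser on the log scale with weight
    prior_df / (prior_df + residual_df). All-zero genes get the common value
    and are flagged.

    Returns (phi_hat (G,), flagged (G,) bool).
    """
    y = np.asarray(counts, float)
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    G, N = y.shape
    P = X.shape[1]
    resid_df = N - P
    if resid_df < 2:
        raise ValueError("need >= 2 residual degrees of freedom")
    if grid is None:
        grid = np.logspace(-4, 1, 41)
    apl = np.empty((len(grid), G))
    for i, phi_val in enumerate(grid):
        apl[i] = _apl(y, X, offsets, phi_val)

    def _argmax_interp(values: np.ndarray) -> np.ndarray:
        """Log-phi at the maximum, refined by a parabola through the
        winning grid point and its neighbours."""
        v = np.atleast_2d(values)
        k = np.argmax(v, axis=1)
        lg = np.log(grid)
        out = lg[k].astype(float)
        inner = (k > 0) & (k < len(grid) - 1)
        ki = k[inner]
        y0 = v[inner, ki - 1]
        y1 = v[inner, ki]
        y2 = v[inner, ki + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        out[inner] = lg[ki] + shift * (lg[ki + 1] - lg[ki])
        return out if values.ndim > 1 else out

    per_gene = np.exp(_argmax_interp(apl.T))
    common = float(np.exp(_argmax_interp(apl.sum(axis=1)[None, :])[0]))
    w = prior_df / (prior_df + resid_df)
    phi_hat = np.exp((1 - w) * np.log(per_gene) + w * np.log(common))
    flagged = y.sum(axis=1) == 0
    phi_hat[flagged] = common
    return np.maximum(phi_hat, floor), flagged


# ---------------------------------------------------------------------------
# LRT and calls

def lrt_effect(
    counts_g: np.ndarray,
    design: pd.DataFrame,
    effect: str,
    offsets: np.ndarray,
    phi: float,
) -> tuple[float, float]:
    """Likelihood-ratio test for one effect column (chi^2, 1 df), phi fixed."""
    if effect == "intercept" or effect not in design.columns:
        raise ValueError(f"effect {effect!r} is not a testable design column")
    col = design[effect].to_numpy(float)
    if np.all(col == 0):
        return 0.0, 1.0
    reduced = design.drop(columns=[effect])
    _, dev_full, _ = fit_nb_glm(counts_g, design, offsets, phi)
    _, dev_red, _ = fit_nb_glm(counts_g, reduced, offsets, phi)
    stat = max(dev_red - dev_full, 0.0)
    return stat, float(chi2.sf(stat, df=1))


@dataclass
class StageEffectFit:
    """Per-gene fitted log2 effects, LRT p-values and FDR for one stage."""

    stage: str
    effects: tuple[str, ...]
    table: pd.DataFrame  # index gene_id; beta_log2_E, p_E, fdr_E, dispersion, converged


def fit_stage_effects(
    counts: CountMatrix,
    samples: SampleTable,
    stage: str,
    genes: list[str] | None = None,
    prior_df: float = 10.0,
    dispersion: np.ndarray | None = None,
) -> StageEffectFit:
    """Full per-stage pipeline: design, dispersion, GLM fits and per-effect LRTs."""
    sub_samples = samples.of_stage(stage)
    if not len(sub_samples.table):
        raise ValueError(f"no samples of stage {stage}")
    cm = counts.subset_samples(sub_samples.sample_ids)
    if genes is not None:
        cm = cm.subset_genes(genes)
    design = build_design(sub_samples, stage)
    X = design.to_numpy(float)
    off = np.log(cm.library_size)
    y = cm.counts.astype(float)

    if dispersion is None:
        phi, flagged = estimate_dispersion(y, design, off, prior_df=prior_df)
    else:
        phi = np.asarray(dispersion, float)
        flagged = np.zeros(len(phi), dtype=bool)

    beta, dev_full, conv = irls_nb(y, X, off, phi)
    effects = STAGE_EFFECTS[stage]
    out = pd.DataFrame(index=cm.gene_ids)
    out.index.name = "gene_id"
    for j, eff in enumerate(effects, start=1):
        out[f"beta_log2_{eff}"] = beta[:, j] / LN2
        col = design[eff].to_numpy(float)
        if np.all(col == 0):
            stat = np.zeros(len(cm.gene_ids))
        else:
            Xr = design.drop(columns=[eff]).to_numpy(float)
            _, dev_red, conv_r = irls_nb(y, Xr, off, phi)
            conv &= conv_r
            stat = np.maximum(dev_red - dev_full, 0.0)
        p = chi2.sf(stat, df=1)
        out[f"lrt_{eff}"] = stat
        out[f"p_{eff}"] = p
        out[f"fdr_{eff}"] = benjamini_hochberg(p)
    out["dispersion"] = phi
    out["converged"] = conv
    out["dispersion_flagged"] = flagged
    return StageEffectFit(stage, tuple(effects), out)


def call_affected(
    fit: StageEffectFit, fdr_max: float = 0.05, lfc_min: float = 2.0
) -> pd.DataFrame:
    """Genes with FDR <= fdr_max and |log2FC| >= lfc_min for any effect.

    Non-converged genes are excluded from calls (they remain in the QC table).
    Returns a long table (gene_id, stage, effect, beta_log2, fdr, direction).
    """
    rows = []
    tab = fit.table[fit.table["converged"].astype(bool)]
    for eff in fit.effects:
        sel = (tab[f"fdr_{eff}"] <= fdr_max) & (tab[f"beta_log2_{eff}"].abs() >= lfc_min)
        for gene, r in tab[sel].iterrows():
            b = r[f"beta_log2_{eff}"]
            rows.append(
                {
                    "gene_id": gene,
                    "stage": fit.stage,
                    "effect": f"{eff}@{fit.stage}",
                    "beta_log2": b,
                    "fdr": r[f"fdr_{eff}"],
                    "direction": "up" if b > 0 else "down",
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "stage", "effect", "beta_log2", "fdr", "direction"])


def de_two_group(
    counts: CountMatrix,
    groups: dict[str, str] | pd.Series,
    fdr_max: float = 0.05,
    lfc_min: float = 2.0,
    prior_df: float = 10.0,
    dispersion: np.ndarray | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Two-group differential expression with the same NB-GLM/LRT machinery.

    ``groups`` maps sample_id -> label (exactly two labels). The log2FC is
    the non-reference group relative to ``reference`` (first label in sorted
    order when not given). Returns a per-gene table with beta_log2, p, fdr
    and a ``significant`` flag at the thresholds.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference {reference!r} not among groups {labels}")
        labels = [reference, next(l for l in labels if l != reference)]
    order = [s for s in counts.sample_ids if s in groups.index]
    if len(order) != counts.n_samples:
        missing = set(counts.sample_ids) - set(groups.index)
        raise KeyError(f"samples without a group label: {sorted(missing)[:5]}")
    ind = np.array([1.0 if groups[s] == labels[1] else 0.0 for s in order])
    n1, n2 = int((ind == 0).sum()), int((ind == 1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    design = pd.DataFrame(
        {"intercept": 1.0, "group": ind}, index=counts.sample_ids
    )
    X = design.to_numpy(float)
    off = np.log(counts.library_size)
    y = counts.counts.astype(float)
    if dispersion is None:
        phi, _ = estimate_dispersion(y, design, off, prior_df=prior_df)
    else:
        phi = np.asarray(dispersion, float)
    beta, dev_full, conv = irls_nb(y, X, off, phi)
    _, dev_red, conv_r = irls_nb(y, X[:, :1], off, phi)
    stat = np.maximum(dev_red - dev_full, 0.0)
    p = chi2.sf(stat, df=1)
    fdr = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "beta_log2": beta[:, 1] / LN2,
            "lrt": stat,
            "p": p,
            "fdr": fdr,
            "dispersion": phi,
            "converged": conv & conv_r,
        },
        index=counts.gene_ids,
    )
    out.index.name = "gene_id"
    out["significant"] = (
        (out["fdr"] <= fdr_max) & (out["beta_log2"].abs() >= lfc_min) & out["converged"]
    )
    out.attrs["contrast"] = f"{labels[1]} vs {labels[0]}"
    out.attrs["n_up"] = int((out["significant"] & (out["beta_log2"] > 0)).sum())
    out.attrs["n_down"] = int((out["significant"] & (out["beta_log2"] < 0)).sum())
    return out
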