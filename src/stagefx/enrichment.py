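"""Categorical enrichment machinery.

Covers chi^2 enrichment of gene groups among affected genes, one-sided
Fisher (hypergeometric) GO-term enrichment with optional elim decorrelation,
Jaccard-distance MDS of significant terms, log-odds PWM scanning with an
exact background score distribution, and binned motif enrichment against an
"other bins" background with BH correction.

Enrichments follow the log2((obs + 1)/(exp + 1)) convention with expected
counts derived from marginals of the same gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom

from .multitest import benjamini_hochberg
from .types import PWM

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# chi^2 group enrichment

def chisq_enrichment(
    membership: dict[str, str] | pd.Series,
    target: set[str],
    universe: set[str],
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Per-group over/under-representation of ``target`` genes in ``universe``.

    expected = |target| * |group| / |universe|; enrichment =
    log2((obs+1)/(exp+1)); p from the 2x2 chi^2 test without continuity
    correction; significant when p <= p_max (default 1%).
    """
    if not universe:
        raise ValueError("empty universe")
    if not target <= universe:
        raise ValueError("target must be a subset of the universe")
    membership = pd.Series(membership)
    membership = membership[membership.index.isin(universe)]
    rows = []
    n_t, n_u = len(target), len(universe)
    for group in sorted(membership.unique()):
        members = set(membership.index[membership == group])
        obs = len(members & target)
        exp = n_t * len(members) / n_u
        table = np.array(
            [
                [obs, len(members) - obs],
                [n_t - obs, (n_u - len(members)) - (n_t - obs)],
            ]
        )
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
        else:
            _, p, _, _ = chi2_contingency(table, correction=False)
        rows.append(
            {
                "group": group,
                "observed": obs,
                "expected": exp,
                "enrichment_log2": np.log2((obs + 1) / (exp + 1)),
                "p": p,
                "significant": p <= p_max,
            }
        )
    return pd.DataFrame(rows)


def chisq_stat_2x2(table: np.ndarray) -> float:
    """Pearson chi^2 statistic sum (O-E)^2 / E without continuity correction."""
    t = np.asarray(table, float)
    rs, cs, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    exp = np.outer(rs, cs) / n
    return float(((t - exp) ** 2 / exp).sum())


# ---------------------------------------------------------------------------
# GO enrichment

@dataclass
class GoResult:
    table: pd.DataFrame  # term, annotated, observed, expected, enrichment, p
    gene_sets: dict[str, set[str]]  # term -> study genes carrying it


def fisher_go(
    study: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
    min_annotated: int = 5,
    dag_parents: dict[str, set[str]] | None = None,
    elim_p: float | None = None,
) -> GoResult:
    """One-sided hypergeometric over-representation test per GO term.

    enrichment = observed/expected (expected from the universe marginal).
    With ``dag_parents`` and ``elim_p`` given, terms are processed most
    specific first and genes of significant terms are removed from their
    ancestors (elim decorrelation).
    """
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene in universe:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)
    term_genes = {t: g for t, g in term_genes.items() if len(g) >= min_annotated}

    order = list(term_genes)
    if dag_parents is not None and elim_p is not None:
        # children before parents: sort by annotation size ascending
        order.sort(key=lambda t: (len(term_genes[t]), t))
    eliminated: dict[str, set[str]] = {t: set() for t in term_genes}

    def ancestors(t: str) -> set[str]:
        out, stack = set(), [t]
        while stack:
            for p in dag_parents.get(stack.pop(), set()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    N, n = len(universe), len(study)
    rows, gene_sets = [], {}
    for t in order:
        genes = term_genes[t] - eliminated[t]
        K = len(genes)
        obs_genes = genes & study
        k = len(obs_genes)
        exp = n * K / N
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term": t,
                "annotated": K,
                "observed": k,
                "expected": exp,
                "enrichment": (k / exp) if exp > 0 else np.nan,
                "p": p,
            }
        )
        gene_sets[t] = obs_genes
        if dag_parents is not None and elim_p is not None and p <= elim_p:
            for anc in ancestors(t):
                if anc in eliminated:
                    eliminated[anc] |= genes
    tab = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    return GoResult(tab, gene_sets)


def jaccard_mds(gene_sets: dict[str, set[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classical (Torgerson) MDS of terms under pairwise Jaccard distance.

    Returns (2-D coordinates, distance matrix). Orientation is canonicalised
    so the first term's coordinates are non-negative.
    """
    terms = list(gene_sets)
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    m = len(terms)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = gene_sets[terms[i]], gene_sets[terms[j]]
            union = len(a | b)
            d = 1.0 - (len(a & b) / union if union else 1.0)
            D[i, j] = D[j, i] = d
    if np.allclose(D, 0):
        import warnings

        warnings.warn("all term sets identical; MDS collapses to the origin")
        coords = np.zeros((m, 2))
    else:
        J = np.eye(m) - np.ones((m, m)) / m
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        idx = np.argsort(vals)[::-1][:2]
        lam = np.maximum(vals[idx], 0.0)
        coords = vecs[:, idx] * np.sqrt(lam)[None, :]
        for k in range(2):
            if coords[0, k] < 0:
                coords[:, k] = -coords[:, k]
    cdf = pd.DataFrame(coords, index=terms, columns=["mds1", "mds2"])
    ddf = pd.DataFrame(D, index=terms, columns=terms)
    return cdf, ddf


# ---------------------------------------------------------------------------
# PWM scanning

def pwm_log_odds(pwm: PWM, background: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Column-normalised log2-odds matrix vs background base frequencies."""
    counts = pwm.matrix + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    bg = np.asarray(background, float)
    bg = bg / bg.sum()
    return np.log2(probs / bg[:, None])


def score_distribution(
    lom: np.ndarray, background: np.ndarray, precision: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the motif score under iid background, by DP.

    Scores are discretised to ``precision`` and convolved position by
    position. Returns (sorted score grid, probabilities).
    """
    bg = np.asarray(background, float)
    bg = bg / bg.sum()
    q = np.round(lom / precision).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for j in range(q.shape[1]):
        new: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + q[b, j]
                new[key] = new.get(key, 0.0) + p * bg[b]
        dist = new
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys])
    return keys * precision, probs


def score_threshold(
    pwm: PWM,
    background: np.ndarray,
    quantile: float = 0.999,
    pseudocount: float = 0.5,
) -> float:
    """Smallest score s with P(score < s) >= quantile under the background."""
    lom = pwm_log_odds(pwm, background, pseudocount)
    scores, probs = score_distribution(lom, background)
    cdf = np.cumsum(probs)
    if quantile >= 1.0:
        return float(scores[-1])
    idx = np.searchsorted(cdf, quantile, side="left")
    idx = min(idx + 1, len(scores) - 1)
    return float(scores[idx])


_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _seq_scores(lom: np.ndarray, seq: str) -> np.ndarray:
    L = lom.shape[1]
    n = len(seq)
    if n < L:
        return np.empty(0)
    idx = np.array([_BASE_IDX.get(c, -1) for c in seq])
    out = np.full(n - L + 1, -np.inf)
    valid = np.ones(n - L + 1, dtype=bool)
    scores = np.zeros(n - L + 1)
    for j in range(L):
        col = idx[j : j + n - L + 1]
        bad = col < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, lom[np.clip(col, 0, 3), j])
    out[valid] = scores[valid]
    return out


def scan_pwm(
    pwm: PWM,
    sequences: dict[str, str],
    background: np.ndarray | None = None,
    score_quantile: float = 0.999,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Scan sequences on both strands; a sequence 'hits' when any offset
    scores at or above the background-quantile threshold.

    Returns a table (seq_id, n_hits, hit).
    """
    if background is None:
        background = np.full(4, 0.25)
    lom = pwm_log_odds(pwm, background, pseudocount)
    thr = score_threshold(pwm, background, score_quantile, pseudocount)
    # the DP threshold is discretised; allow its accumulated rounding error
    thr -= 1e-3 * pwm.length
    rows = []
    for name, seq in sequences.items():
        s = seq.upper()
        fwd = _seq_scores(lom, s)
        rev = _seq_scores(lom, revcomp(s))
        n_hits = int((fwd >= thr).sum() + (rev >= thr).sum())
        rows.append({"seq_id": name, "motif_id": pwm.motif_id, "n_hits": n_hits, "hit": n_hits > 0})
    return pd.DataFrame(rows)


def binned_motif_enrichment(
    bins: dict[str, str] | pd.Series,
    hits: pd.DataFrame,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of motif hits per bin vs all other bins.

    ``bins`` maps gene -> bin label; ``hits`` is a table with columns
    gene_id (or seq_id), motif_id, hit. BH across all (motif, bin) pairs;
    significant when fdr <= fdr_max (default 1%).
    """
    bins = pd.Series(bins)
    key = "gene_id" if "gene_id" in hits.columns else "seq_id"
    rows = []
    for motif_id, sub in hits.groupby("motif_id"):
        hit_map = sub.set_index(key)["hit"]
        genes = bins.index.intersection(hit_map.index)
        b = bins.loc[genes]
        h = hit_map.loc[genes].astype(bool)
        for name in sorted(b.unique()):
            inb = b == name
            n_bin = int(inb.sum())
            if n_bin == 0:
                continue
            k_bin = int(h[inb].sum())
            n_out = int((~inb).sum())
            k_out = int(h[~inb].sum())
            # upper tail: P(overlap >= k_bin) drawing n_bin from k_bin+k_out hits
            p = float(hypergeom.sf(k_bin - 1, n_bin + n_out, k_bin + k_out, n_bin))
            odds = (
                (k_bin / max(n_bin - k_bin, 1)) / max(k_out / max(n_out - k_out, 1), 1e-300)
                if k_out > 0 or k_bin > 0
                else np.nan
            )
            rows.append(
                {
                    "motif_id": motif_id,
                    "bin": name,
                    "hits_bin": k_bin,
                    "n_bin": n_bin,
                    "hits_other": k_out,
                    "n_other": n_out,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["fdr"] <= fdr_max
    return out
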