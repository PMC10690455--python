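"""Promoter windows, CpG observed/expected ratios and CGI classification.

Promoters are the +/-1.5 kb windows around each gene's TSS (strand
independent). Transitively overlapping windows are resolved by keeping one
per overlap group uniformly at random under a seed. The CpG observed/expected
ratio uses the Gardiner-Garden & Frommer form (#CpG * L) / (#C * #G), and
promoters are split into CGI vs non-CGI by a two-component 1-D Gaussian
mixture fitted by EM: a promoter is CGI when the posterior of the
higher-mean component exceeds 1/2.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .types import GeneModel, PromoterRecord


def build_promoters(
    models: list[GeneModel],
    contig_lengths: dict[str, int] | None = None,
    halfwidth: int = 1500,
    seed: int = 0,
) -> tuple[list[PromoterRecord], list[str]]:
    """TSS +/- halfwidth windows with random resolution of overlaps.

    Returns (kept promoter records, dropped gene ids). Windows are clipped at
    contig boundaries when ``contig_lengths`` is given.
    """
    windows = []
    for m in models:
        start = m.tss - halfwidth
        end = m.tss + halfwidth
        if contig_lengths is not None:
            clen = contig_lengths.get(m.chrom)
            if clen is None:
                raise KeyError(f"contig {m.chrom} absent from contig_lengths")
            start, end = max(start, 0), min(end, clen)
        else:
            start = max(start, 0)
        if end - start < 1:
            raise ValueError(f"promoter of {m.gene_id} is empty after clipping")
        windows.append(PromoterRecord(m.gene_id, m.chrom, start, end))
    if not windows:
        raise ValueError("no promoters constructed")

    # group transitively-overlapping windows per chromosome, keep 1 per group
    rng = random.Random(seed)
    kept: list[PromoterRecord] = []
    dropped: list[str] = []
    by_chrom: dict[str, list[PromoterRecord]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end, w.gene_id))
        group: list[PromoterRecord] = []
        group_end = -1
        for w in ws + [None]:
            if w is not None and (not group or w.start < group_end):
                group.append(w)
                group_end = max(group_end, w.end)
                continue
            if group:
                survivor = group[0] if len(group) == 1 else rng.choice(group)
                kept.append(survivor)
                dropped.extend(g.gene_id for g in group if g is not survivor)
            if w is not None:
                group = [w]
                group_end = w.end
    kept.sort(key=lambda w: (w.chrom, w.start))
    return kept, sorted(dropped)


def cpg_obs_exp(seq: str) -> float:
    """(#CpG * L) / (#C * #G) over non-N positions; 0 when #C*#G == 0."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    length = sum(s.count(b) for b in "ACGT")
    if n_c * n_g == 0 or length == 0:
        return 0.0
    n_cpg = 0
    prev_c = False
    for ch in s:
        if ch == "N":
            prev_c = False
            continue
        if ch == "G" and prev_c:
            n_cpg += 1
        prev_c = ch == "C"
    return n_cpg * length / (n_c * n_g)


@dataclass
class GMMFit:
    means: tuple[float, float]  # mu1 < mu2
    sds: tuple[float, float]
    weights: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool


def fit_gmm2(
    ratios,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[GMMFit, np.ndarray]:
    """Two-component 1-D Gaussian mixture by EM.

    Initialised deterministically from the 25th/75th percentile split of the
    data. Returns the fit and the posterior probability of the higher-mean
    (CGI-like) component per observation; classify CGI when it exceeds 0.5.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite ratios")
    if np.var(x) == 0:
        raise ValueError("degenerate (zero-variance) ratios; use a fixed threshold instead")
    q25, q75 = np.percentile(x, [25, 75])
    split = (q25 + q75) / 2.0
    lo, hi = x[x <= split], x[x > split]
    if len(lo) == 0 or len(hi) == 0:
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-4), max(hi.std(), 1e-4)])
    w = np.array([len(lo), len(hi)], dtype=float) / x.size

    def log_npdf(x_, m, s):
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * ((x_ - m) / s) ** 2

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack([np.log(w[k]) + log_npdf(x, mu[k], sd[k]) for k in (0, 1)])
        mx = logp.max(axis=0)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
        resp = np.exp(logp - lse)  # (2, n)
        ll = lse.sum()
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp * x).sum(axis=1) / nk
        sd = np.sqrt((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk)
        sd = np.maximum(sd, 1e-6)
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    # order components by mean
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    logp = np.stack([np.log(w[k]) + log_npdf(x, mu[k], sd[k]) for k in (0, 1)])
    mx = logp.max(axis=0)
    lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
    post_hi = np.exp(logp[1] - lse)
    fit = GMMFit(
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        weights=(float(w[0]), float(w[1])),
        loglik=float(ll_old),
        n_iter=it,
        converged=converged,
    )
    return fit, post_hi


def annotate_promoters(
    promoters: list[PromoterRecord],
    sequences: dict[str, str],
    seed: int = 0,
) -> tuple[list[PromoterRecord], GMMFit]:
    """Attach sequence, CpG ratio and GMM-based CGI call to each promoter.

    ``sequences`` maps either gene ids to promoter sequences or chromosome
    names to full contig sequences (windows are then sliced out).
    """
    for p in promoters:
        if p.gene_id in sequences:
            p.sequence = sequences[p.gene_id]
        elif p.chrom in sequences:
            p.sequence = sequences[p.chrom][p.start : p.end]
        else:
            raise KeyError(f"no sequence for promoter {p.gene_id}")
        p.cpg_obs_exp = cpg_obs_exp(p.sequence)
    ratios = np.array([p.cpg_obs_exp for p in promoters])
    fit, post = fit_gmm2(ratios, seed=seed)
    for p, q in zip(promoters, post):
        p.posterior_cgi = float(q)
        p.cgi = bool(q > 0.5)
    return promoters, fit
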