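"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure of the single-oocyte study
design: 7 cohorts (GRO/FGO x iPSC/PGC/6dpp/in vivo) of 20-25 oocytes,
negative-binomial counts with planted additive per-stage log2 effects,
gene groups with LS/UP/DN/HS in vivo dynamics, CGI vs non-CGI promoter
sequence composition realised by a dinucleotide-controlled Markov chain,
chromatin-mark read pileups elevated at designated Polycomb-target
promoters, JASPAR-style motifs embeddable into chosen promoter sets, GO
annotations with a planted enriched term, and binomial developmental-outcome
tables. Every output is reproducible bit-for-bit from (config, seed), and
the truth object is sufficient to score every downstream inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    COHORT_STAGE,
    COHORTS,
    CountMatrix,
    GeneModel,
    OutcomeTable,
    PWM,
    ReadIntervalSet,
    SampleTable,
)

EFFECTS = ("IVP@GRO", "IVD@GRO", "IVP@FGO", "IVD@FGO", "IVG@FGO")

#: exposure indicators per cohort for the five planted effects (same table
#: the model module encodes, expressed per stage-specific effect).
_EXPOSURE = {
    "GRO_iPSC": (1, 1, 0, 0, 0),
    "GRO_PGC": (0, 1, 0, 0, 0),
    "GRO_invivo": (0, 0, 0, 0, 0),
    "FGO_iPSC": (0, 0, 1, 1, 1),
    "FGO_PGC": (0, 0, 0, 1, 1),
    "FGO_6dpp": (0, 0, 0, 0, 1),
    "FGO_invivo": (0, 0, 0, 0, 0),
}


@dataclass
class SimulationConfig:
    """Study-scale defaults; shrink ``n_genes``/``cohort_size`` for fast tests."""

    n_genes: int = 12000
    cohort_size: int = 23
    lib_size_range: tuple[float, float] = (0.5e6, 2.0e6)
    cgi_fraction: float = 0.5
    # in vivo dynamics composition (LS, UP, DN, HS)
    group_fractions: tuple[float, float, float, float] = (0.35, 0.25, 0.20, 0.20)
    # fraction of genes affected per culture-stage effect; UP genes are
    # sampled preferentially (over-representation among affected genes)
    affected_fraction: float = 0.02
    up_bias: float = 3.0
    effect_low: float = 2.5
    effect_high: float = 4.0
    dispersion_shape: float = 4.0
    dispersion_mean: float = 0.3
    promoter_halfwidth: int = 1500
    gene_spacing: int = 7000
    promoter_overlap_fraction: float = 0.02
    cgi_ratio_mean: float = 0.75
    cgi_ratio_sd: float = 0.08
    noncgi_ratio_mean: float = 0.25
    noncgi_ratio_sd: float = 0.05


@dataclass
class SimulationTruth:
    """Everything needed to score downstream inference."""

    gene_ids: list[str]
    baseline_log2cpm_gro: np.ndarray
    baseline_log2cpm_fgo: np.ndarray
    dispersion: np.ndarray
    beta: pd.DataFrame  # genes x 5 effects, log2 units
    dynamics: pd.Series  # LS/UP/DN/HS
    promoter_class: pd.Series  # CGI / nonCGI
    polycomb_target: pd.Series  # bool
    target_cpg_ratio: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        obj = {
            "seed": self.seed,
            "gene_ids": self.gene_ids,
            "baseline_log2cpm_gro": self.baseline_log2cpm_gro.tolist(),
            "baseline_log2cpm_fgo": self.baseline_log2cpm_fgo.tolist(),
            "dispersion": self.dispersion.tolist(),
            "beta": {e: self.beta[e].tolist() for e in self.beta.columns},
            "dynamics": self.dynamics.tolist(),
            "promoter_class": self.promoter_class.tolist(),
            "polycomb_target": self.polycomb_target.astype(bool).tolist(),
            "target_cpg_ratio": self.target_cpg_ratio.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        obj = json.loads(Path(path).read_text())
        genes = obj["gene_ids"]
        return cls(
            gene_ids=genes,
            baseline_log2cpm_gro=np.array(obj["baseline_log2cpm_gro"]),
            baseline_log2cpm_fgo=np.array(obj["baseline_log2cpm_fgo"]),
            dispersion=np.array(obj["dispersion"]),
            beta=pd.DataFrame({e: obj["beta"][e] for e in EFFECTS}, index=genes),
            dynamics=pd.Series(obj["dynamics"], index=genes),
            promoter_class=pd.Series(obj["promoter_class"], index=genes),
            polycomb_target=pd.Series(obj["polycomb_target"], index=genes),
            target_cpg_ratio=np.array(obj["target_cpg_ratio"]),
            seed=obj["seed"],
        )


def make_truth(config: SimulationConfig, seed: int) -> SimulationTruth:
    """Draw per-gene ground truth: baselines, dispersions, effects, labels."""
    rng = np.random.default_rng(seed)
    G = config.n_genes
    if G < 10:
        raise ValueError("n_genes must be >= 10")
    genes = [f"gene{i:05d}" for i in range(G)]

    fr = np.asarray(config.group_fractions, float)
    fr = fr / fr.sum()
    counts = np.floor(fr * G).astype(int)
    counts[0] += G - counts.sum()
    dynamics = np.repeat(np.array(["LS", "UP", "DN", "HS"]), counts)
    rng.shuffle(dynamics)
    dynamics = pd.Series(dynamics, index=genes, name="group")

    # baselines in log2 CPM; UP/DN get a planted GRO->FGO shift >= 1.2
    b_gro = np.empty(G)
    shift = np.zeros(G)
    # LS baseline sits below ~0.3 RPKM for typical exon lengths, i.e. under
    # the low-stable logRPKM cutoff, while still passing the CPM filter
    for grp, mu, sd in (("LS", -1.5, 0.5), ("UP", 1.5, 1.0), ("DN", 4.0, 1.0), ("HS", 5.5, 1.0)):
        m = dynamics.values == grp
        b_gro[m] = rng.normal(mu, sd, m.sum())
    m_up = dynamics.values == "UP"
    m_dn = dynamics.values == "DN"
    shift[m_up] = np.maximum(rng.normal(2.5, 0.8, m_up.sum()), 1.2)
    shift[m_dn] = -np.maximum(rng.normal(2.5, 0.8, m_dn.sum()), 1.2)
    b_fgo = b_gro + shift

    phi = rng.gamma(
        config.dispersion_shape, config.dispersion_mean / config.dispersion_shape, G
    )
    phi = np.maximum(phi, 1e-4)

    # affected genes per effect, with UP genes over-sampled
    w = np.where(m_up, config.up_bias, 1.0)
    w = w / w.sum()
    beta = pd.DataFrame(0.0, index=genes, columns=list(EFFECTS))
    n_aff = max(int(round(config.affected_fraction * G)), 1)
    for e in EFFECTS:
        idx = rng.choice(G, size=n_aff, replace=False, p=w)
        mag = rng.uniform(config.effect_low, config.effect_high, n_aff)
        sign = rng.choice([-1.0, 1.0], n_aff)
        beta.iloc[idx, beta.columns.get_loc(e)] = sign * mag

    n_cgi = int(round(config.cgi_fraction * G))
    promoter_class = np.array(["nonCGI"] * G, dtype=object)
    promoter_class[rng.permutation(G)[:n_cgi]] = "CGI"
    promoter_class = pd.Series(promoter_class, index=genes, name="promoter_class")

    ratio = np.where(
        promoter_class.values == "CGI",
        rng.normal(config.cgi_ratio_mean, config.cgi_ratio_sd, G),
        rng.normal(config.noncgi_ratio_mean, config.noncgi_ratio_sd, G),
    )
    ratio = np.clip(ratio, 0.02, 1.8)

    affected_any = (beta.abs() >= 2).any(axis=1)
    polycomb = (promoter_class == "CGI") & affected_any
    return SimulationTruth(
        gene_ids=genes,
        baseline_log2cpm_gro=b_gro,
        baseline_log2cpm_fgo=b_fgo,
        dispersion=phi,
        beta=beta,
        dynamics=dynamics,
        promoter_class=promoter_class,
        polycomb_target=polycomb.rename("polycomb_target"),
        target_cpg_ratio=ratio,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genome & promoter sequences

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _cpg_transition(target_ratio: float) -> float:
    """P(G | previous C) achieving the target observed/expected CpG ratio.

    Under the chain (uniform rows except the C row), ratio ~= c / pi_G with
    the stationary pi_G depending on c; a short fixed-point solves for c.
    """
    c = 0.25 * target_ratio
    for _ in range(20):
        pi_c = 0.25 / (1.25 - (1 - c) / 3)  # stationary C frequency
        pi_g = 0.25 * (1 - pi_c) + c * pi_c
        c = min(target_ratio * pi_g, 0.95)
    return c


def _markov_promoters(ratios: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    """(n, length) base codes from per-sequence CpG-controlled chains."""
    n = len(ratios)
    c = np.array([_cpg_transition(r) for r in ratios])
    rest = (1.0 - c) / 3.0  # A, C, T mass after a C
    out = np.empty((n, length), dtype=np.int8)
    cur = rng.integers(0, 4, size=n)
    out[:, 0] = cur
    for j in range(1, length):
        u = rng.random(n)
        # default: uniform next base
        nxt = np.minimum((u * 4).astype(np.int8), 3)
        # rows where current base is C: thresholds A|C|G|T = rest,rest,c,rest
        isc = cur == 1
        if isc.any():
            uu = u[isc]
            r = rest[isc]
            cc = c[isc]
            b = np.empty(isc.sum(), dtype=np.int8)
            b[:] = 3  # T
            b[uu < 2 * r + cc] = 2  # G
            b[uu < 2 * r] = 1  # C
            b[uu < r] = 0  # A
            nxt[isc] = b
        out[:, j] = nxt
        cur = nxt.astype(np.int64)
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]  # chromosome -> sequence
    models: list[GeneModel]
    promoter_sequences: dict[str, str]  # gene -> 3 kb promoter-spanning sequence
    contig_lengths: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.contig_lengths = {c: len(s) for c, s in self.sequences.items()}


def simulate_genome(
    truth: SimulationTruth, config: SimulationConfig, seed: int | None = None
) -> SyntheticGenome:
    """One-chromosome genome with per-gene CpG-controlled promoter sequence.

    Genes are spaced ``gene_spacing`` bp apart; a configurable fraction of
    consecutive TSSs are placed closer than a promoter width so that overlap
    removal is exercised. Strand alternates and TSS follows the strand
    convention (interval start on +, end-1 on -).
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    G = len(truth.gene_ids)
    hw = config.promoter_halfwidth
    spacing = config.gene_spacing
    if spacing < 2 * hw + 1000:
        raise ValueError("gene_spacing too small for promoter width")

    # TSS positions; a fraction of genes sit close to their neighbour
    tss = np.empty(G, dtype=np.int64)
    pos = 2 * hw
    for i in range(G):
        tss[i] = pos
        close = rng.random() < config.promoter_overlap_fraction
        pos += int(rng.integers(hw // 2, hw)) if close else spacing
    chrom_len = int(pos + 2 * hw)
    chrom = "chr1"

    codes = rng.integers(0, 4, size=chrom_len).astype(np.int8)
    prom_codes = _markov_promoters(truth.target_cpg_ratio, 2 * hw + 2, rng)
    # write promoter chunks into the chromosome (later genes win on overlap)
    for i in range(G):
        a = int(tss[i]) - hw
        ln = min(2 * hw + 2, chrom_len - a)
        codes[a : a + ln] = prom_codes[i][:ln]

    strands = np.where(rng.random(G) < 0.5, "+", "-")
    models = []
    for i, g in enumerate(truth.gene_ids):
        length = int(np.exp(rng.uniform(np.log(800), np.log(4000))))
        l1 = max(int(0.3 * length), 100)
        l2 = length - l1
        gap = int(rng.integers(200, 800))
        if strands[i] == "+":
            e1 = (int(tss[i]), int(tss[i]) + l1)
            e2 = (e1[1] + gap, e1[1] + gap + l2)
        else:
            e2_end = int(tss[i]) + 1
            e2 = (e2_end - l1, e2_end)
            e1 = (e2[0] - gap - l2, e2[0] - gap)
        models.append(GeneModel(g, chrom, strands[i], int(tss[i]), [e1, e2]))

    seq = _codes_to_str(codes)
    prom_seqs = {
        g: seq[max(tss[i] - hw, 0) : tss[i] + hw] for i, g in enumerate(truth.gene_ids)
    }
    return SyntheticGenome({chrom: seq}, models, prom_seqs)


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int | None = None,
    cohort_sizes: dict[str, int] | None = None,
) -> tuple[CountMatrix, SampleTable]:
    """NB counts: log2 mean = stage baseline + planted effects + log2(lib/1e6)."""
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    sizes = cohort_sizes or {c: config.cohort_size for c in COHORTS}
    unknown = set(sizes) - set(COHORTS)
    if unknown:
        raise ValueError(f"unknown cohorts: {sorted(unknown)}")
    G = len(truth.gene_ids)
    beta = truth.beta.to_numpy()

    sample_ids, cohorts, libs, mus = [], [], [], []
    lo, hi = config.lib_size_range
    for cohort in COHORTS:
        n = sizes.get(cohort, 0)
        x = np.asarray(_EXPOSURE[cohort], float)
        base = (
            truth.baseline_log2cpm_gro
            if COHORT_STAGE[cohort] == "GRO"
            else truth.baseline_log2cpm_fgo
        )
        log2_cpm = base + beta @ x
        for i in range(n):
            lib = rng.uniform(lo, hi)
            sample_ids.append(f"{cohort}_{i:02d}")
            cohorts.append(cohort)
            libs.append(lib)
            mus.append(np.exp2(log2_cpm) * lib / 1e6)
    mu = np.column_stack(mus)  # genes x samples
    phi = truth.dispersion[:, None]
    lam = np.where(
        phi < 1e-12, mu, rng.gamma(np.maximum(1.0 / phi, 1e-12), phi * mu)
    )
    counts = rng.poisson(lam).astype(np.int64)

    libs = np.asarray(libs, float)
    cm = CountMatrix(list(truth.gene_ids), sample_ids, counts, libs)
    diam = []
    for cohort in cohorts:
        if COHORT_STAGE[cohort] == "GRO":
            diam.append(float(np.clip(rng.normal(65, 5), 55, 75)))
        else:
            diam.append(float(np.clip(rng.normal(75, 3), 70, 80)))
    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort": cohorts,
                "stage": [COHORT_STAGE[c] for c in cohorts],
                "diameter_um": diam,
            }
        )
    )
    return cm, st


# ---------------------------------------------------------------------------
# chromatin reads

REPRESSIVE_MARKS = ("H3K27me3", "H2AK119ub1")
ACTIVE_MARKS = ("H3K4me3",)


def simulate_chip_reads(
    truth: SimulationTruth,
    genome: SyntheticGenome,
    mark_name: str,
    stage_label: str = "FGO",
    enrich_factor: float = 8.0,
    n_reads: int = 200_000,
    read_length: int = 100,
    seed: int | None = None,
) -> ReadIntervalSet:
    """Uniform read placement except Polycomb-target promoters.

    Repressive marks get ``enrich_factor`` x density at target promoters,
    active marks 1/``enrich_factor``. ``n_reads == 0`` yields an empty set
    (total_mapped 1 so the object stays valid; flagged downstream).
    """
    if enrich_factor < 1:
        raise ValueError("enrich_factor must be >= 1")
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    chrom = next(iter(genome.sequences))
    clen = genome.contig_lengths[chrom]
    hw = (len(next(iter(genome.promoter_sequences.values())))) // 2

    factor = (
        enrich_factor
        if mark_name in REPRESSIVE_MARKS
        else (1.0 / enrich_factor if mark_name in ACTIVE_MARKS else 1.0)
    )
    tss = {m.gene_id: m.tss for m in genome.models}
    targets = [g for g in truth.gene_ids if truth.polycomb_target[g]]
    raw = sorted(
        (max(tss[g] - hw, 0), min(tss[g] + hw, clen)) for g in targets
    )
    windows: list[tuple[int, int]] = []
    for a, b in raw:  # merge overlapping target windows
        if windows and a <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], b))
        else:
            windows.append((a, b))
    windows = np.array(windows, dtype=np.int64).reshape(-1, 2)
    if n_reads == 0:
        return ReadIntervalSet(mark_name, stage_label, np.empty((0, 2), np.int64), [], 1)

    # density: 1 outside target windows, `factor` inside
    wlen = int((windows[:, 1] - windows[:, 0]).sum()) if len(windows) else 0
    total_weight = (clen - wlen) + factor * wlen
    p_target = factor * wlen / total_weight
    n_target = rng.binomial(n_reads, p_target)
    n_bg = n_reads - n_target

    def in_window(pos: np.ndarray) -> np.ndarray:
        if not len(windows):
            return np.zeros(len(pos), dtype=bool)
        k = np.searchsorted(windows[:, 0], pos, side="right") - 1
        k_ok = k >= 0
        return k_ok & (pos < windows[np.clip(k, 0, len(windows) - 1), 1])

    mid_bg = rng.integers(0, clen, size=n_bg)
    bad = in_window(mid_bg)
    while bad.any():  # rejection-sample the window complement
        mid_bg[bad] = rng.integers(0, clen, size=int(bad.sum()))
        bad = in_window(mid_bg)
    if len(windows) and n_target:
        wl = windows[:, 1] - windows[:, 0]
        widx = rng.choice(len(windows), size=n_target, p=wl / wl.sum())
        mid_t = windows[widx, 0] + rng.integers(0, wl[widx])
    else:
        mid_t = np.empty(0, dtype=np.int64)
    mids = np.concatenate([mid_bg, mid_t])
    rng.shuffle(mids)
    starts = np.clip(mids - read_length // 2, 0, clen - read_length)
    ivals = np.column_stack([starts, starts + read_length])
    return ReadIntervalSet(
        mark_name, stage_label, ivals, [chrom] * len(ivals), n_reads
    )


# ---------------------------------------------------------------------------
# motifs, GO, outcomes

def consensus_pwm(motif_id: str, consensus: str, weight: float = 100.0) -> PWM:
    idx = {b: i for i, b in enumerate("ACGT")}
    mat = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus.upper()):
        mat[idx[b], j] = weight
    return PWM(motif_id, mat)


def embed_motif(
    promoter_sequences: dict[str, str],
    consensus: str,
    gene_ids: list[str],
    seed: int = 0,
) -> dict[str, str]:
    """Plant one occurrence of ``consensus`` at a random offset in each
    designated promoter; returns a new sequence dict."""
    rng = np.random.default_rng(seed)
    out = dict(promoter_sequences)
    L = len(consensus)
    for g in gene_ids:
        seq = out[g]
        if len(seq) < L:
            continue
        off = int(rng.integers(0, len(seq) - L + 1))
        out[g] = seq[:off] + consensus.upper() + seq[off + L :]
    return out


def simulate_go_annotation(
    gene_ids: list[str],
    enriched_genes: list[str],
    n_terms: int = 50,
    terms_per_gene: float = 3.0,
    enriched_term: str = "GO:TEST0001",
    capture: float = 0.8,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene->terms map with one term planted in ``enriched_genes``."""
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    ann: dict[str, set[str]] = {}
    for g in gene_ids:
        k = rng.poisson(terms_per_gene)
        ann[g] = set(rng.choice(terms, size=min(k, n_terms), replace=False)) if k else set()
    for g in enriched_genes:
        if rng.random() < capture:
            ann.setdefault(g, set()).add(enriched_term)
    # background presence of the planted term at low rate
    for g in gene_ids:
        if g not in enriched_genes and rng.random() < 0.02:
            ann[g].add(enriched_term)
    return ann


def simulate_outcomes(
    rates: dict[str, dict[str, float]],
    denominators: dict[str, dict[str, int]],
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[OutcomeTable, pd.DataFrame]:
    """Binomial outcome counts per condition/transition plus replicate rates.

    ``rates[condition][transition]`` is the true success probability and
    ``denominators`` the attempted counts. Returns the pooled table and a
    long replicate-rate table for t-testing.
    """
    rng = np.random.default_rng(seed)
    rows, rep_rows = [], []
    for cond, trans in rates.items():
        for transition, p in trans.items():
            den = denominators[cond][transition]
            per_rep = np.maximum(den // n_replicates, 1)
            ks = rng.binomial(per_rep, p, size=n_replicates)
            num = int(ks.sum())
            den_eff = int(per_rep * n_replicates)
            rows.append(
                {
                    "condition": cond,
                    "transition": transition,
                    "numerator": num,
                    "denominator": den_eff,
                }
            )
            for k in ks:
                rep_rows.append(
                    {
                        "condition": cond,
                        "transition": transition,
                        "rate": 100.0 * k / per_rep,
                    }
                )
    return OutcomeTable(pd.DataFrame(rows)), pd.DataFrame(rep_rows)
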