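# Methods

## The model

`stagefx` quantifies how each step of an in vitro oogenesis protocol changes
gene expression in single oocytes. Oocytes come in seven cohorts defined by
origin and culture history — growing (GRO) and fully grown (FGO) oocytes
derived from iPSCs, from embryonic gonads (PGCs), from 6 dpp follicles, or
entirely in vivo. Each cohort is encoded by the set of culture steps it
passed: IVP (in vitro PGC specification), IVD (in vitro oocyte
differentiation) and IVG (in vitro growth). Expression at a given oocyte
stage is modelled as a linear combination of these step effects relative to
fully in vivo development:

    log2 E[count_gs] = beta0_g(stage) + sum_e beta_eg x_es + log2(lib_s / 10^6)

with exposure indicators `x_es` per sample:

| cohort      | IVP | IVD | IVG |
|-------------|-----|-----|-----|
| GRO_iPSC    | 1   | 1   | —   |
| GRO_PGC     | 0   | 1   | —   |
| GRO_invivo  | 0   | 0   | —   |
| FGO_iPSC    | 1   | 1   | 1   |
| FGO_PGC     | 0   | 1   | 1   |
| FGO_6dpp    | 0   | 0   | 1   |
| FGO_invivo  | 0   | 0   | 0   |

GRO and FGO samples are fitted separately (two and three estimable effects).
The key additivity assumption — e.g. that the iPSC-vs-in vivo difference in
GROs is IVP@GRO + IVD@GRO — is exact in this design because the exposure
rows of the intermediate cohorts identify each step separately.

Counts are negative binomial (NB2: variance mu + phi mu^2) with a log link
and natural-log library-size offsets. Each gene's GLM is fitted by IRLS
(relative deviance tolerance 1e-8, max 100 iterations; all genes sharing a
design are fitted in one vectorised sweep). Each effect is tested by a
likelihood-ratio test against the model with that column dropped, with the
gene's dispersion held fixed between full and reduced fits; p-values come
from chi^2 with 1 df and are Benjamini-Hochberg-corrected per effect. A gene
is called *affected* by a step when FDR <= 5% and |log2 fold-change| >= 2
(a threshold of 1 is used for the curated display variant).

### Dispersion estimation

Per-gene dispersion maximises the Cox-Reid adjusted profile likelihood on a
fixed log-spaced grid (41 points, 1e-4 to 10), refined by parabolic
interpolation through the winning grid point, then shrunk on the log scale
toward the all-gene maximiser with empirical-Bayes weight
`prior_df / (prior_df + residual_df)` (prior_df = 10), floored at 1e-6.
All-zero genes receive the common value and are flagged. This estimator is
this package's own design: on Poisson data (true phi = 0, 100 samples) the
median estimate is ~1e-4, and with true phi = 0.4 at 150 samples the median
is recovered within +/-0.01; the LRT built on it holds its nominal type-I
error (fraction of null genes with p < 0.05 inside [0.035, 0.065] at 2,000
genes), which is the property that matters downstream.

## Normalisation and filtering

RPKM divides counts by exonic length (kb) and library size (millions of
reads; spike-in rows prefixed `ERCC-` never enter library sizes or tests).
The log transform is `log2(RPKM + psc) - log2(psc)` with psc = 0.1, mapping
zero to exactly 0. Genes enter testing when CPM exceeds 1 (strictly) in at
least 3 samples. Relative expression subtracts the per-gene mean within each
stage (GRO and FGO separately); PCA runs on those gene-centred values
without unit-variance scaling.

## Dynamics groups and response clustering

The in vivo GRO-vs-FGO contrast (same NB-GLM/LRT machinery, explicit
reference level GRO) classifies genes as UP (FDR <= 5% and log2FC >= 1),
DN (<= -1), and otherwise LS or HS by whether mean logRPKM stays at or below
2 in both in vivo cohorts. The 1/2 thresholds and the expression cutoff are
package defaults, exposed in the config; a quantile mode (median split) is
available for the LS/HS boundary. Affected genes are sub-clustered on their
raw fitted 5-effect log2 vectors with seeded Lloyd k-means (k = 5, best of
20 restarts, clusters relabelled by descending IVD@GRO centroid); zeroing of
non-significant responses is a display rule applied only when writing report
tables, never before clustering.

## Promoter features

Promoters are TSS +/- 1.5 kb regardless of strand. Transitively overlapping
windows are resolved by keeping one window per overlap group uniformly at
random under a seed. CpG observed/expected uses the Gardiner-Garden-Frommer
form `(#CpG * L) / (#C * #G)` over non-N positions (0 when no C or no G).
CGI status comes from a two-component 1-D Gaussian mixture fitted by EM in
ratio space, initialised deterministically from the 25th/75th-percentile
split; a promoter is CGI when the posterior of the higher-mean component
exceeds 0.5. EM stops when the log-likelihood change falls below 1e-8
(relative); degenerate zero-variance input is rejected with a pointer to
threshold mode.

## Enrichment statistics

* Group enrichment: 2x2 chi^2 without continuity correction (expected counts
  are large here); enrichment reported as log2((obs+1)/(exp+1)) with
  expectations from the universe marginals; significant at p <= 1%.
* GO terms: one-sided hypergeometric upper tail; enrichment = obs/exp.
  Optional `elim` decorrelation (children first, genes of significant terms
  removed from ancestors) replaces the weight01 algorithm of the original
  tooling, which is out of scope. Term similarity is visualised by classical
  (Torgerson) MDS on pairwise Jaccard distances, orientation canonicalised.
* Motifs: PWMs become log2-odds matrices against background base frequencies
  after a 0.5 pseudo-count per cell. The hit threshold is the stated
  quantile (default 0.999) of the score distribution under an iid background
  computed exactly by dynamic programming on a 1e-3-discretised score grid
  (scanning tolerates the accumulated rounding, <= 1e-3 per position). Both
  strands are scanned; a promoter "hits" when any offset reaches the
  threshold. Binned enrichment tests each (motif, bin) against all other
  bins by one-sided Fisher, BH across all pairs, significant at FDR <= 1%.

## Chromatin marks

Reads are assigned to promoters by interval-midpoint containment (an
any-overlap mode exists; midpoint is the default because it cannot double
count across adjacent windows). Counts become log2 CPM with pseudo-count 16,
then Z-scores across promoters within each (mark, stage) sample. Affected
vs non-affected genes of the same dynamics group and CGI class are compared
with a two-sided Mann-Whitney test — exact null for combined n <= 12 without
ties, otherwise the normal approximation with tie and continuity correction
— BH-corrected across strata, significant at FDR <= 0.1%.

## Competence statistics

Pooled stage-transition rates are 100 * numerator / denominator rounded
half-up to one decimal (matching printed percentages; conditional
transitions use the previous stage's count as denominator). Replicate rates
are compared by unpaired two-tailed Student's t-tests with pooled variance
(df = n1 + n2 - 2); Welch's correction is deliberately not used because the
equal-variance test is the convention for these small balanced designs.
Degenerate zero-variance inputs return p = 1 (equal means) or p = 0 with an
infinite t (unequal means), flagged rather than erroring.

## What the synthetic generator emulates — and what it does not

`stagefx.synthetic` plants every structure the analysis is meant to find:

* 7 cohorts x 23 oocytes (the study scale; configurable down), library
  sizes uniform on 0.5-2 million reads, ~12,000 genes by default;
* NB2 counts with per-gene dispersion ~ Gamma(shape 4, mean 0.3) and
  additive per-step log2 effects of magnitude 2.5-4 planted in 2% of genes
  per effect, with UP-dynamics genes over-sampled 3:1 so affected genes are
  enriched for the UP group;
* dynamics groups LS/UP/DN/HS (35/25/20/20%) with a planted GRO->FGO log2
  shift >= 1.2 for UP/DN and baselines placing LS below and HS above the
  low-expression cutoff;
* promoter sequences from a first-order Markov chain whose C->G transition
  is calibrated by a fixed-point so realised CpG obs/exp matches the target
  (CGI ~ N(0.75, 0.08), non-CGI ~ N(0.25, 0.05), truncated positive);
* chromatin reads uniform outside merged target windows and enrich_factor x
  (default 8) denser inside them for repressive marks, 1/enrich_factor for
  active marks; Polycomb targets are the CGI promoters of affected genes;
* a plantable motif consensus, a GO term planted in a chosen gene set, and
  binomial outcome tables with known per-condition rates.

It does **not** emulate: amplification noise or dropout beyond NB
overdispersion, gene-length or GC biases, correlated gene modules, batch
or size-covariate effects on counts (diameters are drawn per cohort but do
not influence expression by default), multi-chromosome genomes, or read
mapping ambiguity. Passing tests therefore demonstrate correctness of the
estimators and tests under the assumed NB/additive model, not robustness to
real single-cell artefacts.

## Numerical choices

* IRLS: eta clipped to [-30, 30]; 1e-10 ridge on the normal equations; LRT
  statistics floored at 0; non-converged genes flagged and excluded from
  affected calls (reported in QC columns).
* BH is one shared routine used by every module; NaN p-values propagate
  without counting toward m.
* k-means ties and restart selection are delegated to seeded scikit-learn
  Lloyd iterations; reruns under one seed are bit-identical.
* Half-up rounding for printed rates uses decimal arithmetic to avoid
  binary-float round-to-even surprises.

## Problem sizes used by the shipped runs

The analysis walkthrough (`analysis/01...08`) runs at 2,000 genes x 161
oocytes so the full narrative completes in about a minute; the acceptance
suite exercises the generator's full default scale (12,000 genes, 23 per
cohort) for effect-recovery, 2,000 genes for the null calibration, and
600-1,000 genes for promoter/chromatin detection. These sizes are the
package's own choices for a desk-scale demonstration; all are configurable.

## Known limitations

* The dispersion estimator targets calibrated testing, not unbiased
  per-gene dispersion recovery at small n; with very few residual df the
  prior dominates.
* The exposure design cannot separate IVP from IVD using iPSC cohorts
  alone; identifiability rests on the intermediate PGC/6dpp cohorts being
  present, and `fit_stage_effects` will report rank errors otherwise
  (an all-zero effect column yields a null test instead).
* GO decorrelation implements `elim`, not `weight01`; results on deeply
  nested ontologies will differ from the original tooling.
* The motif threshold assumes an iid background; GC-matched backgrounds
  per bin are not implemented.
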