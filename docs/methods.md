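# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `phenogs`.

## Observation structure

The unit of analysis is a **line × environment cell**.  Field plots (a line
grown in one replicate of one trial) are first reduced to per-environment
BLUEs; all prediction models then operate on the cell table.  Incidence is
deliberately unbalanced: a line typically appears in 1.3–1.7 environments
(summarized as n_e, the mean number of environments per line) and fewer
than two replicates per cell (n_r).

## Marker processing

SNPs are coded 0/1/2 with missing calls.  Four quality rules are applied
simultaneously: missing rate < 0.5 (over all lines), minor-allele frequency
> 0.05, heterozygous-call rate < 0.05, and homozygous-call rate > 0.8 — the
latter three computed over non-missing calls.  The homozygosity rule's
denominator (non-missing calls) is our reading; only the threshold is
standard.  Filtering is idempotent and a per-rule rejection log is
returned.

Imputation defaults to the SNP-mean dosage.  A low-rank EM alternative
(mean fill, then iterated truncated-SVD reconstruction of the missing cells
to tolerance 1e-4 or 50 sweeps) is provided for data with structured
missingness; it is our own construction and is recorded in the run
manifest when chosen.

The genomic relationship matrix defaults to the uncentered Gram form
**G** = **MM**′/r; column-centering by 2p̂ is available
(`compute_grm(center=True)`) and is what the examples use, normalized to
mean diagonal 1 before modelling.  Matrix square roots are eigendecomposed
with negative eigenvalues (numerical noise) clipped at zero; the clipped
root satisfies ‖L·L − K‖_F < 1e-8 on PSD input.

## Radiometric calibration and spectral features

Two calibration protocols:

* **panel** — per band, ordinary least squares of panel reflectance on
  panel digital numbers (≥ 2 distinct panels required; slope must be
  positive); applied as SR = DN·slope + intercept, floored at 0.  The
  intercept keeps its regression sign.
* **single2019** — the visible and red-edge bands are calibrated as above;
  NIR is derived from quantum-efficiency coefficients,
  NIR = 2.921·Blue − 0.754·Red, floored at 0 and divided by 3.07 on the
  index-computation path.

Indices use the wavelength → band mapping R800 → NIR, R680 → Red,
R700 → RE1 (configurable).  NDVI and NDRE1 are computed from plot-mean
reflectance by default (per-pixel-then-average is available — the two
differ only at second order for homogeneous plots).  Canopy cover is the
mean over pixels of GNDVI = (NIR − Green)/(NIR + Green), exactly as
printed; a thresholded-fraction variant (share of pixels with GNDVI > 0.5)
is offered because "percent canopy coverage" often denotes a fraction, but
the mean-GNDVI form is the default.

The feature vector **H** holds the 8 calibrated band means plus NDRE1,
NDVI and canopy cover (11 values per cell); **I** is the sub-vector
(CanopyCover, NDRE1, NDVI).  Replicate plots of a cell are averaged.
Before entering any model, H/I columns are standardized to mean 0, sd 1
(means and scales are stored for exact round-tripping); the environment
one-hot block is left as 0/1.  Whether to standardize was an open choice;
we standardize because both PLS and ridge-type shrinkage are
scale-sensitive.

## Trial BLUEs and variance components

Within one environment the mixed model is

    alpha lattice:  y = mu + g_i + check_i + t_j + r_k(j) + b_l(jk) + e
    augmented RCBD: y = mu + g_i + check_i + b_j + e

with genotype and check effects fixed and the design factors random and
i.i.d. normal.  Estimation is EM-REML on Henderson's mixed-model equations:
variance updates sigma2_k = (u_k'u_k + sigma2_e tr(C_kk))/q_k and
sigma2_e = y'(y − Xb − Zu)/(n − rank X), iterated to a relative change
below 1e-6 (at most 500 iterations).  EM was chosen over
average-information REML for its guaranteed monotone restricted likelihood
(asserted in tests via a cheap MME-based likelihood identity) and its
robustness at desk scale; it converges more slowly near boundaries, where
variances are floored at 1e-10·Var(y).  Genotype BLUEs are reported as
intercept + effect under a sum-to-zero constraint over non-check
genotypes; random factors with a single level are dropped (confounded with
the intercept).

Across environments the BLUEs feed
y = mu + env (fixed) + g (random) + g×e (random) + e, and the entry-mean
heritability is

    H2 = s2_g / (s2_g + s2_ge/n_e + s2_e/(n_e·n_r)).

**Identifiability caveat:** with exactly one BLUE per cell the g×e and
residual design matrices coincide, so only s2_ge + s2_e is identified; the
recovery tests therefore use replicated cells.  The H² formula above is the
standard entry-mean form; it is documented rather than asserted against
any published table, since published heritabilities are frequently computed
with software-specific conventions that are not reconstructible from
variance components alone.

## Predictor sets

From the cell table we build one-hot incidences **X**_E (environments),
**Z**_g (lines) and **Z**_gE (cells).  Relatedness enters the
concatenated-matrix view by post-multiplication: **X**_g**L**_g with
**L**_g = **G**^1/2, and **X**_gE**L**_gE with
**L**_gE = **K**_gE^1/2, where **K**_gE = (**Z**_g**G Z**_g′) ∘
(**X**_E**X**_E′) over observed cells (∘ = Hadamard).  The G×E
relationship as a Hadamard product of the line kernel and the
environment-incidence kernel is the standard construction; only its square
root is named in the source material, so the kernel itself is our
reconstruction.  Genomic×spectral interactions are the row-wise Khatri–Rao
product in the matrix view and the Hadamard kernel product in the kernel
view — the canonical matched pair (Schur's product theorem keeps the
kernels PSD, checked to −1e-8).

The nine sets (environment block always present):

| set | blocks beyond X_E | kernels |
|-----|-------------------|---------|
| ETA1 | XgLg | K_g |
| ETA2 | XgLg, H | K_g, K_H |
| ETA3 | XgLg, H, XgELgE | K_g, K_H, K_gE |
| ETA4 | XgLg, H, XgELgE, XgLg:H | K_g, K_H, K_gE, K_g∘K_H |
| ETA5 | XgLg, I | K_g, K_I |
| ETA6 | XgLg, I, XgELgE | K_g, K_I, K_gE |
| ETA7 | XgLg, I, XgELgE, XgLg:I | K_g, K_I, K_gE, K_g∘K_I |
| ETA8 | H | K_H |
| ETA9 | I | K_I |

with K_H = H̃H̃′/11 and K_I = ĨĨ′/3 on the standardized features.  The
five sets evaluated under LOEO default to {ETA1, ETA8, ETA9, ETA3, ETA6}
(genomic only, spectral only, and the additive combinations with G×E) and
are configurable.

## Multi-kernel Bayesian GBLUP

Model: y = **X**β + Σ_k u_k + ε with u_k ~ N(0, σ²_k **K**_k) and
ε ~ N(0, σ²_e I); the environment one-hot **X** absorbs the intercept and
carries a flat prior.  Each kernel is eigendecomposed once
(**K** = **U**D**U**′, eigenvalues below 1e-10 of the maximum dropped) and
effects are sampled in the eigenbasis, where the conditional posterior is
diagonal — O(n·r_k) per term and sweep.  Variances carry
scaled-inverse-χ² priors with df = 5 and scale chosen so each term's prior
mode equals an equal share of 0.5·Var(y), and the residual's mode equals
the remaining half — the convention of the reference Bayesian GBLUP
software, whose exact hyperparameters are not published and are therefore
documented, not asserted.  Chain defaults: 12,000 iterations, 2,000
burn-in, thinning 5 (cross-validation uses shorter chains, see below).

Prediction uses the standard missing-value treatment: test rows are
included in the kernels, their responses masked and re-imputed from the
current model at every sweep.  The stored response values of masked rows
are never read (asserted bit-for-bit in tests).  Fixing all kernel
variances at zero collapses predictions to environment means; fixing them
at given values (the infinite-prior-df limit) reproduces the closed-form
BLUP posterior mean, which the tests verify against a direct-inversion
oracle — note the exact closed form uses the GLS estimate of the
intercept, not the raw mean.

## Kernel PLS

The univariate kernel algorithm: center X and y (column scaling optional,
off by default since the H/I blocks are standardized upstream); per
component w = X'y/‖X'y‖ (the univariate collapse of the dominant
eigenvector of SS′), t = Ew normalized, p = E′t, q = f′t, deflation
E ← E − tp′, f ← f − tq; then R = W(P′W)⁻¹, T = X_c R,
b = (T′T)⁻¹T′y_c on the **undeflated** centered response (the printed
formula; the deflated alternative gives identical b because the scores are
orthogonal), and B = Rb.  New-data predictions via X_new,c·B and via
T_new·b agree to machine precision and both are exposed.  Extraction stops
early when the deflated cross-product is numerically zero, recording the
achieved component count.

The component count is tuned by inner 10-fold cross-validation on
NRMSE = RMSE/sd(observed fold values) (sample sd; range and mean
denominators, or plain MSE, by configuration — per-fold rankings under MSE
and NRMSE can differ only through the averaging).  Ties resolve to the
smallest count.  Because the scores are orthogonal, one fit at a_max per
inner fold yields exact nested sub-model predictions for every a — the
tuning loop is a single pass.

## Cross-validation protocols

* **7FCV**: a uniformly random partition of cells into 7 folds (sizes
  differing by at most one; with n divisible by 7 the outer split is
  exactly 85.71 % / 14.29 %, and the nested inner 10-fold split leaves
  77.14 % inner-training and 8.57 % validation of all data).  Folds are
  drawn at the observation level, so a line can train in one environment
  and test in another — that is what "partially tested lines" means; a
  line-level folding option exists.  PLS re-tunes inside every outer
  training set and refits on the full outer-training set; GBLUP needs no
  tuning.  Per-environment accuracy is the mean over folds of within-fold
  within-environment Pearson correlations (cells with fewer than 3 test
  observations are skipped), with the SE over folds.  The Global accuracy
  correlates per-line means of observed and held-out predicted values over
  whatever environments each line has.
* **LOEO**: each environment is the test set exactly once, so each
  per-environment accuracy comes from a single fold (SE from the analytic
  large-sample formula).  The Global value is reported both pooled over
  all held-out predictions (default — it retains the unpredicted
  environment main effects that make untested environments genuinely hard)
  and as the average of per-environment correlations with its SE across
  environments.

Fold assignment and model randomness use independent seed streams spawned
from one user seed, so splits and chains decouple but the whole run is
reproducible.

## Synthetic-data generator

The generator emulates a breeding-program year: n_lines inbred lines
(SNP calls homozygous 0/2 at allele frequencies uniform on [0.05, 0.5],
~2 % residual heterozygous calls, missingness injected at a configurable
rate, plus a fraction of deliberately QC-failing SNPs — monomorphic,
> 50 % missing, > 5 % heterozygous); per-line environment subsets of size
1 + truncated Poisson targeting a configurable mean (the real-data range
is ~1.3–1.7); partial replication; alpha-lattice (trial/replicate/block)
or augmented (checks in every block) layouts.

Plot yield is mu + g + env + g×e + design + residual with the polygenic
value g = Mβ from the clean SNPs.  Every component's realized plot-level
variance is **rescaled to its nominal value exactly**, and the design and
residual draws are orthogonalized against the signal components first;
with only 3–8 environments the realized environment variance would
otherwise fluctuate by tens of percent and no per-seed heritability
statement could hold.  Consequently Var(g)/Var(y) equals the heritability
target up to the small residual covariance among g, env and g×e
(realized h² within ±0.05 of target per seed, ±0.03 on the mean).  The
default variance budget (in units of var_g = 1) is var_env = 0.5,
var_ge = 0.2, var_design = 0.06, residual solved from the h² target;
configurations whose budget leaves no residual variance are rejected.

Bands are affine in the standardized total plot value z = g + env + g×e:
band = base·(1 + 0.15·(s·z + √(1−s²)·noise)) with s = `spectral_signal`,
per-band canopy-plausible base reflectances, pixel samples (default 8 per
plot) with small additive pixel noise, emitted as raw DN through a known
per-band affine map that the calibration-panel table (five panels at
2–85 % reflectance) inverts exactly.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium (markers are
independent loci; GRM-based methods do not require LD realism, but
marker-density conclusions would not transfer), spatial field trends,
nonlinear band–yield relationships, band-specific environmental artifacts
(sun angle, cloud), genotype-specific canopy phenology, and measurement
error in the reference panels.

## Problem sizes in the shipped checks

The shipped test suite and acceptance script run at desk scale, chosen as
the smallest sizes at which the statistical statements are stable:
recovery simulations use 100–400 lines and 3–30 replicate seeds; the
qualitative multi-source comparison uses 220 lines × 4 environments ×
5 seeds with 1,500-iteration chains; the closed-form sampler check uses
n = 100 with 20,000 iterations.  All tolerances are stated next to the
corresponding checks.

## Known limitations

* EM-REML is slow near variance boundaries; estimates at the boundary are
  floored, not tested for significance.
* The G×E/residual confound on unreplicated cell tables (above) means the
  across-environment "G×E variance" from a standard BLUE table is a
  labelling of one EM fixed point of an unidentified sum.
* The Gibbs sampler assumes a Gaussian response; no marker-effect priors
  (BayesB-style) or multi-trait extensions.
* LOEO for predictor sets without genomic or spectral information about
  the held-out environment's lines is ill-posed and raises rather than
  extrapolating.
* No spatial (row/column) adjustment in the trial models, and no
  environmental-covariate kernels — environments enter only as dummies.
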