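# Methods

`radstab` studies how MRI intensity standardisation and the minimum batch
size (MBS) used for ComBat harmonisation affect the performance *and
stability* of clinical-radiomic Cox survival models in a multi-centre
setting. Because no patient data ships with the package, every stage is
exercised on synthetic cohorts with known ground truth; this note records
the models, the defaults and why, the numerical choices, and what the
synthetic experiments can and cannot show.

## The synthetic cohort

**Feature model.** Observed radiomic features follow the location–scale
batch-effect model that parametric ComBat assumes:

    x_ijg = alpha_g + age_ij * beta_g + gamma_ig + delta_ig * eps_ijg,
    eps_ijg ~ N(0, sigma_g^2),

with batch i, patient j, feature g; additive effects
`gamma_ig ~ N(0, batch_gamma_sd^2)` (default SD 0.5) and multiplicative
effects `delta_ig^2 ~ InverseGamma(50, 49)` (mean 1, i.e. ±15% scale
jitter), drawn per sequence. Because the generative model is exactly the
one ComBat fits, harmonisation is *falsifiable*: recovery tests compare
the fitted `gamma*` to the stored truth.

**Survival.** The prognostic signal is the patient-level biological
component `eps/sigma` of the first four features of the first sequence,
with true log hazard ratios (0.5, −0.4, 0.35, −0.3), plus a linear age
effect (0.02 per year, centred). Event times are Weibull proportional
hazards, `T = scale * (−log U / exp(eta))^(1/shape)` with shape 1.2 and
scale 17.6 months, giving a median overall survival near 13 months at
`eta = 0`. Censoring is uniform on `(0, c)` with `c` solved by root
finding so the expected censored fraction hits the target (default 14%,
i.e. ~86% events); administrative censoring at a fixed date was rejected
because it concentrates censoring at late times and distorts early-time
calibration tests. The real cohort's censoring mechanism is unknown, so
this is a modelling choice, not a reconstruction.

**Batch structure.** 195 patients in 15 unequal batches
(30…3 patients; several below five). Batches of ≥ 15 patients keep the
same membership across the four MRI sequences (one site, one stable
protocol); smaller batches get sequence-specific membership, emulating
acquisition-protocol variability. MBS exclusion therefore intersects
across sequences and removes 13% / 34% / 45% of the cohort at MBS
5 / 10 / 15 — the mechanism that makes raising the MBS a genuine
sample-size intervention. Age means differ across batches (61 ± 6 years
between batches, SD 8 within), so the one-way ANOVA screen that decides
whether age enters ComBat fires at p < 0.05, as it should for a
multi-centre cohort with differing referral populations.

**Phantoms.** Image-mode runs use simple geometric brain phantoms
(ellipsoidal brain, white-matter core, spherical tumour with an oedema
rim and enhancing core; per-sequence compartment means; Gaussian noise,
SD 4) with a per-batch scanner gain (0.7–1.4) and offset (±10) applied to
the intensities, and a second-rater tumour mask (slightly larger sphere)
for the ICC stage. They contain no MRI physics — no bias field, k-space
artefacts or motion — so image-mode results validate the *plumbing*
(standardisation, discretisation, extraction, filtering), not clinical
realism.

## Intensity standardisation

Three transforms plus the RAW identity control, each per sequence and
per patient, all monotone in intensity (rank-preserving, which is what
fixed-bin-number discretisation cares about):

* **Z-score**: subtract the whole-brain mean, divide by the whole-brain
  SD. Population (n) SD convention throughout, to avoid silent n−1 drift
  between implementations.
* **WhiteStripe**: find the white-matter mode of a kernel-smoothed
  (200-bin, sigma 2 bins) in-mask histogram — the highest-intensity local
  mode above 10% of the maximum peak for T1-like sequences, the global
  mode for T2-like — and standardise by the mean/SD of the "stripe", the
  intensities between quantiles F(mode) ± tau. Default tau = 0.05, the
  original method's convention.
* **Nyul histogram matching**: landmark percentiles
  {1, 10, 20, …, 90, 99} are linearly rescaled per training volume so the
  outer landmarks hit [1, 100], averaged across the cohort (all images of
  the sequence — deterministic, rather than "a few" arbitrarily chosen
  scans), and applied by piecewise-linear interpolation with terminal-
  slope extrapolation. Tied landmark intensities are collapsed before
  interpolation so the map stays well defined on spiky histograms.

## Radiomic features

384 features per image set: per sequence 18 first-order, 24 GLCM, 16
GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM (93 × 4 = 372), plus 12 shape features
of the whole-tumour mask attributed to the contrast-enhanced T1 sequence.
Conventions, where a choice had to be made: fixed-bin-number equal-width
discretisation over the in-mask range (affine-equivariant by
construction); GLCM/GLRLM over the 13 unique 3D direction offsets at
Chebyshev distance 1, symmetric, features computed per direction and
averaged; GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity;
the GLDM dependence count includes the centre voxel (j = 1 +
#equal-level neighbours) so size-zone-style formulas never divide by
zero. First-order Entropy/Uniformity use the discretised histogram;
the other first-order features use raw intensities. Shape features are
mask-only: mesh volume and surface area from marching cubes on the
0.5-level set, sphericity from those, maximum 3D and in-slice diameters
from convex-hull vertices, and axis lengths (4·sqrt eigenvalues of the
voxel-coordinate covariance) with elongation and flatness.

**ICC filter.** Features unstable across two independent segmentations
are removed when ICC(2,1) — two-way random effects, absolute agreement,
single measure, computed from the classical ANOVA decomposition — falls
below 0.8. Features with undefined ICC (no between-patient variance)
are removed and flagged. The filter is applied once per IST × bin
configuration.

## ComBat

Standard parametric empirical Bayes, per sequence, with age as the
biological covariate when the batch screen fires: least-squares location
fit with batch indicators and covariates, pooled residual variance,
standardisation, per-batch `gamma_hat` / `delta2_hat`, normal and
inverse-gamma priors with moment-matched hyperparameters, and the usual
iterative conditional-mode update (convergence 1e−6, ≤ 100 iterations).
Adjusted data are returned on the standardised-then-restored scale (no
reference batch). Batch–feature cells with zero within-batch variance
fall back to no scale adjustment, flagged. The implementation agrees
with Bioconductor `sva::ComBat` to ~1e−6 on a covariate-bearing fixture
(tested at 1e−3).

One behaviour worth stating explicitly: EB shrinkage does **not** force
post-adjustment batch means to be exactly equal — it removes the
estimated systematic effect and deliberately leaves a sampling-noise-
level residual (the no-shrinkage `eb=False` path equalises means to
machine precision). Batch-effect removal is therefore quantified by the
reduction of the between-batch ANOVA sum of squares (~96% under the
default effect sizes), not by exact mean equality.

**MBS filtering.** A patient is retained only if their batch reaches the
MBS for *every* sequence (intersection; a per-sequence mode exists).
ComBat is fitted once on the full retained cohort, outside the bootstrap
loop, mirroring the published pipeline order; the optimism this could
leak into "test" evaluations is shared by all settings being compared.

## Model building

Three model types: clinical-only (age, gender, MGMT methylation,
resection extent, adjuvant-treatment category, tumour diameter, and
log-transformed whole-tumour volume; categorical predictors dummy-coded),
radiomics-only (≤ 4 selected features), and combined (their union). A
Spearman collinearity filter (|rho| > 0.7; the offending pair's member
with the larger mean absolute correlation is dropped, name-order
tie-break) precedes the supervised strategies. The five selectors:

* **pca** — PCA on standardised features, Ward clustering of patients on
  the components covering ≥ 80% variance, cut at k = 2, features ranked
  by one-way ANOVA F across cluster labels; top 4. The "variation between
  clusters" measure is unspecified in the underlying description; ANOVA
  F is our choice.
* **forward / backward** — stepwise Efron-partial-likelihood AIC
  minimisation, capped at four features; backward keeps shrinking past
  the cap even at an AIC cost (the cap is an events-per-predictor
  constraint, not a fit criterion), then stops when no removal improves
  AIC. Deterministic name-order tie-breaks.
* **lasso** — L1-penalised Cox path (coxnet). "The largest penalty with
  ≤ 4 non-zero coefficients", read literally, is the fully-penalised null
  model; instead every support of size ≤ 4 on the path (plus the empty
  support) is a candidate and the winner minimises the extended BIC
  (gamma = 0.5) of an unpenalised refit. On pure-noise cohorts this
  returns the empty set in essentially every seed while strongly
  prognostic features always survive — the two behaviours the selector
  must have.
* **rsf** — random survival forest (default 500 trees, log-rank splits,
  ≥ 10 samples per leaf), features ranked by permutation importance
  (5 permutations per feature); top 4.

The Cox fitter is an in-package Newton–Raphson maximiser of the Efron
partial likelihood with step-halving, warm starts, a coefficient cap of
±20 under monotone likelihood (flagged), and the Breslow baseline
cumulative hazard. It matches lifelines to 1e−5 and a brute-force
grid-search oracle to 1e−4; it exists in-package because the bootstrap
engine needs ~1 ms fits (thousands per setting).

## Metrics

Discrimination: Harrell's C (usable pairs under right censoring, risk
ties = 1/2) and the Royston–Sauerbrei D — the Cox coefficient of the
PI's Blom rankits (constant 3/8, average ranks on ties) scaled by
1/kappa, kappa = sqrt(8/pi); explained variation
`R2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2)` (an enforced identity on
every metric set) and Nagelkerke's R2 on the partial likelihood; fit:
AIC = −2 logL + 2k; calibration: the slope of a Cox model with the
externally computed PI as sole covariate (exactly 1 on training data —
an MLE fixed point the tests assert), and the 1-year calibration curve:
predicted risk `1 − S0(12)^exp(PI)` from the Breslow baseline (1 year =
12 months on the study time scale, no IPCW), observed risk from a
secondary Cox fit on a 3-knot restricted cubic spline (knots at the 10th
/50th/90th percentiles) of `log(−log(1 − r_hat))`, read off on a
200-point grid. A fixed coefficient vector can fit new data worse than
the null; Nagelkerke's R2 is then floored at 0 and flagged rather than
reported negative.

## Bootstrap stability

Per experimental setting (IST × bin × ComBat × MBS; full grid 4·4·2·3 =
96), B with-replacement resamples (default 1000; experiments here use
100). Within each resample: collinearity filter, feature selection, and
model fits are *re-run from scratch* — selection is inside the loop,
never before it. Each model is evaluated on its resample (apparent) and
on the original cohort (test); the test value is the optimism-adjusted
quantity that summaries report, and both are stored so the optimism gap
is inspectable. Zero-event resamples are redrawn (counted); failed fits
are recorded as failures, never silently dropped. Summaries: per-metric
mean and percentile 2.5/97.5 CI over successful resamples; feature
co-occurrence = the modal selected set's share of non-empty selections,
per selector; calibration-curve families for instability plots; and the
clinical-centred heatmap transform (value − clinical mean) / SD across
models, sample SD, per setting. All randomness descends from one root
seed via per-setting SHA-256-derived seeds, so results are identical for
any subset or ordering of settings.

## Study sizes used by the shipped experiments

The replicated MBS experiment (`run_mbs_trend_study`) uses 15 synthetic
cohorts × 6 settings (ComBat on/off × MBS 5/10/15) × 100 resamples, with
forward selection on one sequence's five-feature block and combined
models only — about 9,000 model-building bootstrap iterations. Fifteen
replicate seeds keep the Monte-Carlo error of the seed-averaged
statistics well below the trend step sizes (~5 points of co-occurrence
per MBS step). Full five-selector, all-sequence, B = 1000 runs are
supported through the same `RunConfig` but cost roughly 1 s per resample
with the forest selector enabled.

## What the synthetic experiments show — and what they do not

They demonstrate, mechanically and with known truth: batch-effect
recovery improves with batch size (gamma RMSE falls across size classes
5–9 → 10–14 → ≥ 15); raising the MBS shrinks the cohort and degrades
stability (feature co-occurrence falls, bootstrap CI widths grow,
calibration-curve families spread); and with batch effects present,
harmonisation buys discrimination precisely where its parameters are
well estimated (MBS 15). These are the directional findings of the
multi-centre study the pipeline operationalises. They do **not** show
that any particular IST is superior on real MRI — the phantoms'
intensity distributions are far simpler than brain tissue — nor do the
absolute metric values transfer to clinical cohorts.

## Known limitations

* Feature-mode cohorts reuse one feature table across the IST and
  bin-count axes (those axes only label settings); IST/bin effects are
  exercised only in image mode.
* No wavelet/LoG filtered-image features, 2D extraction, DICOM input,
  non-parametric ComBat, ComBat-GAM, or time-varying covariates.
* The RSF permutation importance uses the forest's concordance on its
  training data, not out-of-bag error.
* ComBat outside the bootstrap loop (see above) slightly flatters all
  harmonised settings equally; moving it inside the loop is a one-line
  change in `prepare_setting` usage but multiplies cost by B.
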