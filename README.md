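# radstab

Stability of clinical-radiomic Cox survival models under MRI intensity
standardisation and ComBat minimum-batch-size choices.

## The problem

Radiomic survival models built on multi-centre brain MRI inherit two
nuisances: scanner-dependent intensity scales and batch effects in the
extracted features. Both have standard remedies — intensity
standardisation techniques (ISTs: Z-score, WhiteStripe, Nyul histogram
matching) before feature extraction, and ComBat empirical-Bayes
realignment afterwards — but ComBat needs enough patients per batch to
estimate its effects, so a *minimum batch size* (MBS) must be chosen,
and every patient in a smaller batch is discarded. Raising the MBS
trades better harmonisation against a smaller cohort, and the cost is
paid not only in average performance but in model *stability*: how much
the selected features, the metrics and the calibration curves vary
across bootstrap resamples.

`radstab` implements that whole evaluation as a reusable, tested
pipeline for researchers in radiomics and clinical prediction
modelling: synthetic multi-centre glioblastoma-like cohorts with known
ground truth (so every stage is verifiable without any data download),
the three ISTs, a 384-feature radiomic extractor, parametric ComBat with
MBS filtering, five feature-selection strategies feeding clinical /
radiomic / combined Cox models, and a bootstrap engine that measures
discrimination, calibration, explained variation, fit, and stability
across a 96-setting experimental grid (4 ISTs × 4 bin counts ×
ComBat on/off × MBS ∈ {5, 10, 15}).

## The models at the core

Features carry batch effects in the location–scale form ComBat assumes,

    x_ijg = α_g + age_ij β_g + γ_ig + δ_ig ε_ijg,   ε_ijg ~ N(0, σ_g²),

with empirical-Bayes posterior estimates γ*_ig, δ*²_ig removed per
sequence while covariate (age) effects are preserved. Survival follows
Weibull proportional hazards with prognostic index PI = Σ β_k x_k;
models are evaluated by Harrell's C, the Royston–Sauerbrei
D-statistic (Cox coefficient of the scaled rankits of PI, κ = √(8/π))
and its R²_D = (D²/κ²)/(π²/6 + D²/κ²), Nagelkerke's R², AIC, the
calibration slope, and 1-year calibration curves; stability by bootstrap
95% CI widths, feature co-occurrence (how often the identical feature
set is selected), and calibration-curve spread.

## A worked example

`examples/07_full_pipeline.py` runs the pipeline over four experimental
settings of one simulated 195-patient cohort (ComBat on/off × MBS 5/15,
Z-score IST, 32 bins, 40 bootstrap resamples, forward selection):

```
ZS_bin32_nocombat_mbs5       n=169 retention=87% cooccurrence=28%
ZS_bin32_nocombat_mbs15      n=108 retention=55% cooccurrence=18%
ZS_bin32_combat_mbs5         n=169 retention=87% cooccurrence=25%
ZS_bin32_combat_mbs15        n=108 retention=55% cooccurrence=28%

combined-model test C-index by setting:
ist  bin_count  combat  mbs     mean       lo       hi
 ZS         32   False    5 0.685131 0.651143 0.703737
 ZS         32   False   15 0.731441 0.675550 0.752496
 ZS         32    True    5 0.697152 0.671086 0.713560
 ZS         32    True   15 0.736661 0.705045 0.753546
```

Reading it: raising the MBS from 5 to 15 discards 61 patients
(retention 87% → 55%); feature selection becomes less repeatable without
harmonisation (co-occurrence 28% → 18%), while ComBat at MBS 15 — where
its batch parameters are well estimated — delivers the best mean test
C-index (0.737). The other examples each demonstrate one capability
(cohort simulation, ISTs, feature extraction, ComBat, model building,
bootstrap stability) and print a short interpretation line.

## Layout

```
src/radstab/      synthetic, ist, features, combat, cox, metrics,
                  selection, stability, pipeline
examples/         one narrative script per capability
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, defaults, numerical choices, limitations
```
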