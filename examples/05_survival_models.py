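"""Build and evaluate clinical, radiomic and combined Cox models.

After collinearity filtering, each of the five selection strategies
nominates at most four radiomic features; the combined model joins them
with the clinical predictors (age, gender, MGMT status, resection,
adjuvant treatment, diameter, log whole-tumour volume).  The printed
metrics are apparent (training-data) values: Harrell's C, the
Royston-Sauerbrei D and its R2_D, Nagelkerke's R2, AIC and the
calibration slope (exactly 1 on training data, by construction).
"""

from radstab import (CohortConfig, build_design, clinical_design,
                     collinearity_filter, evaluate_model, fit_model,
                     generate_feature_cohort, select_features)

config = CohortConfig(seed=4)
features, _, clinical, survival, truth = generate_feature_cohort(config)
time, event = survival["time"], survival["event"]

t1w = features.sequence_block("T1W")
filtered = collinearity_filter(t1w, threshold=0.7)
design_clin = clinical_design(clinical)

print(f"{'model':<22} {'C':>6} {'D':>6} {'R2_D':>6} {'R2_N':>6} {'AIC':>8} {'slope':>6}")

def report(label, design):
    model = fit_model(design, time, event)
    m = evaluate_model(model, design[model.predictor_names], time, event)
    print(f"{label:<22} {m.c_index:6.3f} {m.d_statistic:6.3f} {m.r2_d:6.3f} "
          f"{m.r2_nagelkerke:6.3f} {m.aic:8.1f} {m.calibration_slope:6.3f}")

report("clinical-only", design_clin)
for method in ("pca", "forward", "backward", "lasso", "rsf"):
    selected = select_features(filtered, time, event, method, rsf_trees=100)
    if not selected:
        print(f"{method}: empty selection (falls back to clinical-only)")
        continue
    report(f"combined ({method})",
           build_design("combined", design_clin, features, selected))
print(f"\nplanted prognostic features: {truth.prognostic_feature_ids}")
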