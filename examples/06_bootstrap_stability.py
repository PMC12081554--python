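"""Assess model stability with the bootstrap engine.

Fits models on 60 with-replacement resamples of a prepared cohort and
evaluates each on the original cohort (the optimism-adjusted "test"
value).  The printout shows, per metric, the resample mean and percentile
95% CI, the feature co-occurrence percentage (how often the identical
feature set was selected — a selection-stability statistic), and the
apparent-vs-test C-index gap (the optimism the bootstrap corrects for).
"""

import numpy as np

from radstab import (CohortConfig, ExperimentSetting, bootstrap_run,
                     generate_feature_cohort, summarise)
from radstab.pipeline import prepare_setting

config = CohortConfig(seed=19)
features, batch_maps, clinical, survival, _ = generate_feature_cohort(config)
setting = ExperimentSetting("RAW", 32, combat=False, mbs=5)
feats, design_clin, surv, _ = prepare_setting(
    setting, features, batch_maps, clinical, survival)
t1w = [c for c in feats.feature_names if c.startswith("T1W")]

records = bootstrap_run(feats.subset(feature_names=t1w), design_clin, surv,
                        B=60, seed=1, fs_methods=("forward",))
summary = summarise(records, setting)

print(f"resamples: {summary.n_resamples}, with failures: {summary.n_failures}")
print(f"feature co-occurrence (forward): {summary.cooccurrence['forward']:.0f}%")
for metric in ("c_index", "calibration_slope", "d_statistic"):
    row = summary.metrics.loc[("combined", "forward", metric)]
    print(f"test {metric:<18} mean {row['mean']:6.3f}  "
          f"95% CI ({row['lo']:.3f}, {row['hi']:.3f})")

key = ("combined", "forward")
apparent = np.mean([r["models"][key]["apparent"].c_index
                    for r in records
                    if r["resample_id"] != "original" and key in r["models"]])
test = float(summary.metrics.loc[("combined", "forward", "c_index"), "mean"])
print(f"apparent C {apparent:.3f} vs test C {test:.3f} "
      f"(optimism {apparent - test:+.3f})")
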