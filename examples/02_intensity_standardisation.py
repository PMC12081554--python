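"""Standardise phantom MRI intensities with the three ISTs.

Builds six brain phantoms whose two acquisition batches differ by a
scanner gain and offset, then applies Z-score, WhiteStripe and Nyul
histogram matching to the T1-weighted volumes.  The printed numbers show
the between-batch difference in mean white-matter intensity before and
after each transform: a good IST drives it towards zero, and all three
preserve the voxel rank order exactly.
"""

import numpy as np

from radstab import CohortConfig, apply_ist, generate_phantom_volumes

config = CohortConfig(
    n_patients=6, batch_size_distribution=(3, 3), n_batches_per_sequence=2,
    age_mean_by_batch=(58.0, 64.0), shared_batch_threshold=100, seed=7)
volume_sets = generate_phantom_volumes(config)

def batch_gap(volumes):
    wm_means = [v[vs.masks["nawm"]].mean()
                for vs, v in zip(volume_sets, volumes)]
    return abs(np.mean(wm_means[:3]) - np.mean(wm_means[3:]))

raw = [vs.volumes["T1W"] for vs in volume_sets]
print(f"RAW  between-batch WM-mean gap: {batch_gap(raw):8.3f}")
for method in ("ZS", "WS", "HM"):
    out = apply_ist(method, volume_sets, "T1W")
    print(f"{method:<4} between-batch WM-mean gap: {batch_gap(out):8.3f}")
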