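"""Intensity standardisation techniques (ISTs) for brain MRI volumes.

Three transforms conform per-scanner intensity scales before feature
extraction, each applied per sequence and per patient:

* Z-score — subtract the whole-brain mean and divide by the whole-brain
  standard deviation (population convention).
* WhiteStripe — locate the normal-appearing white-matter intensity mode
  and standardise by the mean/SD of the "white stripe", the intensity band
  within +/- tau quantiles of the mode.
* Nyul histogram matching — learn a standard histogram by averaging
  landmark percentiles over training scans, then map each volume's
  landmarks onto it piecewise-linearly.

All three are monotone (rank-preserving) intensity maps; the RAW control
is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

DEFAULT_LANDMARKS = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                     60.0, 70.0, 80.0, 90.0, 99.0)
DEFAULT_STANDARD_RANGE = (1.0, 100.0)

#: sequences whose white matter is the brightest major tissue class
T1_LIKE = {"T1W", "T1CE"}


def raw_standardise(volume: np.ndarray, brain_mask=None) -> np.ndarray:
    """Identity control ("RAW"): returns an unmodified copy."""
    return np.array(volume, dtype=float, copy=True)


def zscore_standardise(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """(volume - mean_brain) / sd_brain, applied to every voxel."""
    mask = np.asarray(brain_mask, bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    vals = np.asarray(volume, float)[mask]
    mu = vals.mean()
    sd = vals.std()  # population (n) convention
    if sd == 0:
        raise ValueError("zero in-mask variance")
    return (np.asarray(volume, float) - mu) / sd


def _histogram_modes(vals: np.ndarray, n_bins: int = 200, smooth_sigma: float = 2.0):
    """Local maxima of a kernel-smoothed in-mask intensity histogram.

    Returns (mode_centres, mode_heights) sorted by intensity.
    """
    hist, edges = np.histogram(vals, bins=n_bins)
    smooth = gaussian_filter1d(hist.astype(float), smooth_sigma)
    centres = (edges[:-1] + edges[1:]) / 2.0
    interior = np.arange(1, n_bins - 1)
    is_peak = (smooth[interior] >= smooth[interior - 1]) & \
              (smooth[interior] > smooth[interior + 1])
    peaks = interior[is_peak]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
    return centres[peaks], smooth[peaks]


def whitestripe_standardise(volume: np.ndarray, brain_mask: np.ndarray,
                            sequence_type: str = "T1-like",
                            stripe_width_tau: float = 0.05,
                            return_info: bool = False):
    """Standardise by the mean/SD of the white-matter intensity stripe.

    The white-matter mode is taken from a smoothed in-mask histogram: the
    largest-intensity local mode whose height exceeds 10% of the maximum
    peak for T1-like sequences (white matter is bright), the overall
    largest mode for T2-like ones.  The stripe is the in-mask intensity
    set between quantiles F(mode) +/- tau.
    """
    if not (0 < stripe_width_tau < 0.5):
        raise ValueError("stripe_width_tau must be in (0, 0.5)")
    if sequence_type not in ("T1-like", "T2-like"):
        raise ValueError("sequence_type must be 'T1-like' or 'T2-like'")
    mask = np.asarray(brain_mask, bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    vals = np.asarray(volume, float)[mask]
    if vals.max() == vals.min():
        raise ValueError("constant in-mask intensities")
    modes, heights = _histogram_modes(vals)
    if sequence_type == "T1-like":
        major = heights >= 0.10 * heights.max()
        mu_ws = modes[major][-1]
    else:
        mu_ws = modes[int(np.argmax(heights))]
    # empirical quantile of the mode, then the stripe band
    f_mode = np.mean(vals <= mu_ws)
    lo_q = max(f_mode - stripe_width_tau, 0.0)
    hi_q = min(f_mode + stripe_width_tau, 1.0)
    lo, hi = np.quantile(vals, [lo_q, hi_q])
    stripe = vals[(vals >= lo) & (vals <= hi)]
    if stripe.size == 0:
        raise ValueError("empty white stripe")
    mu = stripe.mean()
    sd = stripe.std()  # population convention
    if sd == 0:
        raise ValueError("zero stripe variance")
    out = (np.asarray(volume, float) - mu) / sd
    if return_info:
        return out, {"mode": float(mu_ws), "stripe_lo": float(lo),
                     "stripe_hi": float(hi), "stripe_mean": float(mu),
                     "stripe_sd": float(sd)}
    return out


# --------------------------------------------------------------------------
# Nyul histogram matching

@dataclass
class StandardHistogram:
    """Learned standard scale for Nyul histogram matching."""

    landmark_percentiles: tuple
    standard_scale_values: tuple
    intensity_range: tuple

    def __post_init__(self):
        p = np.asarray(self.landmark_percentiles, float)
        s = np.asarray(self.standard_scale_values, float)
        if len(p) != len(s):
            raise ValueError("percentiles and scale values differ in length")
        if not np.all(np.diff(p) > 0) or p.min() <= 0 or p.max() >= 100:
            raise ValueError("percentiles must be strictly increasing in (0, 100)")
        if np.any(np.diff(s) < 0):
            raise ValueError("standard scale values must be non-decreasing")
        self.landmark_percentiles = tuple(p)
        self.standard_scale_values = tuple(s)
        self.intensity_range = tuple(map(float, self.intensity_range))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "landmark_percentiles": list(self.landmark_percentiles),
                "standard_scale_values": list(self.standard_scale_values),
                "intensity_range": list(self.intensity_range),
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StandardHistogram":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["landmark_percentiles"]),
                   tuple(d["standard_scale_values"]),
                   tuple(d["intensity_range"]))


def nyul_train(volumes, masks,
               landmark_percentiles=DEFAULT_LANDMARKS,
               standard_range=DEFAULT_STANDARD_RANGE) -> StandardHistogram:
    """Learn the standard histogram from training volumes.

    Each volume's in-mask landmark intensities are linearly rescaled so the
    outer landmarks hit the standard range; the standard scale is the
    per-landmark mean across volumes.  Rescaled landmarks are affine
    invariant, so scans differing only by gain/offset train identically.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 training volumes")
    p = np.asarray(landmark_percentiles, float)
    if not np.all(np.diff(p) > 0) or p.min() <= 0 or p.max() >= 100:
        raise ValueError("percentiles must be strictly increasing in (0, 100)")
    s_min, s_max = standard_range
    rescaled = []
    for vol, mask in zip(volumes, masks):
        vals = np.asarray(vol, float)[np.asarray(mask, bool)]
        lm = np.percentile(vals, p)
        if lm[-1] == lm[0]:
            raise ValueError("degenerate (constant) training volume")
        rescaled.append(s_min + (lm - lm[0]) * (s_max - s_min) / (lm[-1] - lm[0]))
    scale = np.mean(rescaled, axis=0)
    return StandardHistogram(tuple(p), tuple(scale), (float(s_min), float(s_max)))


def nyul_apply(volume: np.ndarray, mask: np.ndarray,
               hist: StandardHistogram) -> np.ndarray:
    """Map a volume onto the standard scale.

    The volume's own in-mask landmark intensities are sent to the standard
    scale values, with linear interpolation between adjacent landmarks and
    linear extrapolation using the terminal segment slopes outside them.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(volume, float)[mask]
    xp = np.percentile(vals, hist.landmark_percentiles)
    fp = np.asarray(hist.standard_scale_values)
    if np.any(np.diff(xp) < 0) or xp[-1] == xp[0]:
        raise ValueError("degenerate landmark intensities")
    # collapse ties so interpolation is well defined, keeping monotonicity
    keep = np.concatenate([[True], np.diff(xp) > 0])
    xp_u, fp_u = xp[keep], fp[keep]
    out = np.interp(np.asarray(volume, float), xp_u, fp_u)
    # linear extrapolation with terminal slopes
    v = np.asarray(volume, float)
    lo_slope = (fp_u[1] - fp_u[0]) / (xp_u[1] - xp_u[0])
    hi_slope = (fp_u[-1] - fp_u[-2]) / (xp_u[-1] - xp_u[-2])
    below = v < xp_u[0]
    above = v > xp_u[-1]
    out[below] = fp_u[0] + (v[below] - xp_u[0]) * lo_slope
    out[above] = fp_u[-1] + (v[above] - xp_u[-1]) * hi_slope
    return out


# --------------------------------------------------------------------------
# dispatch

IST_NAMES = ("RAW", "ZS", "WS", "HM")


def apply_ist(method: str, volume_sets, sequence: str,
              stripe_width_tau: float = 0.05,
              landmark_percentiles=DEFAULT_LANDMARKS,
              standard_range=DEFAULT_STANDARD_RANGE) -> list[np.ndarray]:
    """Apply one IST to one sequence across a cohort of VolumeSet objects.

    HM (Nyul) trains its standard histogram on all cohort images of the
    sequence; ZS and WS act per patient.  Returns the transformed volumes
    in cohort order.
    """
    vols = [vs.volumes[sequence] for vs in volume_sets]
    brains = [vs.masks["brain"] for vs in volume_sets]
    if method == "RAW":
        return [raw_standardise(v) for v in vols]
    if method == "ZS":
        return [zscore_standardise(v, m) for v, m in zip(vols, brains)]
    if method == "WS":
        st = "T1-like" if sequence in T1_LIKE else "T2-like"
        return [whitestripe_standardise(v, m, st, stripe_width_tau)
                for v, m in zip(vols, brains)]
    if method == "HM":
        hist = nyul_train(vols, brains, landmark_percentiles, standard_range)
        return [nyul_apply(v, m, hist) for v, m in zip(vols, brains)]
    raise ValueError(f"unknown IST {method!r}")
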