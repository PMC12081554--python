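"""Synthetic multi-centre glioblastoma-like cohorts with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`generate_phantom_volumes` — simple 3D brain phantoms (four MRI
  sequences with grey/white-matter, oedema and tumour-core compartments,
  Gaussian noise, and a per-batch scanner gain/offset) with brain, NAWM,
  core and whole-tumour masks.
* :func:`generate_feature_cohort` — a radiomic feature table contaminated
  by additive/multiplicative batch effects under the location-scale model
  that ComBat assumes, together with clinical covariates and survival.
* :func:`simulate_survival` — Weibull-baseline proportional-hazards event
  times with uniform right-censoring calibrated to a target fraction.

Defaults mirror a realistic multi-centre glioblastoma cohort: 195 patients
in 15 unequal batches (some below five patients), ~86% events and a median
overall survival near 13 months.  Age means differ across batches so that
the age-batch association the harmonisation stage screens for is present
by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .combat import BatchMap
from .features import SEQUENCES, FeatureTable

# 15 unequal batches summing to 195, some below five patients.  Large
# batches (>= 15) share membership across the four sequences (same site,
# stable protocol); smaller batches get sequence-specific membership, so
# minimum-batch-size exclusion accumulates across sequences and the
# modelling cohort shrinks substantially as the threshold rises.
DEFAULT_BATCH_SIZES = (30, 25, 21, 17, 15, 14, 13, 12, 11, 10, 8, 7, 5, 4, 3)


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    Batch effects follow the ComBat generative model: additive effects
    gamma_ig ~ N(0, batch_gamma_sd^2) and multiplicative effects
    delta2_ig ~ InverseGamma(batch_delta_shape, batch_delta_scale), both
    drawn per batch x feature.  Survival is driven by the patient-level
    biological component of the first ``n_true_prognostic_features``
    features plus a linear age effect.
    """

    n_patients: int = 195
    n_batches_per_sequence: int = len(DEFAULT_BATCH_SIZES)
    batch_size_distribution: tuple = DEFAULT_BATCH_SIZES
    batch_gamma_sd: float = 0.5
    batch_delta_shape: float = 50.0
    batch_delta_scale: float = 49.0   # mean delta^2 = scale/(shape-1) = 1
    n_features: int = 20
    n_true_prognostic_features: int = 4
    true_log_hazard_ratios: tuple = (0.5, -0.4, 0.35, -0.3)
    weibull_shape: float = 1.2
    weibull_scale: float = 17.6       # months; median OS ~ 13 at eta = 0
    censoring_fraction_target: float = 0.14
    age_mean_by_batch: tuple | None = None   # default: spread around 61
    age_sd: float = 8.0
    age_log_hr: float = 0.02          # per year, centred at the cohort mean
    feature_sigma_range: tuple = (0.8, 1.2)  # residual SD sigma_g
    alpha_range: tuple = (-1.0, 1.0)         # feature intercepts
    beta_age_sd: float = 0.01                # per-feature age slopes
    grid_size: int = 32
    noise_sd: float = 4.0             # voxel noise in phantom volumes
    shared_batch_threshold: int = 15  # batches this big are sequence-shared
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.batch_size_distribution)
        if sum(sizes) != self.n_patients:
            raise ValueError("batch sizes must sum to n_patients")
        if len(sizes) != self.n_batches_per_sequence:
            raise ValueError("batch size list length != n_batches_per_sequence")
        if not (0 <= self.censoring_fraction_target < 1):
            raise ValueError("censoring_fraction_target must be in [0, 1)")
        for name in ("batch_gamma_sd", "batch_delta_shape", "batch_delta_scale",
                     "weibull_shape", "weibull_scale", "age_sd"):
            if getattr(self, name) < 0 or (
                    name != "batch_gamma_sd" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if len(self.true_log_hazard_ratios) != self.n_true_prognostic_features:
            raise ValueError("one log hazard ratio per prognostic feature")
        if self.n_true_prognostic_features > self.n_features:
            raise ValueError("more prognostic features than features")
        self.batch_size_distribution = sizes
        if self.age_mean_by_batch is None:
            rng = np.random.default_rng(self.seed + 1)
            self.age_mean_by_batch = tuple(
                61.0 + rng.uniform(-6, 6, len(sizes)))
        elif len(self.age_mean_by_batch) != len(sizes):
            raise ValueError("one age mean per batch")

    @property
    def batch_labels(self) -> list[str]:
        return [f"b{i:02d}" for i in range(len(self.batch_size_distribution))]

    @property
    def patient_ids(self) -> list[str]:
        return [f"p{i:03d}" for i in range(self.n_patients)]


@dataclass
class GroundTruth:
    """Stored simulation truth, used by recovery tests."""

    gamma: dict          # sequence -> (I, G) additive batch effects
    delta2: dict         # sequence -> (I, G) multiplicative batch effects
    alpha: np.ndarray    # (G,) feature intercepts
    beta_age: np.ndarray  # (G,) per-feature age slopes
    sigma: np.ndarray    # (G,) residual SDs
    prognostic_feature_ids: list
    eta: pd.Series       # per-patient true linear predictor
    censoring_bound: float = np.inf

    def to_json(self, path) -> None:
        payload = {
            "gamma": {k: v.tolist() for k, v in self.gamma.items()},
            "delta2": {k: v.tolist() for k, v in self.delta2.items()},
            "alpha": self.alpha.tolist(),
            "beta_age": self.beta_age.tolist(),
            "sigma": self.sigma.tolist(),
            "prognostic_feature_ids": list(self.prognostic_feature_ids),
            "eta": {str(k): float(v) for k, v in self.eta.items()},
            "censoring_bound": float(self.censoring_bound),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# batch assignment and clinical covariates

def assign_batches(config: CohortConfig) -> dict[str, BatchMap]:
    """Seeded patient -> batch partition per sequence.

    Batches of at least ``shared_batch_threshold`` patients keep identical
    membership across the four sequences (one site, one stable protocol).
    Membership of smaller batches is permuted per sequence, emulating
    acquisition-protocol variability: the same patient can sit in
    different small batches for different sequences, so minimum-batch-size
    exclusion intersected over sequences removes more patients than any
    single sequence would.  Batch sizes equal the configured distribution
    for every sequence.
    """
    base = np.repeat(config.batch_labels, config.batch_size_distribution)
    small = {lab for lab, sz in zip(config.batch_labels,
                                    config.batch_size_distribution)
             if sz < config.shared_batch_threshold}
    pool = np.flatnonzero(np.isin(base, list(small)))
    ids = pd.Index(config.patient_ids)
    maps = {}
    for k, seq in enumerate(SEQUENCES):
        rng = np.random.default_rng([config.seed, 7, k])
        assign = base.copy()
        assign[pool] = base[rng.permutation(pool)]
        maps[seq] = BatchMap(seq, pd.Series(assign, index=ids))
    return maps


def _clinical_table(config: CohortConfig, rng, batch_of) -> pd.DataFrame:
    n = config.n_patients
    means = dict(zip(config.batch_labels, config.age_mean_by_batch))
    age = np.array([rng.normal(means[batch_of[p]], config.age_sd)
                    for p in config.patient_ids])
    diam = rng.gamma(8.0, 0.55, n)                       # cm, median ~ 4.4
    wtv = np.exp(rng.normal(np.log(100), 0.6, n))        # cm^3
    return pd.DataFrame({
        "age": age,
        "gender": rng.binomial(1, 0.37, n),              # 1 = female
        "mgmt_methylated": rng.binomial(1, 0.36, n),
        "resection": rng.choice(["biopsy", "lt90", "ge90", "total"],
                                n, p=[0.23, 0.24, 0.32, 0.21]),
        "adjuvant": rng.choice(["none", "partial", "full"],
                               n, p=[0.52, 0.25, 0.23]),
        "diameter_cm": diam,
        "wtv_cm3": wtv,
    }, index=pd.Index(config.patient_ids, name="patient_id"))


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for the clinical-only Cox model.

    Categorical resection/adjuvant levels are dummy-coded and the
    whole-tumour volume enters log-transformed.
    """
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"]
    out["gender"] = clinical["gender"]
    out["mgmt_methylated"] = clinical["mgmt_methylated"]
    for lev in ("lt90", "ge90", "total"):
        out[f"resection_{lev}"] = (clinical["resection"] == lev).astype(float)
    for lev in ("partial", "full"):
        out[f"adjuvant_{lev}"] = (clinical["adjuvant"] == lev).astype(float)
    out["diameter_cm"] = clinical["diameter_cm"]
    out["log_wtv"] = np.log(clinical["wtv_cm3"])
    return out


# --------------------------------------------------------------------------
# survival

def simulate_survival(eta, config: CohortConfig, rng=None) -> pd.DataFrame:
    """Weibull proportional-hazards event times with uniform censoring.

    T = scale * (-log U / exp(eta))^(1/shape); censoring C ~ Uniform(0, c)
    with c solved so that the expected censored fraction matches
    ``config.censoring_fraction_target``.  Returns a DataFrame with
    ``time`` (> 0) and ``event`` columns.
    """
    eta = pd.Series(eta)
    vals = eta.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("eta must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    u = rng.uniform(size=len(vals))
    t = config.weibull_scale * (-np.log(u) / np.exp(vals)) ** (1.0 / config.weibull_shape)
    t = np.maximum(t, 1e-9)
    target = config.censoring_fraction_target
    if target <= 0:
        return (pd.DataFrame({"time": t, "event": np.ones(len(t), int)},
                             index=eta.index), np.inf)

    def f(c):
        # subject i is censored iff C < T_i; with C ~ U(0, c) that has
        # probability min(T_i/c, 1), so calibrate the mean to the target
        return np.mean(np.minimum(t / c, 1.0)) - target

    # f decreasing in c; bracket
    lo, hi = 1e-6, float(t.max()) * 2
    if f(hi) > 0:
        hi = float(t.max()) / target * 2
    c = optimize.brentq(f, lo, hi)
    cens = rng.uniform(0, c, len(t))
    event = (t <= cens).astype(int)
    time = np.minimum(t, cens)
    return pd.DataFrame({"time": np.maximum(time, 1e-9), "event": event},
                        index=eta.index), c


# --------------------------------------------------------------------------
# feature-level cohort

def generate_feature_cohort(config: CohortConfig):
    """Simulate a harmonisation-ready feature cohort with known truth.

    Per sequence s and feature g the observed value is

        x_ijg = alpha_g + age_ij * beta_g + gamma_ig + delta_ig * eps_ijg

    with eps_ijg ~ N(0, sigma_g^2).  The patient-level standardised
    residual eps/sigma of the first ``n_true_prognostic_features`` features
    of the *first* sequence carries the prognostic signal; survival is
    simulated from eta = sum_k theta_k * (eps/sigma)_k + age effect.

    Returns (FeatureTable, {sequence: BatchMap}, clinical DataFrame,
    survival DataFrame, GroundTruth).
    """
    rng = np.random.default_rng(config.seed)
    batch_maps = assign_batches(config)
    batch_of = batch_maps[SEQUENCES[0]].assignments
    clinical = _clinical_table(config, rng, batch_of)
    age = clinical["age"].to_numpy()
    age_c = age - age.mean()

    G = config.n_features
    I = config.n_batches_per_sequence
    n = config.n_patients
    alpha = rng.uniform(*config.alpha_range, G)
    sigma = rng.uniform(*config.feature_sigma_range, G)
    beta_age = rng.normal(0.0, config.beta_age_sd, G)

    gamma_by_seq = {}
    delta2_by_seq = {}
    blocks = []
    eta = np.zeros(n)
    prog_ids: list[str] = []
    theta = np.asarray(config.true_log_hazard_ratios, float)
    for si, seq in enumerate(SEQUENCES):
        batch_idx = pd.Categorical(
            batch_maps[seq].assignments.loc[config.patient_ids],
            categories=config.batch_labels).codes
        gamma = rng.normal(0.0, config.batch_gamma_sd, size=(I, G))
        # delta^2 ~ InverseGamma(shape, scale): 1 / Gamma(shape, 1/scale)
        delta2 = 1.0 / rng.gamma(config.batch_delta_shape,
                                 1.0 / config.batch_delta_scale, size=(I, G))
        eps = rng.normal(0.0, 1.0, size=(n, G)) * sigma[None, :]
        x = (alpha[None, :] + age_c[:, None] * beta_age[None, :]
             + gamma[batch_idx, :] + np.sqrt(delta2)[batch_idx, :] * eps)
        names = [f"{seq}_sim_f{g:03d}" for g in range(G)]
        blocks.append(pd.DataFrame(x, index=config.patient_ids, columns=names))
        gamma_by_seq[seq] = gamma
        delta2_by_seq[seq] = delta2
        if si == 0 and config.n_true_prognostic_features:
            k = config.n_true_prognostic_features
            eta += (eps[:, :k] / sigma[None, :k]) @ theta
            prog_ids = names[:k]
    eta += config.age_log_hr * age_c
    table = FeatureTable(pd.concat(blocks, axis=1))
    eta_s = pd.Series(eta, index=table.values.index, name="eta")
    survival, cbound = simulate_survival(eta_s, config,
                                         rng=np.random.default_rng(config.seed + 2))
    truth = GroundTruth(
        gamma=gamma_by_seq, delta2=delta2_by_seq, alpha=alpha,
        beta_age=beta_age, sigma=sigma, prognostic_feature_ids=prog_ids,
        eta=eta_s, censoring_bound=cbound,
    )
    return table, batch_maps, clinical, survival, truth


# --------------------------------------------------------------------------
# phantom volumes

@dataclass
class VolumeSet:
    """One patient's four co-registered volumes plus segmentation masks."""

    patient_id: str
    volumes: dict            # sequence -> 3D float array
    masks: dict              # brain / nawm / core / wtv -> 3D bool array
    spacing: tuple = (1.0, 1.0, 1.0)

    def to_nifti(self, directory) -> None:
        import os

        import nibabel as nib
        affine = np.diag(list(self.spacing) + [1.0])
        os.makedirs(directory, exist_ok=True)
        for seq, vol in self.volumes.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     os.path.join(directory, f"{self.patient_id}_{seq}.nii.gz"))
        for name, m in self.masks.items():
            nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                     os.path.join(directory, f"{self.patient_id}_mask_{name}.nii.gz"))


# per-sequence compartment mean intensities (arbitrary scanner units)
_COMPARTMENT_MEANS = {
    #        GM     WM    oedema  core
    "T1W":   (70.0, 100.0, 60.0,  55.0),
    "T2W":   (90.0,  70.0, 130.0, 110.0),
    "FLAIR": (85.0,  75.0, 140.0, 100.0),
    "T1CE":  (70.0, 100.0, 65.0,  140.0),
}


def generate_phantom_volumes(config: CohortConfig) -> list[VolumeSet]:
    """Generate brain phantoms for every patient in the cohort.

    Each phantom is an ellipsoidal brain with a white-matter interior, a
    grey-matter shell, and a spherical tumour (core inside an oedema rim)
    whose radius varies across patients.  A per-batch multiplicative gain
    and additive offset mimic scanner differences; Gaussian voxel noise is
    added before the gain.  Masks satisfy core (CV) within whole tumour
    (WTV) within brain, and the NAWM mask excludes the tumour.
    """
    g = config.grid_size
    if g < 32:
        raise ValueError("grid size must be >= 32 voxels per axis")
    rng = np.random.default_rng(config.seed + 3)
    zz, yy, xx = np.mgrid[:g, :g, :g].astype(float)
    c = (g - 1) / 2.0
    r_brain = 0.45 * g
    dist2 = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    brain = dist2 <= r_brain ** 2
    wm = dist2 <= (0.7 * r_brain) ** 2
    batch_maps = assign_batches(config)
    gains = {(seq, b): rng.uniform(0.7, 1.4)
             for seq in SEQUENCES for b in config.batch_labels}
    offsets = {(seq, b): rng.uniform(-10.0, 10.0)
               for seq in SEQUENCES for b in config.batch_labels}
    out = []
    for pid in config.patient_ids:
        r_tum = rng.uniform(0.12, 0.22) * g
        centre = c + rng.uniform(-0.1, 0.1, 3) * g
        d2t = ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2
               + (xx - centre[2]) ** 2)
        wtv = (d2t <= r_tum ** 2) & brain
        core = (d2t <= (0.6 * r_tum) ** 2) & brain
        if not wtv.any():
            raise ValueError("tumour mask empty; enlarge grid or radius")
        nawm = wm & ~wtv
        # second-rater whole-tumour segmentation: a slightly larger sphere,
        # emulating inter-rater boundary disagreement for the ICC filter
        wtv_b = (d2t <= (r_tum + rng.uniform(0.5, 1.5)) ** 2) & brain
        vols = {}
        for seq in SEQUENCES:
            b = batch_maps[seq].assignments[pid]
            gm_mu, wm_mu, oed_mu, core_mu = _COMPARTMENT_MEANS[seq]
            vol = np.zeros((g, g, g))
            vol[brain] = gm_mu
            vol[wm] = wm_mu
            vol[wtv] = oed_mu
            vol[core] = core_mu
            if config.noise_sd > 0:
                vol[brain] += rng.normal(0, config.noise_sd,
                                         int(brain.sum()))
            vols[seq] = gains[(seq, b)] * vol \
                + np.where(brain, offsets[(seq, b)], 0.0)
        out.append(VolumeSet(pid, vols,
                             {"brain": brain, "nawm": nawm,
                              "core": core, "wtv": wtv, "wtv_b": wtv_b}))
    return out
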