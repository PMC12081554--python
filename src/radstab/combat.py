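"""Parametric empirical-Bayes batch harmonisation (ComBat) for feature tables.

The model assumes additive and multiplicative batch effects on each feature:

    x_ijg = alpha_g + X_ij beta_g + gamma_ig + delta_ig * eps_ijg

with batch i, patient j, feature g and eps ~ N(0, sigma_g^2).  Location
parameters gamma_ig receive a normal prior and scale parameters delta_ig^2
an inverse-gamma prior, with hyperparameters moment-matched across features
within each batch and posterior (conditional) modes found by the standard
iterative update.  Biological covariates (age, in this pipeline) are fitted
alongside and preserved in the adjusted output.

Harmonisation is applied per MRI sequence: each sequence's feature block
has its own batch structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable


@dataclass
class BatchMap:
    """Per-sequence assignment of patients to acquisition batches."""

    sequence: str
    assignments: pd.Series  # index patient_id -> batch label

    def __post_init__(self):
        self.assignments = pd.Series(self.assignments)
        if self.assignments.index.duplicated().any():
            raise ValueError("a patient is assigned more than one batch")

    @property
    def patient_ids(self) -> list:
        return list(self.assignments.index)

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    @property
    def batch_labels(self) -> list:
        return list(self.sizes.index)

    def subset(self, patient_ids) -> "BatchMap":
        return BatchMap(self.sequence, self.assignments.loc[list(patient_ids)])


@dataclass
class CombatModel:
    """Fitted standardisation and empirical-Bayes parameters for one block."""

    feature_names: list[str]
    batch_labels: list
    covariate_names: list[str]
    alpha_hat: np.ndarray            # (G,) grand intercept per feature
    beta_hat: np.ndarray             # (C, G) covariate coefficients
    sigma2_hat: np.ndarray           # (G,) pooled residual variance
    gamma_hat: np.ndarray            # (I, G) raw additive batch effects
    delta2_hat: np.ndarray           # (I, G) raw multiplicative effects
    gamma_star: np.ndarray           # (I, G) EB-shrunk additive effects
    delta2_star: np.ndarray          # (I, G) EB-shrunk multiplicative effects
    gamma_bar: np.ndarray            # (I,) prior means
    tau2: np.ndarray                 # (I,) prior variances
    a_prior: np.ndarray              # (I,) inverse-gamma shape lambda_i
    b_prior: np.ndarray              # (I,) inverse-gamma rate theta_i
    flags: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "batch_labels": [str(b) for b in self.batch_labels],
            "covariate_names": self.covariate_names,
            "alpha_hat": self.alpha_hat.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "sigma2_hat": self.sigma2_hat.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau2": self.tau2.tolist(),
            "a_prior": self.a_prior.tolist(),
            "b_prior": self.b_prior.tolist(),
            "flags": self.flags,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# minimum-batch-size filtering

def filter_by_mbs(batch_maps, mbs: int, mode: str = "intersection"):
    """Retain patients whose batch meets the minimum batch size.

    Parameters
    ----------
    batch_maps : a single BatchMap or dict {sequence: BatchMap}.
    mbs : minimum number of patients a batch must contain.
    mode : "intersection" retains a patient only if their batch has
        >= mbs members for *every* sequence; "per_sequence" returns the
        per-sequence retained sets without intersecting.

    Returns
    -------
    (retained, info) where retained is the ordered list of retained patient
    ids (intersection mode) or {sequence: list} (per-sequence mode), and
    info is a dict with overall and per-sequence retention fractions.
    """
    if mbs < 1:
        raise ValueError("mbs must be >= 1")
    if isinstance(batch_maps, BatchMap):
        batch_maps = {batch_maps.sequence: batch_maps}
    per_seq: dict[str, list] = {}
    fractions: dict[str, float] = {}
    for seq, bm in batch_maps.items():
        sizes = bm.sizes
        big = set(sizes.index[sizes >= mbs])
        keep = [p for p in bm.patient_ids if bm.assignments[p] in big]
        per_seq[seq] = keep
        fractions[seq] = len(keep) / len(bm.patient_ids)
    if mode == "per_sequence":
        return per_seq, {"per_sequence": fractions}
    all_ids = list(next(iter(batch_maps.values())).patient_ids)
    keep_sets = [set(v) for v in per_seq.values()]
    retained = [p for p in all_ids if all(p in s for s in keep_sets)]
    if not retained:
        raise ValueError(f"no batch reaches the minimum batch size {mbs}")
    info = {
        "per_sequence": fractions,
        "overall": len(retained) / len(all_ids),
        "n_retained": len(retained),
        "n_eligible": len(all_ids),
    }
    return retained, info


# --------------------------------------------------------------------------
# covariate screen

def batch_covariate_screen(covariate: pd.Series, batch_map: BatchMap):
    """One-way ANOVA F-test of a covariate across batches.

    Used to decide whether the covariate should enter the harmonisation
    model (include if p < 0.05).  Returns (p_value, flags).
    """
    cov = pd.Series(covariate).loc[batch_map.patient_ids]
    flags: list[str] = []
    groups = []
    for label, idx in batch_map.assignments.groupby(batch_map.assignments).groups.items():
        vals = cov.loc[idx].to_numpy(float)
        if len(vals) < 2:
            flags.append(f"batch {label} has < 2 patients; excluded from test")
            continue
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least 2 batches with >= 2 patients")
    if np.ptp(np.concatenate(groups)) == 0:
        flags.append("covariate constant; p-value undefined, reported as 1")
        return 1.0, flags
    _, p = stats.f_oneway(*groups)
    if np.isnan(p):
        flags.append("degenerate ANOVA; p reported as 1")
        return 1.0, flags
    return float(p), flags


# --------------------------------------------------------------------------
# the EB machinery

def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=100):
    """Iterative conditional-mode solution for one batch.

    z : (n_i, G) standardised data for the batch; returns (gamma*, delta2*).
    """
    n = z.shape[0]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max(initial=0.0),
            np.abs(d_new - d_old).max(initial=0.0),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(table: FeatureTable, batch_map: BatchMap,
                  covariates: pd.DataFrame | None = None,
                  eb: bool = True):
    """Harmonise one feature block across batches.

    Parameters
    ----------
    table : FeatureTable restricted to the patients being harmonised.
    batch_map : batch labels for the same patients.
    covariates : optional patient x covariate DataFrame (e.g. age) whose
        effects are estimated jointly and preserved in the output.
    eb : if False, use the raw per-batch estimates instead of the
        empirical-Bayes shrunk ones (exposed for diagnostics).

    Returns (adjusted FeatureTable, CombatModel).
    """
    ids = table.patient_ids
    X = table.values.to_numpy(float)
    n, G = X.shape
    labels = batch_map.assignments.loc[ids]
    batches = list(pd.unique(labels))
    if len(batches) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    flags: list[str] = []
    B = np.stack([(labels == b).to_numpy(float) for b in batches], axis=1)
    n_i = B.sum(axis=0)
    if covariates is not None:
        Z = covariates.loc[ids].to_numpy(float)
        cov_names = list(map(str, covariates.columns))
    else:
        Z = np.zeros((n, 0))
        cov_names = []
    design = np.concatenate([B, Z], axis=1)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("singular design: covariates confounded with batch")
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    batch_coef = coef[: len(batches)]            # (I, G) per-batch intercepts
    beta_hat = coef[len(batches):]               # (C, G)
    alpha_hat = (n_i / n) @ batch_coef           # weighted grand intercept
    resid = X - design @ coef
    sigma2 = (resid ** 2).mean(axis=0)           # pooled over all samples
    if np.any(sigma2 <= 0):
        raise ValueError("zero pooled variance for some feature(s)")
    stand_mean = alpha_hat[None, :] + Z @ beta_hat
    z = (X - stand_mean) / np.sqrt(sigma2)[None, :]

    gamma_hat = np.empty((len(batches), G))
    delta2_hat = np.empty((len(batches), G))
    for bi, b in enumerate(batches):
        rows = B[:, bi].astype(bool)
        zb = z[rows]
        gamma_hat[bi] = zb.mean(axis=0)
        delta2_hat[bi] = zb.var(axis=0, ddof=1) if rows.sum() > 1 else 1.0

    zero_var = delta2_hat <= 0
    if zero_var.any():
        flags.append(
            f"{int(zero_var.sum())} batch-feature cell(s) with zero "
            "within-batch variance: scale adjustment disabled there")

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
    a_prior = np.where(np.isfinite(a_prior), a_prior, 2.0)
    b_prior = np.where(np.isfinite(b_prior), b_prior, 1.0)

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    if eb:
        for bi, b in enumerate(batches):
            rows = B[:, bi].astype(bool)
            gamma_star[bi], delta2_star[bi] = _it_sol(
                z[rows], gamma_hat[bi],
                np.where(zero_var[bi], 1.0, delta2_hat[bi]),
                gamma_bar[bi], tau2[bi], a_prior[bi], b_prior[bi],
            )
    delta2_star = np.where(zero_var, 1.0, delta2_star)
    delta2_star = np.clip(delta2_star, 1e-12, None)

    z_adj = z.copy()
    for bi in range(len(batches)):
        rows = B[:, bi].astype(bool)
        z_adj[rows] = (z[rows] - gamma_star[bi][None, :]) \
            / np.sqrt(delta2_star[bi])[None, :]
    X_adj = z_adj * np.sqrt(sigma2)[None, :] + stand_mean

    adj = FeatureTable(pd.DataFrame(X_adj, index=table.values.index,
                                    columns=table.values.columns))
    model = CombatModel(
        feature_names=table.feature_names,
        batch_labels=batches,
        covariate_names=cov_names,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        sigma2_hat=sigma2,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        flags=flags,
    )
    return adj, model


def combat_adjust_by_sequence(table: FeatureTable, batch_maps: dict,
                              covariates: pd.DataFrame | None = None,
                              eb: bool = True):
    """Apply combat_adjust independently to each sequence's feature block.

    Features whose sequence has no batch map (e.g. shape features, which are
    image-intensity independent) are passed through unchanged.
    """
    meta = table.metadata()
    blocks = []
    models = {}
    adjusted_cols = set()
    for seq, bm in batch_maps.items():
        cols = [c for c in table.feature_names
                if meta.loc[c, "sequence"] == seq
                and meta.loc[c, "family"] != "shape"]
        if not cols:
            continue
        adj, model = combat_adjust(table.subset(feature_names=cols), bm,
                                   covariates, eb=eb)
        blocks.append(adj.values)
        models[seq] = model
        adjusted_cols.update(cols)
    passthrough = [c for c in table.feature_names if c not in adjusted_cols]
    if passthrough:
        blocks.append(table.values[passthrough])
    df = pd.concat(blocks, axis=1)[table.feature_names]
    return FeatureTable(df), models
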