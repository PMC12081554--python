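"""Feature selection strategies and Cox model building.

Five selection strategies each nominate at most four radiomic features for
the radiomics and combined models, honouring an events-per-predictor cap:

* ``pca`` — unsupervised: Ward clustering of patients on principal
  component scores (components covering >= 80% variance), then the four
  features with the largest one-way ANOVA F across cluster labels.
* ``forward`` / ``backward`` — stepwise Cox partial-likelihood AIC
  minimisation, capped at four features.
* ``lasso`` — L1-penalised Cox path; the largest penalty giving at most
  four non-zero coefficients.
* ``rsf`` — random survival forest permutation importance, top four.

Supervised strategies are preceded by a Spearman collinearity filter.
Model types: clinical-only (age, gender, MGMT status, resection category,
adjuvant-treatment category, tumour diameter, log-transformed whole-tumour
volume), radiomics-only, and combined (clinical plus the selected
features).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .cox import FittedCoxModel, fit_cox
from .features import FeatureTable
from .metrics import model_aic

MAX_RADIOMIC_FEATURES = 4
FS_METHODS = ("pca", "forward", "backward", "lasso", "rsf")
MODEL_TYPES = ("clinical", "radiomics", "combined")


# --------------------------------------------------------------------------
# collinearity filter

def collinearity_filter(table: FeatureTable, threshold: float = 0.7) -> FeatureTable:
    """Greedy removal of highly rank-correlated feature pairs.

    While any pair has |Spearman rho| > threshold, the worst pair is
    resolved by dropping its member with the larger mean absolute
    correlation to all remaining features (ties broken by feature-name
    order).  Constant features, whose rank correlation is undefined, are
    dropped first.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    df = table.values
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s)")
        df = df.drop(columns=constant)
    names = list(df.columns)
    if len(names) < 2:
        return FeatureTable(df.copy())
    rho = np.abs(stats.spearmanr(df.to_numpy()).statistic)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 0.0)
    keep = np.ones(len(names), bool)
    while True:
        sub = rho[np.ix_(keep, keep)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        idx = np.flatnonzero(keep)
        i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = idx[i_s], idx[j_s]
        mean_i = rho[i, keep].sum() / max(keep.sum() - 1, 1)
        mean_j = rho[j, keep].sum() / max(keep.sum() - 1, 1)
        if mean_i > mean_j or (mean_i == mean_j and names[i] > names[j]):
            keep[i] = False
        else:
            keep[j] = False
    kept = [n for n, k in zip(names, keep) if k]
    return FeatureTable(df[kept].copy())


# --------------------------------------------------------------------------
# unsupervised PCA-cluster selection

def select_pca_cluster(table: FeatureTable, k_clusters: int = 2,
                       variance_threshold: float = 0.80,
                       n_select: int = MAX_RADIOMIC_FEATURES) -> list[str]:
    """Features best separating Ward clusters of patients in PCA space.

    Features are standardised, patients clustered on the leading principal
    component scores (smallest set explaining >= ``variance_threshold`` of
    variance), the tree cut at ``k_clusters``, and features ranked by the
    one-way ANOVA F-statistic across cluster labels.
    """
    X = table.values.to_numpy(float)
    n = X.shape[0]
    if k_clusters >= n:
        raise ValueError("k_clusters must be smaller than n_patients")
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    # PCA via SVD
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    evr = S ** 2 / (S ** 2).sum()
    k_comp = int(np.searchsorted(np.cumsum(evr), variance_threshold) + 1)
    scores = U[:, :k_comp] * S[:k_comp]
    labels = fcluster(linkage(scores, method="ward"), k_clusters,
                      criterion="maxclust")
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate single-cluster solution")
    fstats = []
    for gi, name in enumerate(table.feature_names):
        groups = [X[labels == lab, gi] for lab in np.unique(labels)]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, _ = stats.f_oneway(*groups)
        fstats.append((-(f if np.isfinite(f) else -np.inf), name))
    fstats.sort()
    return [name for _, name in fstats[:n_select]]


# --------------------------------------------------------------------------
# supervised strategies

def _forward(df, time, event, cap):
    names = sorted(df.columns)
    X = df[names].to_numpy(float)
    current: list[int] = []
    beta_cur = np.zeros(0)
    null = fit_cox(np.zeros((len(time), 0)), time, event, names=[])
    best_aic = model_aic(null.log_likelihood, 0)
    remaining = list(range(len(names)))
    while remaining and len(current) < cap:
        trials = []
        for j in remaining:
            cols = current + [j]
            try:
                m = fit_cox(X[:, cols], time, event,
                            init_beta=np.append(beta_cur, 0.0))
            except (ValueError, np.linalg.LinAlgError):
                continue
            trials.append((model_aic(m.log_likelihood, len(cols)), j,
                           m.coefficients))
        if not trials:
            break
        aic, j, beta = min(trials, key=lambda t: (t[0], t[1]))
        if aic >= best_aic:
            break
        best_aic = aic
        current.append(j)
        beta_cur = beta
        remaining.remove(j)
    return [names[j] for j in current]


def _backward(df, time, event, cap):
    names = sorted(df.columns)
    if not names:
        return []
    X = df[names].to_numpy(float)
    current = list(range(len(names)))
    try:
        m = fit_cox(X, time, event)
        best_aic = model_aic(m.log_likelihood, len(current))
        beta_cur = m.coefficients
    except (ValueError, np.linalg.LinAlgError):
        best_aic = np.inf
        beta_cur = np.zeros(len(current))
    while len(current) > 1:
        trials = []
        for pos, j in enumerate(current):
            reduced = current[:pos] + current[pos + 1:]
            try:
                m = fit_cox(X[:, reduced], time, event,
                            init_beta=np.delete(beta_cur, pos))
            except (ValueError, np.linalg.LinAlgError):
                continue
            trials.append((model_aic(m.log_likelihood, len(reduced)), j,
                           m.coefficients))
        if not trials:
            break
        aic, j, beta = min(trials, key=lambda t: (t[0], t[1]))
        if aic < best_aic or len(current) > cap:
            # over the cap the set must keep shrinking even at an AIC cost
            best_aic = aic
            beta_cur = beta
            current.remove(j)
        else:
            break
    current = current if len(current) <= cap else current[:cap]
    return [names[j] for j in current]


def _lasso(df, time, event, cap, max_iter=100000):
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    y = np.empty(len(time), dtype=[("event", bool), ("time", float)])
    y["event"] = np.asarray(event, bool)
    y["time"] = np.asarray(time, float)
    X = df.to_numpy(float)
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01,
                                   n_alphas=60, max_iter=max_iter)
    try:
        model.fit(Xs, y)
    except Exception:
        return []
    coefs = model.coef_  # (p, n_alphas), alphas decreasing
    nnz = (np.abs(coefs) > 1e-12).sum(axis=0)
    # candidate supports: every distinct support of size <= cap on the
    # path, plus the null support; the winner minimises the extended BIC
    # (Chen & Chen, gamma = 0.5) of an unpenalised refit, so pure-noise
    # data falls back to the empty set while real signal survives
    supports = {frozenset()}
    for j in np.flatnonzero(nnz <= cap):
        supports.add(frozenset(np.flatnonzero(np.abs(coefs[:, j]) > 1e-12)))
    time = y["time"]
    event = y["event"].astype(float)
    n_ev = max(event.sum(), 1.0)
    p_cand = X.shape[1]
    penalty = np.log(n_ev) + np.log(p_cand)  # EBIC with gamma = 1/2
    best = (np.inf, frozenset())
    from .cox import fit_cox as _fit
    for sup in sorted(supports, key=lambda s: (len(s), sorted(s))):
        cols = sorted(sup)
        try:
            m = _fit(Xs[:, cols] if cols else np.zeros((len(time), 0)),
                     time, event)
        except (ValueError, np.linalg.LinAlgError):
            continue
        crit = -2.0 * m.log_likelihood + penalty * len(cols)
        if crit < best[0] - 1e-12:
            best = (crit, sup)
    return sorted(df.columns[sorted(best[1])])


def _rsf(df, time, event, cap, n_trees=500, seed=0, n_repeats=5):
    from sksurv.ensemble import RandomSurvivalForest

    y = np.empty(len(time), dtype=[("event", bool), ("time", float)])
    y["event"] = np.asarray(event, bool)
    y["time"] = np.asarray(time, float)
    X = df.to_numpy(float)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees, min_samples_leaf=10, max_features="sqrt",
        random_state=seed, n_jobs=1)
    rsf.fit(X, y)
    rng = np.random.default_rng(seed)
    base = rsf.score(X, y)
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - rsf.score(Xp, y))
        importances[j] = np.mean(drops)
    order = np.argsort(-importances, kind="stable")
    return sorted(df.columns[order[:cap]])


def select_supervised(table: FeatureTable, time, event, strategy: str,
                      cap: int = MAX_RADIOMIC_FEATURES,
                      rsf_trees: int = 500, seed: int = 0) -> list[str]:
    """Select at most ``cap`` features with one supervised strategy.

    The caller is expected to have applied :func:`collinearity_filter`
    first.  Forward selection may legitimately return an empty list (no
    feature improves AIC); the combined model then reduces to
    clinical-only.
    """
    if strategy not in ("forward", "backward", "lasso", "rsf"):
        raise ValueError(f"unknown strategy {strategy!r}")
    df = table.values
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    if strategy == "forward":
        out = _forward(df, time, event, cap)
    elif strategy == "backward":
        out = _backward(df, time, event, cap)
    elif strategy == "lasso":
        out = _lasso(df, time, event, cap)
    else:
        out = _rsf(df, time, event, cap, n_trees=rsf_trees, seed=seed)
    assert len(out) <= cap
    return list(out)


def select_features(table: FeatureTable, time, event, method: str,
                    cap: int = MAX_RADIOMIC_FEATURES,
                    k_clusters: int = 2, rsf_trees: int = 500,
                    seed: int = 0) -> list[str]:
    """Dispatch to one of the five selection strategies."""
    if method == "pca":
        return select_pca_cluster(table, k_clusters=k_clusters, n_select=cap)
    return select_supervised(table, time, event, method, cap=cap,
                             rsf_trees=rsf_trees, seed=seed)


# --------------------------------------------------------------------------
# model building

def _drop_degenerate(df: pd.DataFrame) -> pd.DataFrame:
    """Remove constant columns (can arise inside bootstrap resamples)."""
    keep = [c for c in df.columns if df[c].nunique() > 1]
    return df[keep]


def build_design(model_type: str, clinical_design: pd.DataFrame,
                 features: FeatureTable | None = None,
                 selected: list[str] | None = None) -> pd.DataFrame:
    """Design matrix for one of the three model types.

    combined = clinical predictors plus the selected radiomic features
    (their union); radiomics = the selected features alone.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    if model_type == "clinical":
        return clinical_design.copy()
    if features is None or selected is None:
        raise ValueError("radiomics/combined models need selected features")
    rad = features.values[list(selected)]
    if model_type == "radiomics":
        return rad.copy()
    return pd.concat([clinical_design, rad], axis=1)


def fit_model(design: pd.DataFrame, time, event) -> FittedCoxModel:
    """Fit a Cox model, silently dropping degenerate (constant) columns."""
    design = _drop_degenerate(design)
    return fit_cox(design, np.asarray(time, float), np.asarray(event, float))
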