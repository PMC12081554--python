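"""Performance metrics for Cox survival models.

Four domains are covered, matching how prognostic models are customarily
validated: discrimination (Harrell's C-index and the Royston-Sauerbrei
D-statistic), calibration (calibration slope and 1-year calibration
curves), relative explained variation (R2_D and Nagelkerke's R2 on the
partial likelihood) and relative model fit (AIC).

All metrics are computed on the evaluation sample alone; the fitted model
enters only through its linear predictor (prognostic index, PI) and, for
the 1-year curve, its baseline cumulative hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cox import FittedCoxModel, cox_loglik, fit_cox

KAPPA = float(np.sqrt(8.0 / np.pi))      # rankit scaling constant
SIGMA2_RANKIT = float(np.pi ** 2 / 6.0)  # variance term in R2_D

ONE_YEAR_MONTHS = 12.0


@dataclass
class MetricSet:
    """One model's performance metrics on one evaluation sample."""

    c_index: float
    d_statistic: float
    r2_d: float
    r2_nagelkerke: float
    aic: float
    calibration_slope: float
    n: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        expected = r2_d_from_d(self.d_statistic)
        if abs(self.r2_d - expected) > 1e-10:
            raise ValueError("R2_D inconsistent with D")

    def as_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "d_statistic": self.d_statistic,
            "r2_d": self.r2_d,
            "r2_nagelkerke": self.r2_nagelkerke,
            "aic": self.aic,
            "calibration_slope": self.calibration_slope,
        }


METRIC_NAMES = ("c_index", "d_statistic", "r2_d", "r2_nagelkerke",
                "aic", "calibration_slope")


# --------------------------------------------------------------------------
# discrimination

def harrell_c(pi, time, event) -> float:
    """Harrell's concordance index with risk ties counted as 1/2.

    A pair is usable when the ordering of survival is determinable under
    right censoring: the earlier time is an event, or the times are tied
    with exactly one event (the censored member outlived the other).
    Higher PI must predict shorter survival.
    """
    pi = np.asarray(pi, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    dt = time[:, None] - time[None, :]            # t_i - t_j
    usable = ((dt < 0) & event[:, None]) | (
        (dt == 0) & event[:, None] & ~event[None, :])
    dp = pi[:, None] - pi[None, :]
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs")
    concordant = (usable & (dp > 0)).sum()
    tied = (usable & (dp == 0)).sum()
    return float((concordant + 0.5 * tied) / n_usable)


def blom_rankits(x) -> np.ndarray:
    """Expected standard-normal order statistics (Blom 3/8 approximation),
    with average ranks for ties."""
    x = np.asarray(x, float)
    n = len(x)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))


def royston_d(pi, time, event) -> tuple[float, float]:
    """Royston-Sauerbrei D-statistic and its explained-variation R2_D.

    D is the Cox coefficient of the scaled rankits z/kappa of the PI; it
    estimates the log hazard ratio between the prognostic-index halves of
    the cohort.  R2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2).
    """
    pi = np.asarray(pi, float)
    if len(pi) < 10:
        raise ValueError("D-statistic needs n >= 10")
    if np.ptp(pi) == 0:
        warnings.warn("constant PI: D = 0 by convention")
        return 0.0, 0.0
    z = blom_rankits(pi) / KAPPA
    m = fit_cox(z[:, None], np.asarray(time, float),
                np.asarray(event, float), names=["scaled_rankit"])
    d = float(m.coefficients[0])
    return d, r2_d_from_d(d)


def r2_d_from_d(d: float) -> float:
    q = d ** 2 / KAPPA ** 2
    return q / (SIGMA2_RANKIT + q)


# --------------------------------------------------------------------------
# explained variation and fit

def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int):
    """Nagelkerke's R2 from partial log-likelihoods.

    R2_CS = 1 - exp(2 (L0 - L1)/n), normalised by its maximum
    1 - exp(2 L0 / n).  If the model likelihood falls below the null (a
    fixed coefficient vector evaluated on new data can do this) the value
    is floored at 0 and flagged.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    flags = []
    if loglik_model < loglik_null:
        flags.append("model log-likelihood below null; R2_N floored at 0")
        return 0.0, flags
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        flags.append("degenerate null likelihood; R2_N reported as 0")
        return 0.0, flags
    return float(r2_cs / denom), flags


def model_aic(loglik_model: float, k_parameters: int) -> float:
    """AIC = -2 log L + 2k on the partial likelihood (lower is better)."""
    if k_parameters < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * loglik_model + 2.0 * k_parameters


# --------------------------------------------------------------------------
# calibration

def calibration_slope(pi, time, event) -> float:
    """Cox coefficient of an externally computed PI on evaluation data.

    1.0 indicates ideal calibration-in-slope; values below 1 indicate the
    PI spreads risk too widely (overfitting).
    """
    pi = np.asarray(pi, float)
    if np.ptp(pi) == 0:
        raise ValueError("constant PI: calibration slope undefined")
    m = fit_cox(pi[:, None], np.asarray(time, float),
                np.asarray(event, float), names=["pi"])
    return float(m.coefficients[0])


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis; k knots give k-1 columns."""
    k = len(knots)
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]

    def plus3(u):
        return np.where(u > 0, u ** 3, 0.0)

    cols = [x]
    denom = (tk - t1) ** 2
    for j in range(k - 2):
        tj = knots[j]
        term = (plus3(x - tj)
                - plus3(x - tk1) * (tk - tj) / (tk - tk1)
                + plus3(x - tk) * (tk1 - tj) / (tk - tk1))
        cols.append(term / denom)
    return np.stack(cols, axis=1)


def predicted_risk_1yr(model: FittedCoxModel, X_eval,
                       horizon: float = ONE_YEAR_MONTHS) -> np.ndarray:
    """Predicted probability of death by the horizon from the Breslow
    baseline: r_i = 1 - S0(h)^exp(PI_i)."""
    return 1.0 - model.predict_survival(np.asarray(X_eval, float), horizon)


def calibration_curve_1yr(model: FittedCoxModel, X_eval, time, event,
                          horizon: float = ONE_YEAR_MONTHS,
                          n_grid: int = 200):
    """Observed-vs-predicted event risk at the 1-year horizon.

    Predicted risks come from the model's Breslow baseline; observed risks
    from a flexible recalibration — a secondary Cox model on a restricted
    cubic spline (3 knots) of log(-log(1 - r_hat)) fitted to the
    evaluation data — read off at the horizon on a 200-point grid spanning
    the observed predictions.

    Returns a dict with 'predicted' (grid), 'observed', and 'flags'.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    if time.max() <= horizon:
        warnings.warn("no follow-up beyond the horizon")
    r_hat = predicted_risk_1yr(model, X_eval, horizon)
    flags: list[str] = []
    if np.ptp(r_hat) < 1e-12:
        flags.append("all predictions identical; curve degenerates to a point")
        grid = np.full(n_grid, r_hat[0] if len(r_hat) else np.nan)
        return {"predicted": grid, "observed": grid.copy(), "flags": flags}
    cll = np.log(-np.log(np.clip(1.0 - r_hat, 1e-12, 1 - 1e-12)))
    knots = np.quantile(cll, [0.1, 0.5, 0.9])
    if len(np.unique(knots)) < 3:
        knots = np.linspace(cll.min(), cll.max(), 3)
    basis = _rcs_basis(cll, knots)
    keep = basis.std(axis=0) > 1e-12
    basis = basis[:, keep]
    sec = fit_cox(basis, time, event,
                  names=[f"rcs{j}" for j in range(basis.shape[1])])
    lo, hi = r_hat.min(), r_hat.max()
    grid = np.linspace(lo, hi, n_grid)
    cll_g = np.log(-np.log(np.clip(1.0 - grid, 1e-12, 1 - 1e-12)))
    basis_g = _rcs_basis(cll_g, knots)[:, keep]
    h0 = sec.baseline_cumhaz_at(horizon)
    observed = 1.0 - np.exp(-h0 * np.exp(basis_g @ sec.coefficients))
    return {"predicted": grid, "observed": observed, "flags": flags}


# --------------------------------------------------------------------------
# one-call evaluation

def evaluate_model(model: FittedCoxModel, X_eval, time, event) -> MetricSet:
    """Compute the full MetricSet for a fitted model on evaluation data.

    The model's coefficients are held fixed; its partial log-likelihood is
    re-evaluated on the evaluation sample, so apparent (training)
    evaluation reproduces the fitted log-likelihood and AIC exactly.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    X_eval = np.asarray(X_eval, float)
    if X_eval.ndim == 1:
        X_eval = X_eval[:, None]
    flags: list[str] = []
    if model.k_parameters:
        pi = model.predict_pi(X_eval)
        ll_model = cox_loglik(model.coefficients, X_eval, time, event)
    else:
        pi = np.zeros(len(time))
        ll_model = cox_loglik(np.zeros(0), np.zeros((len(time), 0)), time, event)
    ll_null = cox_loglik(np.zeros(0), np.zeros((len(time), 0)), time, event)
    c = harrell_c(pi, time, event) if np.ptp(pi) > 0 else 0.5
    if np.ptp(pi) > 0:
        try:
            d, r2d = royston_d(pi, time, event)
        except ValueError as exc:
            d, r2d = np.nan, np.nan
            flags.append(f"D unavailable: {exc}")
        slope = calibration_slope(pi, time, event)
    else:
        d, r2d = 0.0, 0.0
        slope = np.nan
        flags.append("constant PI: D = 0, slope undefined")
    r2n, nflags = nagelkerke_r2(ll_null, ll_model, len(time))
    flags.extend(nflags)
    return MetricSet(
        c_index=c, d_statistic=d, r2_d=r2d, r2_nagelkerke=r2n,
        aic=model_aic(ll_model, model.k_parameters),
        calibration_slope=slope, n=len(time), n_events=int(event.sum()),
        flags=flags,
    )
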