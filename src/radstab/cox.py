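"""Cox proportional hazards fitting by Newton-Raphson with Efron tie handling.

A small, fast implementation used throughout the bootstrap engine, where
thousands of fits on cohorts of a few hundred patients are needed.  The
log-partial-likelihood, gradient and Hessian follow the Efron approximation
for tied event times; the baseline cumulative hazard is the Breslow
estimator evaluated at the fitted coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_ABS_COEF = 20.0  # cap under monotone likelihood / separation


@dataclass
class FittedCoxModel:
    """A fitted proportional-hazards model.

    The linear predictor (prognostic index) is PI_i = x_i @ coefficients,
    uncentred: no mean offset is subtracted, and the baseline hazard is the
    hazard of a subject with all predictors at zero.
    """

    predictor_names: list[str]
    coefficients: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    baseline_times: np.ndarray       # unique event times, increasing
    baseline_cumhaz: np.ndarray      # Breslow H0 at those times
    linear_predictor: np.ndarray     # per-patient PI on the training data
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    pi_convention: str = "uncentred"

    @property
    def k_parameters(self) -> int:
        return len(self.coefficients)

    def predict_pi(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coefficients

    def baseline_cumhaz_at(self, t: float) -> float:
        """Breslow H0(t): step function, right-continuous."""
        idx = np.searchsorted(self.baseline_times, t, side="right")
        return 0.0 if idx == 0 else float(self.baseline_cumhaz[idx - 1])

    def predict_survival(self, X: np.ndarray, t: float) -> np.ndarray:
        """S(t | x) = exp(-H0(t))^exp(PI)."""
        h0 = self.baseline_cumhaz_at(t)
        return np.exp(-h0 * np.exp(self.predict_pi(X)))


class _PartialLikelihood:
    """Efron log partial likelihood with beta-independent structure cached.

    Sorting, tied-block boundaries and the Efron within-block expansion
    l/d (l = 0..d-1 for d tied events) depend only on (time, event), so
    they are computed once; each evaluation then reduces to exponentials,
    cumulative sums and segment reductions.  With no tied times the Efron
    and Breslow forms coincide and the block machinery is skipped.
    """

    def __init__(self, X, time, event):
        n, p = X.shape
        self.n, self.p = n, p
        order = np.argsort(-time, kind="stable")  # decreasing time
        self.Xo = np.ascontiguousarray(X[order])
        self.eo = event[order].astype(bool)
        to = time[order]
        self.sum_x_events = self.Xo[self.eo].sum(axis=0) if p else np.zeros(0)
        self.tied = n != len(np.unique(time))
        if not self.tied:
            self.ev = np.flatnonzero(self.eo)
            return
        bs = np.r_[0, np.flatnonzero(to[1:] != to[:-1]) + 1]
        self.bs = bs
        self.last = np.r_[bs[1:], n] - 1
        d_k = np.add.reduceat(self.eo.astype(np.int64), bs)
        self.has_ev = d_k > 0
        reps = d_k[self.has_ev]
        self.idx = np.repeat(np.arange(len(reps)), reps)
        offs = np.repeat(np.r_[0, np.cumsum(reps)[:-1]], reps)
        self.frac = (np.arange(reps.sum()) - offs) / reps[self.idx]

    def __call__(self, beta, want_derivs=True):
        # extreme coefficients during step-halving can underflow weights to
        # zero; the resulting infinities are handled by the line search
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            return self._evaluate(beta, want_derivs)

    def _evaluate(self, beta, want_derivs):
        Xo, eo, p = self.Xo, self.eo, self.p
        eta_o = Xo @ beta if p else np.zeros(self.n)
        shift = eta_o.max() if self.n else 0.0
        w = np.exp(eta_o - shift)
        cs_w = np.cumsum(w)
        if not self.tied:
            ev = self.ev
            denom = cs_w[ev]
            frac = None
            idx = slice(None)
            n_terms = len(ev)
        else:
            sw_r = cs_w[self.last][self.has_ev]
            we = np.where(eo, w, 0.0)
            sw_d = np.add.reduceat(we, self.bs)[self.has_ev]
            idx = self.idx
            frac = self.frac
            denom = sw_r[idx] - frac * sw_d[idx]
        ll = float(eta_o[eo].sum() - np.log(denom).sum() - eo.sum() * shift)
        if not want_derivs:
            return ll, None, None
        wx = w[:, None] * Xo
        cs_wx = np.cumsum(wx, axis=0)
        wxx = wx[:, :, None] * Xo[:, None, :]
        cs_wxx = np.cumsum(wxx, axis=0)
        if not self.tied:
            mean_x = cs_wx[self.ev] / denom[:, None]
            num_xx = cs_wxx[self.ev]
        else:
            swx_r = cs_wx[self.last][self.has_ev]
            swx_d = np.add.reduceat(
                np.where(eo[:, None], wx, 0.0), self.bs, axis=0)[self.has_ev]
            mean_x = (swx_r[idx] - frac[:, None] * swx_d[idx]) / denom[:, None]
            swxx_r = cs_wxx[self.last][self.has_ev]
            swxx_d = np.add.reduceat(
                np.where(eo[:, None, None], wxx, 0.0), self.bs,
                axis=0)[self.has_ev]
            num_xx = swxx_r[idx] - frac[:, None, None] * swxx_d[idx]
        grad = self.sum_x_events - mean_x.sum(axis=0)
        hess = -(num_xx / denom[:, None, None]).sum(axis=0)
        hess += np.einsum("ij,ik->jk", mean_x, mean_x)
        return ll, grad, hess


def _efron_ll_grad_hess(beta, X, time, event, want_derivs=True):
    return _PartialLikelihood(X, time, event)(beta, want_derivs)


def cox_loglik(beta, X, time, event) -> float:
    """Efron log partial likelihood at an arbitrary coefficient vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    ll, _, _ = _efron_ll_grad_hess(
        np.asarray(beta, dtype=float), X, np.asarray(time, float),
        np.asarray(event, float), want_derivs=False,
    )
    return ll


def fit_cox(
    X,
    time,
    event,
    names: list[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-8,
    ridge: float = 0.0,
    init_beta=None,
) -> FittedCoxModel:
    """Fit a Cox model by maximum Efron partial likelihood.

    Parameters
    ----------
    X : (n, p) array or DataFrame; p may be 0 (null model).
    time, event : survival outcome; event is 1 for death, 0 for censoring.
    ridge : optional small L2 penalty used only as a fallback when the
        unpenalised fit fails to converge (monotone likelihood).

    Separation / monotone likelihood is handled by capping coefficients at
    +/-20 and flagging the model rather than erroring.
    """
    if hasattr(X, "columns"):
        names = list(map(str, X.columns)) if names is None else names
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, p = X.shape
    if n != len(time) or n != len(event):
        raise ValueError("X, time and event must agree in length")
    if int(event.sum()) < 1:
        raise ValueError("at least one event is required")
    if names is None:
        names = [f"x{k}" for k in range(p)]
    flags: list[str] = []
    if p:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant predictor column(s): "
                             + ", ".join(np.array(names)[sd == 0]))

    prob_null = _PartialLikelihood(X[:, :0], time, event)
    ll_null, _, _ = prob_null(np.zeros(0), False)

    beta = np.zeros(p) if init_beta is None else np.asarray(init_beta, float).copy()
    ll = ll_null
    converged = True
    if p:
        prob = _PartialLikelihood(X, time, event)
        ll, grad, hess = prob(beta)
        for _ in range(max_iter):
            H = hess - ridge * np.eye(p)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            new_beta = beta - step
            # step-halving (likelihood-only evaluations) if no improvement
            for _ in range(25):
                new_ll, _, _ = prob(new_beta, want_derivs=False)
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    break
                new_beta = (beta + new_beta) / 2.0
            if not np.isfinite(new_ll):
                converged = False
                break
            delta = np.abs(new_beta - beta).max()
            beta = new_beta
            ll, grad, hess = prob(beta)
            if delta < tol or np.abs(grad).max() < 1e-9:
                break
        else:
            converged = False
        if np.abs(beta).max() > MAX_ABS_COEF:
            beta = np.clip(beta, -MAX_ABS_COEF, MAX_ABS_COEF)
            ll, _, _ = prob(beta, False)
            flags.append("separation: coefficients capped at 20")
            converged = False
        if not converged and "separation" not in " ".join(flags):
            flags.append("non-convergence")

    eta = X @ beta if p else np.zeros(n)
    bt, bh = _breslow_baseline(eta, time, event)
    return FittedCoxModel(
        predictor_names=list(names),
        coefficients=beta,
        log_likelihood=float(ll),
        log_likelihood_null=float(ll_null),
        n=n,
        n_events=int(event.sum()),
        baseline_times=bt,
        baseline_cumhaz=bh,
        linear_predictor=eta,
        converged=converged,
        flags=flags,
    )


def _breslow_baseline(eta, time, event):
    """Breslow estimator of the baseline cumulative hazard.

    With capped-separation models the baseline can legitimately reach the
    floating-point limits; infinities are propagated rather than raised.
    """
    order = np.argsort(time, kind="stable")
    shift = eta.max() if len(eta) else 0.0
    with np.errstate(over="ignore", divide="ignore"):
        t, e, w = time[order], event[order], np.exp(eta[order] - shift)
        scale = float(np.exp(np.clip(-shift, None, 700.0)))
    # risk-set sum of w for each position: total minus cumulative of earlier
    rev_cum = np.cumsum(w[::-1])[::-1]  # sum over j with t_j >= t_i (sorted)
    times = []
    haz = []
    i, n = 0, len(t)
    H = 0.0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        d = e[i : j + 1].sum()
        if d > 0:
            H += scale * d / max(rev_cum[i], np.finfo(float).tiny)
            times.append(t[i])
            haz.append(H)
        i = j + 1
    return np.asarray(times), np.asarray(haz)
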