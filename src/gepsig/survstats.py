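"""Censored-survival statistical kernel.

Provides the Nelson-Aalen cumulative hazard, martingale/deviance
residuals from the covariate-free null model, Kaplan-Meier estimation,
the two-group log-rank test, a Cox proportional-hazards fit with Breslow
tie handling, and Harrell's concordance index.

Deviance residuals are the censoring-aware continuous response used
throughout the signature pipeline: with ``m_i = delta_i - Lambda(t_i)``
the martingale residual under the null model,

    d_i = sign(m_i) * sqrt(-2 * [m_i + delta_i * log(delta_i - m_i)])

(the ``delta_i = 0`` logarithm term is taken as 0).  A large positive
residual marks a sample that recurred earlier than the cohort hazard
predicts; a large negative one marks a long, event-free follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "StepFunction",
    "DevianceResiduals",
    "CoxFitResult",
    "nelson_aalen",
    "null_deviance_residuals",
    "km_estimate",
    "KMEstimate",
    "logrank_test",
    "cox_fit",
    "harrell_c",
]


def _check_outcomes(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValueError("empty outcome vector")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and positive")
    event = event.astype(int)
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event flags must be 0/1")
    return time, event


@dataclass
class StepFunction:
    """Right-continuous non-decreasing step function with value 0 at t=0."""

    times: np.ndarray   # jump locations, strictly increasing
    values: np.ndarray  # function value at and after each jump

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.zeros_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)


def nelson_aalen(time, event) -> StepFunction:
    """Nelson-Aalen cumulative-hazard estimator sum(d_j / n_j)."""
    time, event = _check_outcomes(time, event)
    event_times = np.unique(time[event == 1])
    increments = []
    for t in event_times:
        d = int(np.sum((time == t) & (event == 1)))
        n_at_risk = int(np.sum(time >= t))
        increments.append(d / n_at_risk)
    values = np.cumsum(increments) if increments else np.array([])
    return StepFunction(times=event_times, values=values)


@dataclass
class DevianceResiduals:
    martingale: np.ndarray
    deviance: np.ndarray
    cumulative_hazard: np.ndarray  # Lambda-hat evaluated at each t_i


def null_deviance_residuals(time, event) -> DevianceResiduals:
    """Martingale and deviance residuals from the covariate-free model."""
    time, event = _check_outcomes(time, event)
    if time.size < 2:
        raise ValueError("need at least 2 outcomes")
    if event.sum() == 0:
        raise ValueError("all-censored input: residuals carry no signal")
    cumhaz = nelson_aalen(time, event)(time)
    m = event - cumhaz
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(event == 1, np.log(np.maximum(event - m, 1e-300)), 0.0)
    inner = -2.0 * (m + event * log_term)
    d = np.sign(m) * np.sqrt(np.maximum(inner, 0.0))
    return DevianceResiduals(martingale=m, deviance=d, cumulative_hazard=cumhaz)


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate with median survival.

    ``median`` is the smallest observed time at which the survival curve
    drops to 0.5 or below, or ``nan`` when the curve never reaches 0.5.
    """

    survival: StepFunction
    median: float
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(time, event) -> KMEstimate:
    time, event = _check_outcomes(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    values = sf.to_numpy(dtype=float)
    # drop the t=0 anchor; StepFunction is 1 before the first jump
    mask = times > 0
    step = StepFunction(times=times[mask], values=values[mask])
    below = values <= 0.5
    median = float(times[below][0]) if below.any() else float("nan")
    return KMEstimate(
        survival=step, median=median, n=int(time.size), n_events=int(event.sum())
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time, event = _check_outcomes(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"exactly 2 groups required, got {labels.size}")
    if event.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    a = group == labels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a],
                      event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFitResult:
    """Cox proportional-hazards fit (Breslow tie handling)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    converged: bool
    monotone_likelihood: bool

    def row(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "hr": float(self.hazard_ratio[i]),
            "ci_lower": float(self.ci_lower[i]),
            "ci_upper": float(self.ci_upper[i]),
            "p": float(self.p_value[i]),
        }


def _cox_loglik(beta, time, event, X):
    """Breslow partial log-likelihood, gradient, and information matrix."""
    order = np.argsort(-time)  # decreasing time
    t, d, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    # cap to avoid overflow during monotone-likelihood divergence
    w = np.exp(np.clip(eta, -500, 500))
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    ll, grad, info = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1],) * 2)
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set = samples with time >= t[i] = indices 0..j
        deaths = np.nonzero(d[i : j + 1])[0] + i
        if deaths.size:
            D = deaths.size
            S0 = cum_w[j]
            S1 = cum_wx[j]
            S2 = cum_wxx[j]
            ll += eta[deaths].sum() - D * np.log(S0)
            grad += Xs[deaths].sum(axis=0) - D * S1 / S0
            info += D * (S2 / S0 - np.outer(S1, S1) / S0**2)
        i = j + 1
    return ll, grad, info


def cox_fit(time, event, X, names=None, max_iter=100, tol=1e-9) -> CoxFitResult:
    """Fit a Cox model by Newton-Raphson on the Breslow partial likelihood.

    Raises on constant covariates or a singular information matrix;
    flags (rather than raises) non-convergence and monotone-likelihood
    divergence, as happens with complete separation or zero-event strata.
    """
    time, event = _check_outcomes(time, event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if n < p + 1:
        raise ValueError(f"n={n} too small for {p} covariates")
    const = np.nonzero(X.std(axis=0) == 0)[0]
    if const.size:
        raise ValueError(f"constant covariate(s): {[names[i] for i in const]}")
    if event.sum() == 0:
        raise ValueError("no events: partial likelihood is constant")

    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    monotone = False
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik(beta, time, event, X)
        if np.linalg.norm(np.abs(beta)) > 20:
            monotone = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix in Cox fit"
            ) from exc
        # step-halving to guarantee monotone likelihood ascent
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, _, _ = _cox_loglik(cand, time, event, X)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2
        beta = beta + alpha * step
        if np.max(np.abs(grad)) < tol or abs(ll_new - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
    ll, grad, info = _cox_loglik(beta, time, event, X)
    if np.max(np.abs(beta)) > 15:
        monotone = True
        converged = False
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    return CoxFitResult(
        names=list(names),
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci_lower=np.exp(np.clip(beta - zc * se, -700, 700)),
        ci_upper=np.exp(np.clip(beta + zc * se, -700, 700)),
        p_value=pvals,
        log_likelihood=float(ll),
        converged=converged,
        monotone_likelihood=monotone,
    )


def cox_score_test(time, event, x) -> float:
    """Score (Rao) test statistic at beta=0 for a single covariate.

    Equals the log-rank chi-square for a binary covariate without ties.
    """
    time, event = _check_outcomes(time, event)
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    _, grad, info = _cox_loglik(np.zeros(1), time, event, X)
    return float(grad[0] ** 2 / info[0, 0])


def harrell_c(scores, time, event) -> float:
    """Harrell's concordance index: higher score must mean higher risk.

    A pair is comparable iff the shorter time is an event (pairs with
    equal times and both events are excluded).  Tied scores on
    comparable pairs count 0.5.
    """
    time, event = _check_outcomes(time, event)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != time.shape:
        raise ValueError("scores must align with outcomes")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    # comparable: t_i < t_j and event_i (i the earlier sample)
    ti = time[:, None]
    tj = time[None, :]
    di = event[:, None].astype(bool)
    comparable = (ti < tj) & di
    si = scores[:, None]
    sj = scores[None, :]
    concordant = comparable & (si > sj)
    tied = comparable & (si == sj)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)
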