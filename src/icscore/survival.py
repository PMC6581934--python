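"""Survival and association statistics, implemented from first principles.

The cohort analysis needs four classical procedures: the Kaplan–Meier
product-limit estimator with Greenwood variance, the k-sample log-rank
test, Cox proportional-hazards regression with Breslow tie handling, and
the Pearson chi-square test of association.  They are written here
directly from their defining formulas — the point of this module — with
established packages (lifelines, scipy) used only as independent oracles
in the test-suite.

All p-values are two-sided.  Times are in months, strictly positive;
event indicators are 0/1 with ties between deaths and censorings at the
same time resolved deaths-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxModel",
    "ContingencyResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "CoxPH",
    "chisq_test",
    "ConvergenceError",
]

_Z95 = norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """Cox partial likelihood failed to converge (e.g. complete separation)."""


def _check_times(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be equal-length 1-D arrays")
    if len(time) == 0:
        raise ValueError("at least one record required")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("times must be positive and finite")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``; ``variance`` is the Greenwood estimate of
    Var S(t).  ``median`` is the earliest time with S(t) ≤ 0.5 (NaN when
    never reached) with a Brookmeyer–Crowley 95% CI from inversion of the
    log(−log) Greenwood band.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    median: float
    median_ci: tuple[float, float]
    _all_times: np.ndarray = field(repr=False, default=None)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def rates_12_36_60(self) -> tuple[float, float, float]:
        """Survival at 12, 36, 60 months (the 1/3/5-year rates)."""
        return tuple(self.survival_at(t) for t in (12.0, 36.0, 60.0))


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier estimator with Greenwood variance and median CI."""
    time, event = _check_times(time, event)
    # deaths before censorings at tied times: sort by (time, 1-event)
    order = np.lexsort((1 - event, time))
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    n_risk = np.array([np.sum(t >= u) for u in ev_times], dtype=float)
    n_ev = np.array([np.sum((t == u) & (e == 1)) for u in ev_times], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - n_ev / n_risk
        surv = np.cumprod(frac)
        # Greenwood: Var = S(t)^2 * sum d/(n(n-d))
        gw = np.cumsum(n_ev / (n_risk * (n_risk - n_ev)))
        var = surv**2 * gw
    var = np.where(np.isfinite(var), var, 0.0)

    below = np.nonzero(surv <= 0.5)[0]
    median = float(ev_times[below[0]]) if len(below) else float("nan")

    # Brookmeyer–Crowley: times where |log(-log S) - log(-log 0.5)| <= z*se_g
    lo = hi = float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (surv > 0) & (surv < 1)
        g = np.log(-np.log(surv[ok]))
        se_g = np.sqrt(var[ok]) / np.abs(surv[ok] * np.log(surv[ok]))
        inside = np.abs(g - np.log(-np.log(0.5))) <= _Z95 * se_g
    if np.any(inside):
        sel = np.nonzero(ok)[0][inside]
        lo = float(ev_times[sel[0]])
        # upper limit open when the band still covers 0.5 at the last event time
        hi = float(ev_times[sel[-1]]) if sel[-1] < len(ev_times) - 1 else float("nan")
    return KMCurve(ev_times, surv, var, n_risk, n_ev, median, (lo, hi), t)


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(time, event, group) -> LogRankResult:
    """k-sample log-rank test with hypergeometric variance.

    ``group`` is any k-level factor, k ≥ 2, every level nonempty.  The
    statistic is referred to a chi-square distribution with k−1 degrees
    of freedom.
    """
    time, event = _check_times(time, event)
    group = np.asarray(group)
    levels, gidx = np.unique(group, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")
    ev_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in ev_times:
        at_risk = time >= u
        n = at_risk.sum()
        d = ((time == u) & (event == 1)).sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(time == u) & (event == 1)], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            p = n_g / n
            # multivariate hypergeometric covariance of deaths per group
            V += d * (n - d) / (n - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(stat, df, float(chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxModel:
    """Fitted Cox proportional-hazards model (Breslow ties, Wald CIs)."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + _Z95 * self.se)

    def summary(self) -> dict:
        with np.errstate(over="ignore"):  # huge SE legitimately gives inf CI bound
            return {
                name: {
                    "coef": float(b), "hr": float(np.exp(b)), "se": float(s),
                    "ci_95": [float(np.exp(b - _Z95 * s)),
                              float(np.exp(b + _Z95 * s))],
                }
                for name, b, s in zip(self.names, self.coef, self.se)
            }


def _breslow_loglik_grad_hess(beta, X, time, event, ties: str = "breslow"):
    """Cox partial log-likelihood with gradient and Hessian.

    Risk-set sums are accumulated from the largest time downwards in a
    single pass (O(n p²) after sorting).  ``ties`` selects the Breslow
    (default) or Efron approximation for tied death times; they coincide
    on tie-free data.
    """
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    n, p = Xs.shape
    eta = Xs @ beta
    eta -= eta.max()  # guard overflow; cancels in the ratios
    w = np.exp(np.maximum(eta, -700))  # risk-set sum stays positive
    w = np.maximum(w, 1e-290)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:  # absorb the whole tied block
            s0 += w[j]
            s1 += w[j] * Xs[j]
            s2 += w[j] * np.outer(Xs[j], Xs[j])
            j += 1
        ev = es[i:j] == 1
        d = int(ev.sum())
        if d:
            xb = Xs[i:j][ev]
            ll += eta[i:j][ev].sum()
            if ties == "breslow" or d == 1:
                mu = s1 / s0
                ll -= d * np.log(s0)
                grad += xb.sum(axis=0) - d * mu
                hess -= d * (s2 / s0 - np.outer(mu, mu))
            else:  # Efron: deflate the tied-death block progressively
                wd = w[i:j][ev]
                d0 = wd.sum()
                d1 = (wd[:, None] * xb).sum(axis=0)
                d2 = np.einsum("k,ki,kj->ij", wd, xb, xb)
                grad += xb.sum(axis=0)
                for l in range(d):
                    f = l / d
                    e0 = s0 - f * d0
                    e1 = s1 - f * d1
                    e2 = s2 - f * d2
                    mu = e1 / e0
                    ll -= np.log(e0)
                    grad -= mu
                    hess -= e2 / e0 - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def cox_fit(X, time, event, names: list[str] | None = None,
            tol: float = 1e-8, max_iter: int = 100,
            ties: str = "breslow") -> CoxModel:
    """Maximise the Cox partial likelihood by damped Newton iterations.

    ``X`` is an (n, p) design matrix of pre-expanded (reference-coded)
    covariates.  Iterates until the gradient's max-norm drops below
    ``tol``; each Newton step is halved until the log-likelihood does not
    decrease.  Tied death times use the Breslow approximation by default
    (``ties="efron"`` selects Efron's).  Raises
    :class:`ConvergenceError` on non-convergence or a monotone
    likelihood (complete separation); a constant covariate is an input
    error.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    time, event = _check_times(time, event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if event.sum() == 0:
        raise ValueError("no events: Cox model is undefined")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate in design matrix")

    beta = np.zeros(p)
    ll, grad, hess = _breslow_loglik_grad_hess(beta, X, time, event, ties)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Hessian in Cox fit") from exc
        # damping: halve until the partial likelihood does not decrease
        # (up to float noise, which scales with |ll| near the optimum)
        alpha = 1.0
        slack = 1e-10 * (abs(ll) + 1.0)
        for _ in range(40):
            cand = beta + alpha * step
            ll_new, grad_new, hess_new = _breslow_loglik_grad_hess(
                cand, X, time, event, ties)
            if ll_new >= ll - slack:
                break
            alpha /= 2
        else:
            raise ConvergenceError("step-halving failed: monotone likelihood?")
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
    if np.max(np.abs(beta)) > 50:
        raise ConvergenceError("diverging coefficient: complete separation suspected")
    cov = np.linalg.inv(-hess)
    if not np.all(np.diag(cov) > 0):
        raise ConvergenceError("non-positive-definite information matrix")
    se = np.sqrt(np.diag(cov))
    return CoxModel(list(names), beta, se, float(ll), it, True)


class CoxPH:
    """Cox proportional-hazards regression, scikit-learn style.

    A thin estimator wrapper over :func:`cox_fit`: ``fit(X, y)`` with
    ``y`` a structured/2-column array of (time, event), fitted attributes
    ``coef_``, ``se_``, ``hazard_ratios_``; ``predict(X)`` returns the
    linear risk score Xβ (higher = greater hazard).
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "CoxPH":
        for k, v in params.items():
            if k not in ("tol", "max_iter"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, feature_names: list[str] | None = None) -> "CoxPH":
        y = np.asarray(y, dtype=float)
        model = cox_fit(X, y[:, 0], y[:, 1].astype(int), names=feature_names,
                        tol=self.tol, max_iter=self.max_iter)
        self.model_ = model
        self.coef_ = model.coef
        self.se_ = model.se
        self.hazard_ratios_ = model.hazard_ratios
        self.log_likelihood_ = model.loglik
        self.n_iter_ = model.n_iter
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_


# ---------------------------------------------------------------------------
# Pearson chi-square


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    statistic: float
    df: int
    p_value: float
    dropped_rows: tuple[int, ...]
    dropped_cols: tuple[int, ...]


def chisq_test(table) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    All-zero rows and columns are dropped before computing expected
    counts; the degrees of freedom use the reduced table.  A table left
    with a single row or column is degenerate and raises ``ValueError``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0) or np.any(obs != np.floor(obs)):
        raise ValueError("table must hold nonnegative integers")
    if obs.sum() == 0:
        raise ValueError("table total must be positive")
    row_zero = np.nonzero(obs.sum(axis=1) == 0)[0]
    col_zero = np.nonzero(obs.sum(axis=0) == 0)[0]
    red = np.delete(np.delete(obs, row_zero, axis=0), col_zero, axis=1)
    r, c = red.shape
    if r < 2 or c < 2:
        raise ValueError("degenerate table: fewer than two nonzero rows or columns")
    expected = np.outer(red.sum(axis=1), red.sum(axis=0)) / red.sum()
    stat = float(((red - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return ContingencyResult(
        obs.astype(int), stat, df, float(chi2.sf(stat, df)),
        tuple(int(i) for i in row_zero), tuple(int(i) for i in col_zero),
    )
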