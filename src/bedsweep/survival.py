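"""Time-to-event machinery implemented from first principles.

Provides the product-limit (Kaplan–Meier) estimator and its cumulative
incidence, the two-group log-rank test, Cox proportional-hazards regression
(Newton–Raphson on the log partial likelihood with Breslow or Efron ties
handling), variance-inflation-factor collinearity diagnostics, and one-way
ANOVA.  Established survival packages serve only as independent oracles in
the test suite; the estimators here are self-contained.

Conventions: time is measured in days from radiotherapy completion;
``event`` is 1 when the outcome (post-radiotherapy edema) was observed and
0 when follow-up ended without it (right censoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    InvalidDesignError,
    InvalidParameterError,
    UndefinedTestError,
)

__all__ = [
    "KaplanMeierEstimate",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "vif",
    "AnovaResult",
    "one_way_anova",
]


def _validate_time_event(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if t.ndim != 1 or t.shape != e.shape:
        raise InvalidParameterError("time and event must be equal-length 1-D sequences")
    if t.size == 0:
        raise EmptyInputError("empty survival sample")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise InvalidParameterError("times must be finite and non-negative")
    if not set(np.unique(e).tolist()) <= {0, 1}:
        raise InvalidParameterError("event indicators must be 0 or 1")
    return t, e.astype(int)


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with at least one event,
    ascending; ``survival[k]`` is S(t) for t in [event_times[k],
    event_times[k+1]).  S(0) = 1 and the function is right-continuous.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        """S(t), evaluated elementwise (right-continuous step function)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def cumulative_incidence_at(self, t) -> np.ndarray:
        """1 - S(t): cumulative incidence of the event by time t."""
        return 1.0 - self.survival_at(t)


def km_estimate(time, event) -> KaplanMeierEstimate:
    """Kaplan–Meier product-limit estimator of the survival function."""
    t, e = _validate_time_event(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    at_risk = np.empty(uniq.size, dtype=int)
    d = np.empty(uniq.size, dtype=int)
    for k, u in enumerate(uniq):
        at_risk[k] = int(np.sum(t >= u))
        d[k] = int(np.sum((t == u) & (e == 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk) if uniq.size else np.empty(0)
    return KaplanMeierEstimate(
        event_times=uniq, survival=surv, n_at_risk=at_risk, n_events=d, n=int(t.size)
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank test (observed minus expected over pooled event
    times; chi-square with 1 df)."""
    ta, ea = _validate_time_event(time_a, event_a)
    tb, eb = _validate_time_event(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise UndefinedTestError("log-rank test undefined: no events in either group")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    o1 = e1 = v = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n_j = float(at_risk.sum())
        n1 = float(np.sum(at_risk & (g == 0)))
        d_j = float(np.sum((t == u) & (e == 1)))
        d1 = float(np.sum((t == u) & (e == 1) & (g == 0)))
        o1 += d1
        e1 += d_j * n1 / n_j
        if n_j > 1:
            v += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    total = float(ea.sum() + eb.sum())
    if v <= 0:
        return LogrankResult(0.0, 1.0, (o1, total - o1), (e1, total - e1))
    stat = (o1 - e1) ** 2 / v
    return LogrankResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
        observed=(o1, total - o1),
        expected=(e1, total - e1),
    )


@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox proportional-hazards model.

    Per covariate: log-hazard coefficient, Wald standard error, hazard
    ratio exp(coef) with its 95% CI exp(coef +/- 1.96 SE), and the
    two-sided Wald p-value.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "p_value": self.p_value,
            },
            index=list(self.names),
        )


def _cox_loglik_deriv(beta, t, e, x, ties):
    """Log partial likelihood, score vector and observed information.

    Event times are grouped; ``ties`` selects the Breslow or Efron
    approximation for tied event times (they coincide when no two events
    share a time).
    """
    p = x.shape[1]
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for u in np.unique(t[e == 1]):
        risk = t >= u
        dead = (t == u) & (e == 1)
        d = int(dead.sum())
        s0 = float(w[risk].sum())
        s1 = w[risk] @ x[risk]
        s2 = (w[risk, None] * x[risk]).T @ x[risk]
        sx = x[dead].sum(axis=0)
        ll += float(eta[dead].sum())
        if ties == "breslow" or d == 1:
            ll -= d * np.log(s0)
            mean = s1 / s0
            score += sx - d * mean
            info += d * (s2 / s0 - np.outer(mean, mean))
        else:  # efron
            s0d = float(w[dead].sum())
            s1d = w[dead] @ x[dead]
            s2d = (w[dead, None] * x[dead]).T @ x[dead]
            for l in range(d):
                f = l / d
                den = s0 - f * s0d
                num1 = s1 - f * s1d
                num2 = s2 - f * s2d
                mean = num1 / den
                ll -= np.log(den)
                score += sx / d - mean
                info += num2 / den - np.outer(mean, mean)
    return ll, score, info


def cox_fit(
    time,
    event,
    covariates,
    names=None,
    ties: str = "breslow",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    time, event
        Follow-up time (days) and event indicator per subject.
    covariates
        2-D design (subjects x covariates) or a DataFrame (columns become
        covariate names).
    ties
        ``"breslow"`` (default, the SPSS convention) or ``"efron"``.

    Monotone-likelihood separation (a covariate perfectly ordering events)
    does not raise; the fit is returned with ``converged=False`` and a
    diagnostic message, and a warning is emitted.
    """
    if ties not in ("breslow", "efron"):
        raise InvalidParameterError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    if isinstance(covariates, pd.DataFrame):
        if names is None:
            names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    t, e = _validate_time_event(time, event)
    if x.shape[0] != t.size:
        raise InvalidParameterError("covariate rows must match the number of subjects")
    if not np.all(np.isfinite(x)):
        raise InvalidDesignError("covariates must be finite")
    if e.sum() == 0:
        raise InvalidDesignError("Cox model requires at least one event")
    const = np.ptp(x, axis=0) == 0
    if np.any(const):
        bad = [i for i, c in enumerate(const) if c]
        raise InvalidDesignError(f"constant covariate column(s): {bad}")
    p = x.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = tuple(str(n) for n in names)

    beta = np.zeros(p)
    ll, score, info = _cox_loglik_deriv(beta, t, e, x, ties)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik_deriv(new_beta, t, e, x, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik_deriv(new_beta, t, e, x, ties)
            halvings += 1
        delta_ll = new_ll - ll
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < score_tol or abs(delta_ll) < loglik_tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    # monotone-likelihood separation: the partial likelihood plateaus as a
    # coefficient runs to +/- infinity, so Newton "converges" at a large
    # coefficient with an exploding Wald SE
    diverged = (np.abs(beta) > 50) | (se > 100.0 * np.maximum(1.0, np.abs(beta)))
    if np.any(diverged):
        converged = False
        bad = ", ".join(names[j] for j in np.flatnonzero(diverged))
        message = (
            f"possible monotone-likelihood separation in covariate(s) {bad}; "
            "estimates and Wald intervals are unreliable"
        )
        warnings.warn(message, RuntimeWarning, stacklevel=2)
    elif not converged:
        message = f"Newton-Raphson did not converge in {max_iter} iterations"
        warnings.warn(message, RuntimeWarning, stacklevel=2)
    z = np.zeros_like(beta)
    ok = se > 0
    z[ok] = beta[ok] / se[ok]
    z[~ok & (beta != 0)] = np.inf
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci95_low=np.exp(beta - 1.959963984540054 * se),
        ci95_high=np.exp(beta + 1.959963984540054 * se),
        p_value=2.0 * stats.norm.sf(np.abs(z)),
        log_likelihood=float(ll),
        iterations=it,
        converged=converged,
        message=message,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors via auxiliary least-squares regressions.

    For each column j, regress it (with intercept) on the remaining columns
    and report 1 / (1 - R^2_j).  Exactly collinear columns get ``inf``.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
    x = design.to_numpy(dtype=float)
    n, p = x.shape
    if n < 3:
        raise InvalidDesignError("VIF requires at least 3 rows")
    if p < 2:
        raise InvalidDesignError("VIF requires at least 2 columns")
    if np.any(np.ptp(x, axis=0) == 0):
        raise InvalidDesignError("VIF undefined for constant columns")
    out = {}
    for j, name in enumerate(design.columns):
        yj = x[:, j]
        zj = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(zj, yj, rcond=None)
        resid = yj - zj @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across k groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise InvalidParameterError("ANOVA needs >= 2 non-empty groups")
    n = sum(g.size for g in groups)
    k = len(groups)
    if n <= k:
        raise InvalidParameterError("ANOVA needs total n greater than the number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        return AnovaResult(np.inf, 0.0, dfb, dfw)
    f = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(f), float(stats.f.sf(f, dfb, dfw)), dfb, dfw)
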