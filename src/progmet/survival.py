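"""Survival statistics engine: Kaplan-Meier, log-rank, Cox proportional hazards.

The Cox fitter maximizes the Breslow partial likelihood by Newton iterations
(gradient infinity-norm < 1e-8), reports Wald 95% confidence intervals and a
likelihood-ratio test against the null model.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "ConvergenceError",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]


class ConvergenceError(RuntimeError):
    """Raised on Newton non-convergence or monotone likelihood (separation)."""


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at distinct event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    group_label: str = ""
    n: int = 0

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "group": self.group_label,
            }
        )


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-covariate estimates plus model-level likelihood-ratio test.

    ``ties`` records the partial-likelihood tie convention; confidence
    intervals are Wald intervals at 1.96 standard errors.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    n_used: int
    n_events: int
    loglik: float
    loglik_null: float
    ties: str = "breslow"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hazard_ratio": self.hazard_ratio,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "se": self.se,
                "wald_p": self.wald_p,
            },
            index=self.names,
        )

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "coef": float(self.coef[i]),
            "hazard_ratio": float(self.hazard_ratio[i]),
            "ci95_low": float(self.ci95_low[i]),
            "ci95_high": float(self.ci95_high[i]),
            "wald_p": float(self.wald_p[i]),
        }


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events length mismatch")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times, events, group_label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator (simultaneous-death tie handling)."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    at_risk_all = n - first  # subjects with time >= uniq[k]
    d = np.zeros(uniq.size, dtype=int)
    np.add.at(d, np.searchsorted(uniq, t[e == 1]), 1)
    has_event = d > 0
    ev_times = uniq[has_event]
    at_risk = at_risk_all[has_event]
    d = d[has_event]
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(ev_times, surv, at_risk, d, group_label=group_label, n=n)


def logrank_test(groups: list[tuple]) -> LogrankResult:
    """k-group log-rank chi-square test (df = k-1, two-sided p).

    Parameters
    ----------
    groups : list of (times, events) pairs, one per group.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    tt, ee, gg = [], [], []
    for g, (t, e) in enumerate(groups):
        t, e = _check_surv(t, e)
        tt.append(t)
        ee.append(e)
        gg.append(np.full(t.size, g))
    times = np.concatenate(tt)
    events = np.concatenate(ee)
    grp = np.concatenate(gg)
    if events.sum() == 0:
        raise ValueError("no events")
    k = len(groups)
    ev_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = times >= t
        n = at_risk.sum()
        died = at_risk & (times == t) & (events == 1)
        d = died.sum()
        nj = np.array([(at_risk & (grp == j)).sum() for j in range(k)], dtype=float)
        dj = np.array([(died & (grp == j)).sum() for j in range(k)], dtype=float)
        O += dj
        E += d * nj / n
        if n > 1:
            frac = nj / n
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, p_value=p)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _breslow_ll_grad_info(X, eta, event_idx, tie_start):
    """Breslow partial log-likelihood, gradient and information at linear
    predictor ``eta`` for time-ascending data."""
    w = np.exp(eta)
    S0 = _rev_cumsum(w)
    S1 = _rev_cumsum(X * w[:, None])
    p = X.shape[1]
    XX = X[:, :, None] * X[:, None, :]
    S2 = _rev_cumsum(XX * w[:, None, None])
    s = tie_start[event_idx]
    s0 = S0[s]
    m = S1[s] / s0[:, None]
    ll = float(np.sum(eta[event_idx]) - np.sum(np.log(s0)))
    grad = X[event_idx].sum(axis=0) - m.sum(axis=0)
    info = (S2[s] / s0[:, None, None]).sum(axis=0) - (m[:, :, None] * m[:, None, :]).sum(axis=0)
    return ll, grad, info


def cox_fit(
    covariates,
    times,
    events,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    covariates : array-like (n, p) or (n,) or DataFrame
        Covariate matrix; constant columns are rejected.
    times, events : array-like
        Follow-up times (>= 0) and event indicators (0/1).
    """
    if isinstance(covariates, pd.DataFrame):
        if names is None:
            names = [str(c) for c in covariates.columns]
        covariates = covariates.to_numpy(dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times, events = _check_surv(times, events)
    n, p = X.shape
    if n != times.size:
        raise ValueError("covariate rows must match number of samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing/non-finite covariate values")
    if events.sum() < 1:
        raise ValueError("no events")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant covariates: {bad}")

    order = np.argsort(times, kind="stable")
    t_s = times[order]
    e_s = events[order]
    X_s = X[order]
    center = X_s.mean(axis=0)
    X_s = X_s - center
    event_idx = np.flatnonzero(e_s == 1)
    tie_start = np.searchsorted(t_s, t_s, side="left")

    beta = np.zeros(p)
    ll, grad, info = _breslow_ll_grad_info(X_s, X_s @ beta, event_idx, tie_start)
    ll_null = ll
    converged = False
    x_sd = X_s.std(axis=0)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving safeguards against overshoot; the acceptance slack is
        # relative to |ll| so float noise near the optimum cannot stall it
        slack = 1e-10 * (1.0 + abs(ll))
        for _half in range(30):
            beta_new = beta + step
            ll_new, grad_new, info_new = _breslow_ll_grad_info(
                X_s, X_s @ beta_new, event_idx, tie_start
            )
            if np.isfinite(ll_new) and ll_new >= ll - slack:
                break
            step = step / 2.0
        else:
            raise ConvergenceError("step-halving failed")
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        # |beta| * sd(x) > 15 means HR > e^15 per covariate SD: monotone
        # likelihood / perfect separation, not a real effect
        if np.max(np.abs(beta) * x_sd) > 15:
            raise ConvergenceError(
                "monotone likelihood (possible perfect separation); |beta| diverged"
            )
    if not converged and np.max(np.abs(grad)) >= tol:
        raise ConvergenceError(f"Newton did not converge in {max_iter} iterations")

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix at optimum") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if np.any(se == 0):
        raise ConvergenceError("zero standard error")
    z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    lrt_stat = max(2.0 * (ll - ll_null), 0.0)
    lrt_p = float(stats.chi2.sf(lrt_stat, p))
    return CoxResult(
        names=list(names),
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci95_low=np.exp(beta - 1.96 * se),
        ci95_high=np.exp(beta + 1.96 * se),
        wald_p=wald_p,
        lrt_stat=lrt_stat,
        lrt_df=p,
        lrt_p=lrt_p,
        n_used=n,
        n_events=int(events.sum()),
        loglik=ll,
        loglik_null=ll_null,
        ties="breslow",
    )
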