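"""Survival-analysis primitives: Kaplan–Meier curves, univariate Cox fits for a
binary group covariate, and the k-group log-rank test.

These are the statistics every cutoff scan in :mod:`survddg.ddg1d`,
:mod:`survddg.ddg2d` and :mod:`survddg.swvg` calls, so they are written as
vectorised NumPy routines rather than delegating to a general-purpose survival
library: a single gene scan evaluates hundreds of candidate groupings and a
signature search evaluates thousands.

Conventions
-----------
* A cohort is ``(time, event)``: nonnegative follow-up times and a 0/1 event
  indicator (1 = event observed, 0 = censored).
* Group codes are small positive integers; for two groups the convention
  throughout the package is ``1 = low risk, 2 = high risk``.
* Tied event times are handled with the Breslow approximation of the partial
  likelihood (each tied event contributes its own factor with the full risk
  set). This differs from the Efron default of most general libraries.
* P-values are floored at :data:`P_FLOOR` so that ``-log P`` voting weights
  are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300
#: cap on |beta| used when the partial likelihood is monotone (separation)
BETA_CAP = 20.0
_NEWTON_TOL = 1e-8
_NEWTON_MAXITER = 50


def check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Validate and coerce a cohort's follow-up times and event indicators."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be one-dimensional and aligned")
    if not np.all(np.isfinite(time)):
        raise ValueError("survival times must be finite")
    if np.any(time < 0):
        raise ValueError("survival times must be nonnegative")
    uniq = np.unique(event)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(np.int8)


@dataclass(frozen=True)
class CoxFitResult:
    """Univariate Cox fit of a binary grouping.

    ``beta`` is the log hazard ratio of group 2 relative to group 1;
    ``wald_stat`` is ``(beta / se)**2``, referred to chi-square(1).  The
    baseline hazard is eliminated by the partial likelihood and is not
    estimated.  ``converged`` is False when Newton iteration hit the
    separation cap or the iteration limit.
    """

    beta: float
    se: float
    wald_stat: float
    wald_p: float
    logrank_stat: float
    logrank_p: float
    converged: bool
    n_events: int

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))


def _risk_table(time, event, x):
    """Per-event-time risk/death counts for a binary covariate ``x``.

    Returns ``(d, d1, n, n1)`` arrays over the distinct event times:
    total deaths, deaths with x=1, total at risk, at risk with x=1.
    """
    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    n_total = len(t)
    # distinct event times and, for each, the index of the first patient with
    # that time (everyone at or after that index is at risk)
    uniq = np.unique(t[e == 1])
    start = np.searchsorted(t, uniq, side="left")
    n = n_total - start
    cum_x = np.concatenate([[0.0], np.cumsum(xs)])
    n1 = cum_x[-1] - cum_x[start]
    is_ev = e == 1
    # deaths per distinct event time
    idx = np.searchsorted(uniq, t[is_ev])
    d = np.bincount(idx, minlength=len(uniq)).astype(float)
    d1 = np.bincount(idx, weights=xs[is_ev], minlength=len(uniq))
    return d, d1, n.astype(float), n1


def _breslow_newton(d, d1, n, n1):
    """Maximise the Breslow partial log-likelihood for a binary covariate.

    All inputs are per-distinct-event-time count vectors. Returns
    ``(beta, se, converged)``; supports vector inputs of shape (C, T) to fit
    C candidate groupings at once (used by the cutoff scans).
    """
    d = np.atleast_2d(d)
    d1 = np.atleast_2d(d1)
    n = np.atleast_2d(n)
    n1 = np.atleast_2d(n1)
    C = d.shape[0]
    beta = np.zeros(C)
    converged = np.zeros(C, dtype=bool)
    info = np.zeros(C)
    active = np.ones(C, dtype=bool)
    for _ in range(_NEWTON_MAXITER):
        eb = np.exp(beta[active, None])
        denom = (n[active] - n1[active]) + n1[active] * eb
        p = n1[active] * eb / denom
        score = np.sum(d1[active] - d[active] * p, axis=1)
        fisher = np.sum(d[active] * p * (1.0 - p), axis=1)
        info[active] = fisher
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(fisher > 0, score / np.maximum(fisher, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        newbeta = np.clip(beta[active] + step, -BETA_CAP, BETA_CAP)
        done = np.abs(newbeta - beta[active]) < _NEWTON_TOL
        beta[active] = newbeta
        conv_now = np.flatnonzero(active)[done]
        converged[conv_now] = np.abs(beta[conv_now]) < BETA_CAP
        active[conv_now] = False
        if not active.any():
            break
    # final information at the solution for the SE
    eb = np.exp(beta[:, None])
    denom = (n - n1) + n1 * eb
    p = n1 * eb / denom
    info = np.sum(d * p * (1.0 - p), axis=1)
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
    return beta, se, converged


def _logrank_from_table(d, d1, n, n1):
    """Two-group log-rank statistic from per-event-time counts (vectorisable)."""
    d = np.atleast_2d(d)
    d1 = np.atleast_2d(d1)
    n = np.atleast_2d(n)
    n1 = np.atleast_2d(n1)
    e1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n1 / n) * (1.0 - n1 / n) * np.where(n > 1, (n - d) / np.maximum(n - 1, 1), 0.0)
    o_minus_e = np.sum(d1 - e1, axis=1)
    var = np.sum(v, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, o_minus_e**2 / np.maximum(var, 1e-300), 0.0)
    return stat


def fit_cox_binary(time, event, groups) -> CoxFitResult:
    """Fit the univariate Cox model for a two-group (or recoded binary) split.

    Parameters
    ----------
    time, event:
        Cohort follow-up data (see :func:`check_survival`).
    groups:
        Integer codes with exactly two distinct values; the larger code is
        treated as the x=1 level, so ``beta > 0`` means the higher code has
        the higher hazard.

    Notes
    -----
    Ties are handled with the Breslow form of the partial likelihood; the
    Wald statistic is ``(beta/se)**2`` on chi-square(1).  Complete separation
    does not raise: ``beta`` is capped at +/-20 and ``converged`` set False.
    """
    time, event = check_survival(time, event)
    groups = np.asarray(groups)
    codes = np.unique(groups)
    if len(codes) != 2:
        raise ValueError(f"need exactly 2 nonempty groups, got {len(codes)}")
    if event.sum() == 0:
        raise ValueError("no events in cohort; Cox fit undefined")
    x = (groups == codes[1]).astype(float)
    d, d1, n, n1 = _risk_table(time, event, x)
    beta, se, conv = _breslow_newton(d, d1, n, n1)
    beta, se, conv = float(beta[0]), float(se[0]), bool(conv[0])
    wald = (beta / se) ** 2 if np.isfinite(se) and se > 0 else 0.0
    wald_p = max(float(stats.chi2.sf(wald, 1)), P_FLOOR)
    lr = float(_logrank_from_table(d, d1, n, n1)[0])
    lr_p = max(float(stats.chi2.sf(lr, 1)), P_FLOOR)
    return CoxFitResult(
        beta=beta, se=se, wald_stat=wald, wald_p=wald_p,
        logrank_stat=lr, logrank_p=lr_p, converged=conv,
        n_events=int(event.sum()),
    )


def logrank_test(time, event, groups) -> tuple[float, float]:
    """k-group log-rank test; returns ``(statistic, p)`` on chi-square(k-1)."""
    time, event = check_survival(time, event)
    groups = np.asarray(groups)
    codes = np.unique(groups)
    k = len(codes)
    if k < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], groups[order]
    uniq = np.unique(t[e == 1])
    start = np.searchsorted(t, uniq, side="left")
    n_at_risk = len(t) - start
    is_ev = e == 1
    tidx = np.searchsorted(uniq, t[is_ev])
    d = np.bincount(tidx, minlength=len(uniq)).astype(float)
    # per-group at-risk and death counts
    O = np.zeros(k)
    E = np.zeros(k)
    nmat = np.zeros((k, len(uniq)))
    for i, c in enumerate(codes):
        xi = (g == c).astype(float)
        cum = np.concatenate([[0.0], np.cumsum(xi)])
        nmat[i] = cum[-1] - cum[start]
        O[i] = np.sum(e[g == c])
        E[i] = np.sum(d * nmat[i] / n_at_risk)
    # covariance of (O - E) restricted to the first k-1 groups
    V = np.zeros((k - 1, k - 1))
    n = n_at_risk.astype(float)
    frac = np.where(n > 1, (n - d) / np.maximum(n - 1, 1.0), 0.0)
    for i in range(k - 1):
        for j in range(k - 1):
            pi = nmat[i] / n
            pj = nmat[j] / n
            if i == j:
                V[i, j] = np.sum(d * pi * (1 - pi) * frac)
            else:
                V[i, j] = -np.sum(d * pi * pj * frac)
    z = (O - E)[: k - 1]
    try:
        stat = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(V) @ z)
    p = max(float(stats.chi2.sf(stat, k - 1)), P_FLOOR)
    return stat, p


def km_estimate(time, event, groups=None) -> dict:
    """Product-limit (Kaplan–Meier) survival curve per group.

    Returns a dict mapping group code to a tidy DataFrame with columns
    ``time, at_risk, events, survival``; with ``groups=None`` a single curve
    keyed ``1`` is returned. Censoring reduces the risk set but never the
    survival estimate.
    """
    time, event = check_survival(time, event)
    if groups is None:
        groups = np.ones(len(time), dtype=int)
    groups = np.asarray(groups)
    out = {}
    for c in np.unique(groups):
        m = groups == c
        t, e = time[m], event[m]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t)
        start = np.searchsorted(t, uniq, side="left")
        at_risk = len(t) - start
        is_ev = e == 1
        d = np.bincount(np.searchsorted(uniq, t[is_ev]), minlength=len(uniq))
        surv = np.cumprod(1.0 - d / at_risk)
        out[int(c)] = pd.DataFrame(
            {"time": uniq, "at_risk": at_risk, "events": d, "survival": surv}
        )
    return out
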