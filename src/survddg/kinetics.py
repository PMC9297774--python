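"""Tumor-growth kinetics and metastatic-foci size-distribution models.

Two nonlinear models:

* exponential tumor volume, ``f(t; a, b) = (a - b) * exp(a t)`` — ``a`` is
  the growth rate per week and ``(a - b)`` the initial tumor volume.  An
  alternative additive form ``f = a - b * exp(a t)`` is selectable for
  comparison.
* shifted log-normal focus-size frequency,
  ``f(x; y0, x0, a, b) = y0 + a * exp(-0.5 * (ln(x / x0) / b)**2)`` fitted
  to a histogram of focus areas — ``x0`` is the modal focus size, ``y0`` a
  constant background count.

Both are least-squares fits with analytic Jacobians and multiple starts;
parameter standard errors come from the Jacobian at the optimum and each
parameter gets a t-test P-value.

Two binning rules for focus areas (square micrometres) are implemented:
``round_kilo`` (bin = area/1000 rounded half-up to the nearest integer) and
``width5000`` (bin k covers ((k-1)*5000, k*5000] for k = 1..20, bin 21 is
everything above 100000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares


@dataclass(frozen=True)
class ExpFitResult:
    a: float
    b: float
    se_a: float
    se_b: float
    p_a: float
    p_b: float
    rss: float
    converged: bool
    model: str

    @property
    def initial_volume(self) -> float:
        return self.a - self.b


@dataclass(frozen=True)
class FociHistogram:
    rule: str
    bins: np.ndarray       # bin index per focus
    counts: pd.Series      # count per occupied bin (index = bin number)
    n_rejected: int        # nonpositive areas dropped

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-centre sizes in the rule's natural units (see module doc)."""
        idx = self.counts.index.to_numpy(dtype=float)
        if self.rule == "round_kilo":
            return idx  # units of 10^3 um^2
        centers = (idx - 0.5) * 5000.0
        centers[idx == 21] = 102_500.0
        return centers


@dataclass(frozen=True)
class ShiftedLogNormalFit:
    y0: float
    x0: float
    a: float
    b: float
    se: tuple
    rss: float
    converged: bool


def _curve(params, t, model):
    a, b = params
    if model == "initial":
        return (a - b) * np.exp(a * t)
    return a - b * np.exp(a * t)


def _jac(params, t, model):
    a, b = params
    e = np.exp(a * t)
    if model == "initial":
        return np.column_stack([e * (1.0 + (a - b) * t), -e])
    return np.column_stack([1.0 - b * t * e, -e])


def fit_exponential(timepoints, volumes, model="initial") -> ExpFitResult:
    """Fit the exponential growth curve by Levenberg–Marquardt least squares.

    Five log-spaced starting growth rates are tried (plus a log-linear
    regression start when volumes are positive) and the best optimum kept.
    Non-convergence is flagged on the result, never raised.
    """
    t = np.asarray(timepoints, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("timepoints and volumes must be aligned 1-D arrays")
    if len(t) < 3:
        raise ValueError("need at least 3 points to fit two parameters")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("inputs must be finite")
    if model not in ("initial", "additive"):
        raise ValueError("model must be 'initial' or 'additive'")

    starts = []
    if np.all(v > 0) and np.ptp(t) > 0:
        slope, intercept = np.polyfit(t, np.log(v), 1)
        if model == "initial" and slope > 0:
            starts.append((slope, slope - np.exp(intercept)))
    for a0 in np.geomspace(0.05, 2.0, 5):
        if model == "initial":
            b0 = a0 - v[np.argmin(t)] * np.exp(-a0 * t.min())
        else:
            b0 = (a0 - v[np.argmin(t)]) * np.exp(-a0 * t.min())
        starts.append((a0, b0))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                lambda p: _curve(p, t, model) - v, x0=x0,
                jac=lambda p: _jac(p, t, model), method="lm",
                xtol=1e-14, ftol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return ExpFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.inf, False, model)
    rss, sol = best
    a, b = sol.x
    dof = max(len(t) - 2, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = np.abs(np.array([a, b]) / se)
    pvals = 2.0 * stats.t.sf(tstats, dof)
    return ExpFitResult(
        a=float(a), b=float(b), se_a=float(se[0]), se_b=float(se[1]),
        p_a=float(pvals[0]), p_b=float(pvals[1]), rss=rss,
        converged=bool(sol.success), model=model,
    )


def bin_foci(areas, rule="round_kilo") -> FociHistogram:
    """Histogram focus areas under one of the two binning rules.

    Nonpositive areas are rejected (counted in ``n_rejected``). Counts sum
    to the number of accepted foci.
    """
    areas = np.asarray(areas, dtype=float)
    ok = areas > 0
    n_rej = int((~ok).sum())
    a = areas[ok]
    if rule == "round_kilo":
        # half-up rounding: ties at .5 go away from zero
        bins = np.floor(a / 1000.0 + 0.5).astype(int)
    elif rule == "width5000":
        bins = np.ceil(a / 5000.0).astype(int)
        bins = np.minimum(bins, 21)
    else:
        raise ValueError("rule must be 'round_kilo' or 'width5000'")
    counts = pd.Series(bins).value_counts().sort_index()
    counts.index.name = "bin"
    return FociHistogram(rule=rule, bins=bins, counts=counts, n_rejected=n_rej)


def fit_shifted_lognormal(hist: FociHistogram) -> ShiftedLogNormalFit:
    """Fit counts vs bin-centre size with the shifted log-normal curve.

    Initialisation: y0 = min count, x0 = modal bin centre, a = count range,
    b = 1; bounds keep x0 and b positive and a nonnegative.  Requires at
    least 5 occupied bins (the model has 4 parameters).  Degenerate
    histograms (e.g. flat) come back flagged non-converged rather than
    raising.
    """
    x = hist.bin_centers
    y = hist.counts.to_numpy(dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least 5 nonempty bins to fit 4 parameters")

    def resid(p):
        y0, x0, a, b = p
        return y0 + a * np.exp(-0.5 * (np.log(x / x0) / b) ** 2) - y

    def jac(p):
        y0, x0, a, b = p
        u = np.log(x / x0) / b
        g = np.exp(-0.5 * u**2)
        return np.column_stack([
            np.ones_like(x),
            a * g * u / (b * x0),
            g,
            a * g * u**2 / b,
        ])

    p0 = np.array([y.min(), x[np.argmax(y)], y.max() - y.min(), 1.0])
    eps = 1e-9
    lo = [-np.inf, eps, 0.0, eps]
    hi = [np.inf, np.inf, np.inf, np.inf]
    best = None
    for b0 in (0.5, 1.0, 2.0):
        start = p0.copy()
        start[3] = b0
        start[1] = max(start[1], eps * 10)
        try:
            sol = least_squares(resid, x0=start, jac=jac, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, max_nfev=5000)
        except Exception:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return ShiftedLogNormalFit(np.nan, np.nan, np.nan, np.nan,
                                   (np.nan,) * 4, np.inf, False)
    rss, sol = best
    y0, x0f, af, bf = sol.x
    dof = max(len(x) - 4, 1)
    try:
        cov = (rss / dof) * np.linalg.inv(sol.jac.T @ sol.jac)
        se = tuple(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    except np.linalg.LinAlgError:
        se = (np.nan,) * 4
    # an amplitude indistinguishable from zero leaves x0 unidentifiable
    identifiable = af > 1e-8 and np.isfinite(se[1])
    return ShiftedLogNormalFit(
        y0=float(y0), x0=float(x0f), a=float(af), b=float(bf), se=se,
        rss=rss, converged=bool(sol.success and identifiable),
    )


def compare_foci_distributions(sample_a, sample_b, paired=False):
    """Rank-based comparison of two focus-size samples.

    Unpaired Mann–Whitney U by default; ``paired=True`` runs the Wilcoxon
    signed-rank test on the per-index differences (samples must then be
    equally long). Returns ``(statistic, p)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal sample sizes")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
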