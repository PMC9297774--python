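"""Bivariate data-driven grouping (2D-DDg).

Two genes' 1D cutoffs split the expression plane into four quadrants; the
method enumerates every way to merge the quadrants into two mutually
exclusive, exhaustive risk regions (seven designs up to label swap) and
keeps the design whose Cox P-value is smallest, subject to the minimum
group-size constraint.  For strongly correlated gene pairs the plane is
first rotated onto the pair's least-squares regression line — an isometry,
so distances between patients are preserved — and the cutoffs are re-derived
on the rotated axes, which decorrelates the two coordinates and typically
sharpens the attainable split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ddg1d import MIN_GROUP_FRAC, as_survival, candidate_cutoffs, fit_ddg1d
from .survival import check_survival, fit_cox_binary

#: the 7 two-colourings of the 4 quadrants, up to label swap: the listed
#: quadrant subset is region "A", its complement region "B".  Quadrant index
#: is (x > cx) + 2*(y > cy).
DESIGNS = (
    (0,),
    (1,),
    (2,),
    (3,),
    (0, 1),
    (0, 2),
    (0, 3),
)


@dataclass(frozen=True)
class RegressionLine:
    """Ordinary-least-squares line y = alpha + beta * x."""

    alpha: float
    beta: float
    residual_sd: float


@dataclass(frozen=True)
class RotatedPair:
    """Coordinates after rotating onto a regression line.

    gamma = atan(beta) is the rotation angle; xr runs along the line,
    yr measures signed distance off it (points on the line map to yr = 0).
    """

    xr: np.ndarray
    yr: np.ndarray
    gamma: float
    line: RegressionLine


@dataclass(frozen=True)
class DDg2DResult:
    gene_pair: tuple
    design: tuple
    rotated: bool
    cutoff_x: float
    cutoff_y: float
    p_value: float
    beta: float
    groups: np.ndarray
    line: RegressionLine | None
    statistic: str


def pair_correlation(x, y, method="kendall") -> tuple[float, float]:
    """Rank correlation between two genes' expressions (Kendall tau by
    default, Spearman selectable)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "kendall":
        res = stats.kendalltau(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'kendall' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def fit_regression(x, y) -> RegressionLine:
    """Least-squares line through the pair cloud; errors on a constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(x) == 0:
        raise ValueError("predictor variance is zero; regression undefined")
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    sd = float(np.std(resid, ddof=2)) if len(x) > 2 else 0.0
    return RegressionLine(alpha=float(alpha), beta=float(beta), residual_sd=sd)


def rotate_coordinates(x, y, line: RegressionLine) -> RotatedPair:
    """Rotate (x, y - alpha) onto the regression line.

    With s = sqrt(1 + beta^2):
    xr = (x + beta*(y - alpha)) / s,  yr = (-beta*x + (y - alpha)) / s.
    This is a proper rotation, hence an isometry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(line.alpha) and np.isfinite(line.beta)):
        raise ValueError("regression line parameters must be finite")
    s = np.sqrt(1.0 + line.beta**2)
    yc = y - line.alpha
    xr = (x + line.beta * yc) / s
    yr = (-line.beta * x + yc) / s
    return RotatedPair(xr=xr, yr=yr, gamma=float(np.arctan(line.beta)), line=line)


def _axis_cutoff(values, time, event, statistic, min_group_frac):
    """1D-DDg optimal cutoff on one axis; None when the axis is degenerate."""
    scale = max(1.0, float(np.max(np.abs(values), initial=0.0)))
    if np.ptp(values) <= 1e-10 * scale or len(np.unique(values)) < 2:
        return None
    res = fit_ddg1d(values, time, event, statistic=statistic,
                    min_group_frac=min_group_frac)
    return None if res is None else res.cutoff


def fit_ddg2d(x, y, survival, rotate_if_correlated=True, corr_alpha=1e-4,
              corr_method="kendall", statistic="wald", gene_pair=("A", "B"),
              min_group_frac=MIN_GROUP_FRAC) -> DDg2DResult | None:
    """Best two-region quadrant design for a gene pair.

    Steps: (1) optionally rotate onto the regression line when the rank
    correlation is significant at ``corr_alpha``; (2) derive each axis's
    1D-DDg cutoff; (3) enumerate the seven quadrant designs, fit a Cox model
    to each admissible split (both regions >= ``min_group_frac`` of
    patients), and return the design minimising the P-value.  Risk labels
    (1 = low, 2 = high) are assigned from group mean survival times.

    When one axis is degenerate (constant, or no admissible cutoff) the
    design space collapses to the single split on the other axis, so with
    rotation disabled and a constant second gene the result equals the 1D
    fit of the first gene.  Returns ``None`` when no admissible design
    exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    time, event = as_survival(survival) if not isinstance(survival, tuple) else check_survival(*survival)

    line = None
    rotated = False
    if rotate_if_correlated:
        _, p_corr = pair_correlation(x, y, method=corr_method)
        if p_corr < corr_alpha and np.var(x) > 0:
            line = fit_regression(x, y)
            rot = rotate_coordinates(x, y, line)
            x, y = rot.xr, rot.yr
            rotated = True

    cx = _axis_cutoff(x, time, event, statistic, min_group_frac)
    cy = _axis_cutoff(y, time, event, statistic, min_group_frac)
    if cx is None and cy is None:
        return None

    n = len(x)
    min_size = int(np.ceil(min_group_frac * n))
    if cx is None or cy is None:
        # degenerate: single-axis split
        vals = y if cx is None else x
        c = cy if cx is None else cx
        membership_list = [(None, vals > c)]
        cx_out = np.nan if cx is None else cx
        cy_out = np.nan if cy is None else cy
    else:
        quad = (x > cx).astype(int) + 2 * (y > cy).astype(int)
        membership_list = [(design, np.isin(quad, design)) for design in DESIGNS]
        cx_out, cy_out = cx, cy

    best = None
    for design, in_a in membership_list:
        na = int(in_a.sum())
        if na < min_size or n - na < min_size:
            continue
        fit = fit_cox_binary(time, event, in_a.astype(int) + 1)
        p = fit.wald_p if statistic == "wald" else fit.logrank_p
        if best is None or p < best[0]:
            best = (p, design, in_a, fit)
    if best is None:
        return None
    p, design, in_a, fit = best
    mean_a = float(np.mean(time[in_a]))
    mean_b = float(np.mean(time[~in_a]))
    groups = np.where(in_a, 2, 1) if mean_a < mean_b else np.where(in_a, 1, 2)
    refit = fit_cox_binary(time, event, groups)
    return DDg2DResult(
        gene_pair=tuple(gene_pair), design=design, rotated=rotated,
        cutoff_x=float(cx_out), cutoff_y=float(cy_out), p_value=float(p),
        beta=float(refit.beta), groups=groups, line=line, statistic=statistic,
    )


class DDgBivariate:
    """Two-gene risk classifier with a scikit-learn estimator surface.

    ``fit(X, y)`` takes ``X`` with exactly two columns and survival labels
    ``y``; ``transform(X)``/``predict(X)`` return risk codes (1 = low,
    2 = high) by re-applying the fitted design, rotation and cutoffs.
    """

    def __init__(self, rotate_if_correlated=True, corr_alpha=1e-4,
                 corr_method="kendall", statistic="wald",
                 min_group_frac=MIN_GROUP_FRAC):
        self.rotate_if_correlated = rotate_if_correlated
        self.corr_alpha = corr_alpha
        self.corr_method = corr_method
        self.statistic = statistic
        self.min_group_frac = min_group_frac

    def get_params(self, deep=True):
        return {
            "rotate_if_correlated": self.rotate_if_correlated,
            "corr_alpha": self.corr_alpha,
            "corr_method": self.corr_method,
            "statistic": self.statistic,
            "min_group_frac": self.min_group_frac,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            names = tuple(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = ("A", "B")
        if X.shape[1] != 2:
            raise ValueError("DDgBivariate requires exactly two genes")
        res = fit_ddg2d(
            X[:, 0], X[:, 1], as_survival(y),
            rotate_if_correlated=self.rotate_if_correlated,
            corr_alpha=self.corr_alpha, corr_method=self.corr_method,
            statistic=self.statistic, gene_pair=names,
            min_group_frac=self.min_group_frac,
        )
        if res is None:
            raise ValueError("no admissible two-region design for this pair")
        self.result_ = res
        # orientation of region A vs risk label, for out-of-sample prediction
        in_a = self._region_membership(X[:, 0], X[:, 1])
        self._a_is_high_ = bool(np.mean(res.groups[in_a] == 2) > 0.5)
        return self

    def _region_membership(self, x, y):
        res = self.result_
        if res.rotated:
            rot = rotate_coordinates(x, y, res.line)
            x, y = rot.xr, rot.yr
        if np.isnan(res.cutoff_y):
            return x > res.cutoff_x
        if np.isnan(res.cutoff_x):
            return y > res.cutoff_y
        quad = (x > res.cutoff_x).astype(int) + 2 * (y > res.cutoff_y).astype(int)
        return np.isin(quad, res.design)

    def predict(self, X):
        import pandas as pd

        if not hasattr(self, "result_"):
            raise RuntimeError("DDgBivariate is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        in_a = self._region_membership(X[:, 0], X[:, 1])
        high = in_a if self._a_is_high_ else ~in_a
        return np.where(high, 2, 1)

    transform = predict
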