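"""One-dimensional data-driven grouping (1D-DDg).

For each gene the method scans candidate expression cutoffs inside the
gene's 10th–90th quantile range, splits the cohort at each candidate, scores
the split with a univariate Cox fit (Wald statistic, or the log-rank test),
and keeps the cutoff minimising the P-value.  Risk labels are assigned
afterwards from group mean survival times — the group with the lower mean
survival is "high risk" (code 2) — so both pro-oncogenic (high expression =
high risk) and suppressor-like genes are discovered automatically.

The minimised P-value is reported raw: no multiple-testing correction is
applied across the candidate grid, so scan minima are optimistically biased.
Reproducibility across independent cohorts (:func:`select_prognostic_genes`)
is the guard against that bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import (
    P_FLOOR,
    _breslow_newton,
    _logrank_from_table,
    check_survival,
)
from scipy import stats as _sstats

from .simulate import PRO_ONCOGENIC, SUPPRESSOR_LIKE

MIN_GROUP_FRAC = 0.10
_MIN_PATIENTS = 20


@dataclass(frozen=True)
class CutoffScan:
    """Per-candidate scan record: cutoffs (ascending) and their P-values."""

    gene_id: str
    cutoffs: np.ndarray
    p_values: np.ndarray
    statistic: str


@dataclass(frozen=True)
class DDg1DResult:
    """Optimal cutoff for one gene and the grouping it induces.

    ``groups`` uses 1 = low risk, 2 = high risk; ``pattern`` says whether
    the high-risk group is the high-expression side (pro-oncogenic) or the
    low-expression side (suppressor-like). ``beta`` is the log hazard ratio
    of high vs low risk (nonnegative by construction of the labels).
    """

    gene_id: str
    cutoff: float
    p_value: float
    beta: float
    statistic: str
    pattern: str
    groups: np.ndarray
    mean_survival: dict
    scan: CutoffScan

    @property
    def group_sizes(self) -> dict:
        return {1: int(np.sum(self.groups == 1)), 2: int(np.sum(self.groups == 2))}


def candidate_cutoffs(values, q_low=0.10, q_high=0.90) -> np.ndarray:
    """Candidate cutoffs for one gene: midpoints between consecutive distinct
    sorted values whose midpoint lies within the [q_low, q_high] quantiles
    (linear-interpolation quantiles).

    Midpoints guarantee no observation ever equals a cutoff, which removes
    the boundary ambiguity of a strict ``value > c`` split. A constant
    vector yields an empty list (the gene is non-informative).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < _MIN_PATIENTS:
        raise ValueError(
            f"need at least {_MIN_PATIENTS} patients for a cutoff scan, got {len(values)}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    distinct = np.unique(values)
    if len(distinct) < 2:
        return np.empty(0)
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    lo, hi = np.quantile(values, [q_low, q_high])
    return mids[(mids >= lo) & (mids <= hi)]


def _scan(values, time, event, cutoffs, statistic, min_group_frac):
    """Vectorised Cox/log-rank P-values for every candidate cutoff.

    Builds the per-event-time risk tables for all candidate splits at once
    and runs the Newton iterations jointly; equivalent to (and regression-
    tested against) calling :func:`survddg.survival.fit_cox_binary` per
    candidate.
    """
    n = len(values)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    v = values[order]
    uniq = np.unique(t[e == 1])
    start = np.searchsorted(t, uniq, side="left")
    n_at_risk = (n - start).astype(float)
    is_ev = e == 1
    tidx = np.searchsorted(uniq, t[is_ev])
    d = np.bincount(tidx, minlength=len(uniq)).astype(float)

    X = v[None, :] > cutoffs[:, None]  # candidates x patients (time-ordered)
    high_n = X.sum(axis=1)
    min_size = int(np.ceil(min_group_frac * n))
    admissible = (high_n >= min_size) & (n - high_n >= min_size)

    cum = np.concatenate([np.zeros((len(cutoffs), 1)), np.cumsum(X, axis=1)], axis=1)
    n1 = cum[:, [-1]] - cum[:, start]
    d1 = np.stack([
        np.bincount(tidx, weights=X[c, is_ev].astype(float), minlength=len(uniq))
        for c in range(len(cutoffs))
    ]) if len(cutoffs) else np.zeros((0, len(uniq)))

    D = np.broadcast_to(d, d1.shape)
    N = np.broadcast_to(n_at_risk, n1.shape)
    if statistic == "wald":
        beta, se, conv = _breslow_newton(D, d1, N, n1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(se > 0, (beta / se) ** 2, 0.0)
        p = np.maximum(_sstats.chi2.sf(w, 1), P_FLOOR)
    elif statistic == "logrank":
        stat = _logrank_from_table(D, d1, N, n1)
        p = np.maximum(_sstats.chi2.sf(stat, 1), P_FLOOR)
        beta = None
    else:
        raise ValueError("statistic must be 'wald' or 'logrank'")
    p = np.where(admissible, p, np.nan)
    return p, admissible


def fit_ddg1d(values, time, event, statistic="wald", gene_id="gene",
              min_group_frac=MIN_GROUP_FRAC):
    """Run the full 1D-DDg scan for one gene.

    Returns a :class:`DDg1DResult` (with the :class:`CutoffScan` attached)
    or ``None`` when the gene is non-informative: no candidate cutoffs, or
    no candidate satisfying the minimum-group-size constraint (each side
    must hold at least ``min_group_frac`` of the patients).

    Ties in the minimised P-value break toward the cutoff closest to the
    median expression value.
    """
    values = np.asarray(values, dtype=float)
    time, event = check_survival(time, event)
    if len(values) != len(time):
        raise ValueError("expression and survival lengths differ")
    if event.sum() == 0:
        raise ValueError("no events in cohort")
    cuts = candidate_cutoffs(values)
    if len(cuts) == 0:
        return None
    p, admissible = _scan(values, time, event, cuts, statistic, min_group_frac)
    p = p[0] if p.ndim > 1 else p
    if not admissible.any():
        return None
    pmin = np.nanmin(p)
    ties = np.flatnonzero(p == pmin)
    med = np.median(values)
    best = ties[np.argmin(np.abs(cuts[ties] - med))]
    cutoff = float(cuts[best])

    high_expr = values > cutoff
    # risk from mean survival time: lower mean time = higher risk (code 2)
    mean_high = float(np.mean(time[high_expr]))
    mean_low = float(np.mean(time[~high_expr]))
    if mean_high < mean_low:
        groups = np.where(high_expr, 2, 1)
        pattern = PRO_ONCOGENIC
        mean_survival = {2: mean_high, 1: mean_low}
    else:
        groups = np.where(high_expr, 1, 2)
        pattern = SUPPRESSOR_LIKE
        mean_survival = {1: mean_high, 2: mean_low}

    from .survival import fit_cox_binary

    fit = fit_cox_binary(time, event, groups)
    beta = fit.beta  # group 2 (high risk) vs 1: positive when labels consistent
    scan = CutoffScan(gene_id=gene_id, cutoffs=cuts, p_values=p, statistic=statistic)
    return DDg1DResult(
        gene_id=gene_id, cutoff=cutoff, p_value=float(pmin), beta=float(beta),
        statistic=statistic, pattern=pattern, groups=groups,
        mean_survival=mean_survival, scan=scan,
    )


def classify_pattern(groups, values) -> str:
    """Prognostic direction of a fitted grouping: pro-oncogenic when the
    high-risk group (code 2) has the higher mean expression, suppressor-like
    otherwise."""
    groups = np.asarray(groups)
    values = np.asarray(values, dtype=float)
    m_high = values[groups == 2].mean()
    m_low = values[groups == 1].mean()
    return PRO_ONCOGENIC if m_high > m_low else SUPPRESSOR_LIKE


@dataclass(frozen=True)
class PrognosticGeneSet:
    """Genes admitted by the cross-cohort reproducibility filter."""

    genes: list
    strict: list
    relaxed: list
    p_table: pd.DataFrame


def select_prognostic_genes(cohort_results, strict_p=0.05, relaxed_p=0.15,
                            max_relaxed=2) -> PrognosticGeneSet:
    """Select genes reproducibly prognostic across cohorts.

    ``cohort_results`` maps cohort name -> {gene_id -> DDg1DResult (or P)}.
    A gene is admitted strictly when P <= ``strict_p`` in every cohort.
    Additionally, up to ``max_relaxed`` genes are admitted when P <=
    ``strict_p`` in all cohorts but one and <= ``relaxed_p`` in that one;
    relaxed admissions are ranked by their worst-cohort P.
    """
    if len(cohort_results) < 2:
        raise ValueError("cross-cohort selection needs at least 2 cohorts")

    def pval(x):
        return x.p_value if isinstance(x, DDg1DResult) else float(x)

    cohorts = list(cohort_results)
    genes = sorted(
        set.intersection(*(set(cohort_results[c]) for c in cohorts))
    )
    table = pd.DataFrame(
        {c: [pval(cohort_results[c][g]) for g in genes] for c in cohorts},
        index=genes,
    )
    strict, relaxed_cand = [], []
    for g in genes:
        ps = table.loc[g]
        if (ps <= strict_p).all():
            strict.append(g)
        else:
            n_fail = int((ps > strict_p).sum())
            if n_fail == 1 and float(ps.max()) <= relaxed_p:
                relaxed_cand.append((float(ps.max()), g))
    relaxed = [g for _, g in sorted(relaxed_cand)[:max_relaxed]]
    return PrognosticGeneSet(
        genes=strict + relaxed, strict=strict, relaxed=relaxed, p_table=table
    )


class DDgUnivariate:
    """Per-gene cutoff discretiser with a scikit-learn estimator surface.

    ``fit(X, y)`` expects ``X`` of shape (n_samples, n_genes) — a DataFrame
    or array with patients as rows — and ``y`` a ``(time, event)`` pair,
    a structured array with ``time``/``event`` fields, or a DataFrame with
    those columns. ``transform(X)`` returns per-gene risk codes
    (1 = low risk, 2 = high risk) using the fitted cutoffs and directions.

    Fitted attributes: ``cutoffs_``, ``pvalues_``, ``betas_``,
    ``patterns_``, ``results_`` (None for non-informative genes),
    ``feature_names_in_``.
    """

    def __init__(self, statistic="wald", min_group_frac=MIN_GROUP_FRAC):
        self.statistic = statistic
        self.min_group_frac = min_group_frac

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep=True):
        return {"statistic": self.statistic, "min_group_frac": self.min_group_frac}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X, names = _as_matrix(X)
        time, event = as_survival(y)
        self.feature_names_in_ = names
        self.results_ = []
        for j, name in enumerate(names):
            self.results_.append(
                fit_ddg1d(
                    X[:, j], time, event, statistic=self.statistic,
                    gene_id=name, min_group_frac=self.min_group_frac,
                )
            )
        self.cutoffs_ = np.array(
            [r.cutoff if r else np.nan for r in self.results_]
        )
        self.pvalues_ = np.array(
            [r.p_value if r else np.nan for r in self.results_]
        )
        self.betas_ = np.array([r.beta if r else np.nan for r in self.results_])
        self.patterns_ = [r.pattern if r else None for r in self.results_]
        return self

    def transform(self, X):
        if not hasattr(self, "results_"):
            raise RuntimeError("DDgUnivariate is not fitted")
        X, names = _as_matrix(X)
        if list(names) != list(self.feature_names_in_) and len(names) != len(
            self.feature_names_in_
        ):
            raise ValueError("feature mismatch with fitted data")
        codes = np.ones(X.shape, dtype=int)
        for j, r in enumerate(self.results_):
            if r is None:
                continue
            high_expr = X[:, j] > r.cutoff
            if r.pattern == PRO_ONCOGENIC:
                codes[:, j] = np.where(high_expr, 2, 1)
            else:
                codes[:, j] = np.where(high_expr, 1, 2)
        return codes

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def as_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce survival labels to ``(time, event)`` arrays.

    Accepts a ``(time, event)`` tuple, a DataFrame with ``time``/``event``
    columns, or a structured array with those fields.
    """
    if isinstance(y, pd.DataFrame):
        return check_survival(y["time"].to_numpy(), y["event"].to_numpy())
    if isinstance(y, np.ndarray) and y.dtype.names:
        return check_survival(y["time"], y["event"])
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return check_survival(y[0], y[1])
    raise TypeError("y must be (time, event), a time/event DataFrame, or a structured array")


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]
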