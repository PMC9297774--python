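"""Statistically weighted voting grouping (SWVg).

Each selected gene casts a per-patient binary risk vote (its 1D-DDg
grouping); votes are weighted by the gene's evidence strength
``w_j = -log P_j / sum_m -log P_m`` and summed into a score in [0, 1].
After recoding (high-risk vote 2 -> 0, low-risk vote 1 -> 1) a score near 0
means unanimously high risk and a score near 1 unanimously low risk, so a
patient whose score exceeds the voting cutoff lands in the LOW-risk group.
One cutoff yields a 2-group stratification, two cutoffs a
low/intermediate/high 3-group stratification.  The number of genes in the
signature is optimised stepwise from the most significant gene down.

Weights are invariant to the logarithm base (a ratio of logs); base 10 is
used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddg1d import DDgUnivariate, as_survival
from .simulate import PRO_ONCOGENIC
from .survival import P_FLOOR, check_survival, logrank_test

TWO_GROUP_GRID = np.round(np.arange(0.20, 0.80 + 1e-9, 0.01), 2)
THREE_GROUP_GRID_LO = np.round(np.arange(0.20, 0.44 + 1e-9, 0.01), 2)
THREE_GROUP_GRID_HI = np.round(np.arange(0.56, 0.80 + 1e-9, 0.01), 2)
MIN_GROUP_FRAC = 0.10


def compute_weights(p_values) -> np.ndarray:
    """Relative voting weights w_j = (-log P_j) / sum_m (-log P_m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p >= 1.0) or np.any(p <= 0.0):
        raise ValueError("P-values must lie strictly inside (0, 1)")
    logs = -np.log10(np.maximum(p, P_FLOOR))
    return logs / logs.sum()


def voting_score(votes, weights) -> np.ndarray:
    """Per-patient weighted voting score in [0, 1].

    ``votes`` is (n_patients, n_genes) with codes 1 (low risk) / 2 (high
    risk); high-risk votes are recoded 2 -> 0 so the score is the weighted
    fraction of low-risk votes: 1 = unanimously low risk, 0 = unanimously
    high risk.
    """
    votes = np.asarray(votes)
    weights = np.asarray(weights, dtype=float)
    if votes.ndim != 2 or votes.shape[1] != len(weights):
        raise ValueError("votes must be (n_patients, n_genes) matching weights")
    if not np.all(np.isin(votes, [1, 2])):
        raise ValueError("votes must be coded 1 (low risk) or 2 (high risk)")
    recoded = np.where(votes == 2, 0.0, 1.0)
    # clip away float jitter so unanimous votes land exactly on 0/1
    return np.clip(recoded @ weights, 0.0, 1.0)


def _admissible_sizes(labels, n, min_frac):
    counts = np.bincount(labels)
    sizes = counts[counts > 0]
    return len(sizes) == labels.max() and sizes.min() >= np.ceil(min_frac * n)


def optimize_two_group(scores, time, event, min_group_frac=MIN_GROUP_FRAC):
    """Grid-search the voting cutoff G_c in [0.20, 0.80] (step 0.01).

    Patients with score > G_c form the low-risk group (1), the rest the
    high-risk group (2). Objective: log-rank P of the split; cutoffs leaving
    a group below ``min_group_frac`` of patients are inadmissible. Ties in
    the objective break toward the cutoff nearest 0.5 (then the lower one).
    Returns ``(g_c, labels, p)``.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = check_survival(time, event)
    n = len(scores)
    best = None
    for gc in TWO_GROUP_GRID:
        labels = np.where(scores > gc, 1, 2)
        n_low = int((labels == 1).sum())
        if min(n_low, n - n_low) < np.ceil(min_group_frac * n):
            continue
        _, p = logrank_test(time, event, labels)
        key = (p, abs(gc - 0.5), gc)
        if best is None or key < best[0]:
            best = (key, gc, labels, p)
    if best is None:
        raise ValueError(
            "no voting cutoff in [0.2, 0.8] leaves both groups with at least "
            f"{min_group_frac:.0%} of patients"
        )
    _, gc, labels, p = best
    return float(gc), labels, float(p)


def optimize_three_group(scores, time, event, min_group_frac=MIN_GROUP_FRAC):
    """Grid-search (G_c1, G_c2) over [0.20, 0.44] x [0.56, 0.80] (step 0.01).

    Labels: score > G_c2 -> 1 (low risk); G_c1 < score <= G_c2 -> 2
    (intermediate); score <= G_c1 -> 3 (high risk). Objective: sum of the
    three pairwise log-rank P-values. Ties break toward the widest
    intermediate band, then the pair nearest symmetric about 0.5.
    Returns ``(g_c1, g_c2, labels, objective)``.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = check_survival(time, event)
    n = len(scores)
    min_size = np.ceil(min_group_frac * n)
    best = None
    for gc1 in THREE_GROUP_GRID_LO:
        for gc2 in THREE_GROUP_GRID_HI:
            labels = np.where(scores > gc2, 1, np.where(scores > gc1, 2, 3))
            counts = [(labels == g).sum() for g in (1, 2, 3)]
            if min(counts) < min_size:
                continue
            obj = 0.0
            for a, b in ((1, 2), (2, 3), (1, 3)):
                m = np.isin(labels, (a, b))
                _, p = logrank_test(time[m], event[m], labels[m])
                obj += p
            key = (obj, -(gc2 - gc1), abs((gc1 + gc2) / 2 - 0.5))
            if best is None or key < best[0]:
                best = (key, gc1, gc2, labels, obj)
    if best is None:
        raise ValueError(
            "no (G_c1, G_c2) pair leaves all three groups with at least "
            f"{min_group_frac:.0%} of patients"
        )
    _, gc1, gc2, labels, obj = best
    return float(gc1), float(gc2), labels, float(obj)


@dataclass(frozen=True)
class SignatureModel:
    """A fitted multigene voting signature.

    ``genes`` are ordered by ascending 1D-DDg P-value; only the first
    ``n_opt`` participate, with ``weights`` renormalised over them.
    ``cutoffs``/``patterns`` reproduce each gene's vote on new data;
    ``g_c`` (2-group) or ``(g_c1, g_c2)`` (3-group) threshold the score.
    """

    genes: tuple
    p_values: tuple
    cutoffs: tuple
    patterns: tuple
    weights: tuple
    mode: str
    n_opt: int
    g_c: float | None
    g_c1: float | None
    g_c2: float | None
    objective: float
    trace: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode, "n_opt": self.n_opt,
            "objective": self.objective, "g_c": self.g_c,
            "g_c1": self.g_c1, "g_c2": self.g_c2,
        }
        for i, g in enumerate(self.genes):
            d[f"gene.{g}"] = {
                "p_value": self.p_values[i], "cutoff": self.cutoffs[i],
                "pattern": self.patterns[i], "weight": self.weights[i],
            }
        return d


@dataclass(frozen=True)
class RiskStratification:
    """Per-patient voting scores and risk labels (1=low .. 2 or 3=high)."""

    scores: np.ndarray
    labels: np.ndarray

    @property
    def group_sizes(self) -> dict:
        return {int(g): int((self.labels == g).sum()) for g in np.unique(self.labels)}


def _votes_from_model(genes, cutoffs, patterns, X: pd.DataFrame) -> np.ndarray:
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise ValueError(f"cohort is missing signature genes: {missing}")
    votes = np.ones((len(X), len(genes)), dtype=int)
    for j, g in enumerate(genes):
        high_expr = X[g].to_numpy(dtype=float) > cutoffs[j]
        if patterns[j] == PRO_ONCOGENIC:
            votes[:, j] = np.where(high_expr, 2, 1)
        else:
            votes[:, j] = np.where(high_expr, 1, 2)
    return votes


def build_signature(ddg_results, time, event, mode="3group", n_min=3,
                    min_group_frac=MIN_GROUP_FRAC) -> SignatureModel:
    """Stepwise gene-count optimisation of the voting signature.

    ``ddg_results`` is a list of :class:`survddg.ddg1d.DDg1DResult` (one per
    candidate gene; ``None`` entries are dropped).  Genes are ranked by
    ascending P; for every N from ``n_min`` to the number of genes the top-N
    weights, scores and optimal voting cutoff(s) are computed, and the N
    minimising the objective (log-rank P for 2 groups, pairwise-P sum for 3)
    is returned with the full trace.
    """
    results = [r for r in ddg_results if r is not None]
    if mode not in ("2group", "3group"):
        raise ValueError("mode must be '2group' or '3group'")
    if len(results) < n_min:
        raise ValueError(f"need at least {n_min} informative genes, got {len(results)}")
    time, event = check_survival(time, event)
    results = sorted(results, key=lambda r: r.p_value)
    genes = [r.gene_id for r in results]
    pvals = np.array([r.p_value for r in results])
    votes_all = np.stack([np.where(r.groups == 2, 2, 1) for r in results], axis=1)

    trace_rows = []
    best = None
    for N in range(n_min, len(results) + 1):
        w = compute_weights(pvals[:N])
        scores = voting_score(votes_all[:, :N], w)
        try:
            if mode == "2group":
                gc, labels, obj = optimize_two_group(
                    scores, time, event, min_group_frac=min_group_frac)
                cuts = (gc, None, None)
            else:
                gc1, gc2, labels, obj = optimize_three_group(
                    scores, time, event, min_group_frac=min_group_frac)
                cuts = (None, gc1, gc2)
        except ValueError:
            trace_rows.append({"n_genes": N, "objective": np.nan})
            continue
        trace_rows.append({"n_genes": N, "objective": obj})
        if best is None or obj < best[0]:
            best = (obj, N, w, cuts)
    if best is None:
        raise ValueError("no gene count admitted a valid stratification")
    obj, n_opt, w, (gc, gc1, gc2) = best
    return SignatureModel(
        genes=tuple(genes[:n_opt]), p_values=tuple(pvals[:n_opt]),
        cutoffs=tuple(r.cutoff for r in results[:n_opt]),
        patterns=tuple(r.pattern for r in results[:n_opt]),
        weights=tuple(w), mode=mode, n_opt=n_opt,
        g_c=gc, g_c1=gc1, g_c2=gc2, objective=float(obj),
        trace=pd.DataFrame(trace_rows),
    )


def apply_signature(model: SignatureModel, X: pd.DataFrame) -> RiskStratification:
    """Stratify a new cohort with a fitted signature (no re-optimisation).

    ``X`` is patients x genes and must contain every signature gene.
    """
    votes = _votes_from_model(model.genes, model.cutoffs, model.patterns, X)
    scores = voting_score(votes, np.asarray(model.weights))
    if model.mode == "2group":
        labels = np.where(scores > model.g_c, 1, 2)
    else:
        labels = np.where(scores > model.g_c2, 1,
                          np.where(scores > model.g_c1, 2, 3))
    return RiskStratification(scores=scores, labels=labels)


class SWVgClassifier:
    """Weighted-voting risk classifier with a scikit-learn estimator surface.

    ``fit(X, y)`` runs per-gene 1D-DDg on the columns of ``X`` (patients x
    genes DataFrame), then the stepwise signature search; ``predict(X)``
    returns risk labels (1 = low, ... 2 or 3 = high) and
    ``predict_score(X)`` the underlying voting scores.  The fitted signature
    is exposed as ``model_``.
    """

    def __init__(self, mode="3group", statistic="wald", n_min=3,
                 min_group_frac=MIN_GROUP_FRAC):
        self.mode = mode
        self.statistic = statistic
        self.n_min = n_min
        self.min_group_frac = min_group_frac

    def get_params(self, deep=True):
        return {
            "mode": self.mode, "statistic": self.statistic,
            "n_min": self.n_min, "min_group_frac": self.min_group_frac,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in X.columns]
        time, event = as_survival(y)
        ddg = DDgUnivariate(statistic=self.statistic,
                            min_group_frac=self.min_group_frac).fit(X, (time, event))
        self.ddg_ = ddg
        self.model_ = build_signature(
            ddg.results_, time, event, mode=self.mode, n_min=self.n_min,
            min_group_frac=self.min_group_frac,
        )
        self.classes_ = np.array([1, 2] if self.mode == "2group" else [1, 2, 3])
        return self

    def predict_score(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("SWVgClassifier is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in X.columns]
        return apply_signature(self.model_, X).scores

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("SWVgClassifier is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in X.columns]
        return apply_signature(self.model_, X).labels
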