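"""Synthetic cohorts, growth curves and foci-size samples with known truth.

The generator emulates the statistical structure the stratification methods
assume: per-gene standard-normal log-expression marginals, a Gaussian copula
inducing requested rank correlations between gene pairs, and exponential
(constant-baseline-hazard) survival in which crossing a gene-specific
expression cutoff multiplies the hazard by ``exp(log_hr)``.  Censoring is an
independent exponential time whose rate is solved numerically so the marginal
censored fraction matches the request.  Every generator is deterministic
under a fixed seed and returns the ground truth alongside the data, so
recovery tests never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

PRO_ONCOGENIC = "pro-oncogenic"
SUPPRESSOR_LIKE = "suppressor-like"


@dataclass(frozen=True)
class InformativeGene:
    """A gene carrying a threshold-type proportional-hazards effect.

    ``cutoff_quantile`` places the true cutoff on the gene's expression
    distribution; patients on the high-risk side have their hazard multiplied
    by ``exp(log_hr)``. ``direction`` says which side is high-risk:
    pro-oncogenic = above the cutoff, suppressor-like = below.
    """

    gene: int
    cutoff_quantile: float
    log_hr: float
    direction: str = PRO_ONCOGENIC

    def __post_init__(self):
        if not 0.0 < self.cutoff_quantile < 1.0:
            raise ValueError("cutoff_quantile must lie strictly inside (0, 1)")
        if not np.isfinite(self.log_hr) or self.log_hr == 0:
            raise ValueError("log_hr must be finite and nonzero")
        if self.direction not in (PRO_ONCOGENIC, SUPPRESSOR_LIKE):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated expression + survival cohort."""

    n_patients: int
    n_genes: int
    informative_genes: tuple = ()
    baseline_hazard_rate: float = 0.1
    censoring_rate: float = 0.3
    correlated_pairs: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("n_patients and n_genes must be positive")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        genes = [g.gene for g in self.informative_genes]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate informative gene indices")
        if any(g < 0 or g >= self.n_genes for g in genes):
            raise ValueError("informative gene index out of range")
        for a, b, rho in self.correlated_pairs:
            if not (0 <= a < self.n_genes and 0 <= b < self.n_genes and a != b):
                raise ValueError("correlated pair indices invalid")
            if not abs(rho) < 1.0:
                raise ValueError("|target rank correlation| must be < 1")


def _copula_correlation(spec: CohortSpec) -> np.ndarray:
    """Pearson correlation matrix of the Gaussian copula.

    The Pearson parameter r reproducing a target Spearman rho under a
    bivariate normal is r = 2 sin(pi * rho / 6).
    """
    R = np.eye(spec.n_genes)
    for a, b, rho in spec.correlated_pairs:
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        R[a, b] = R[b, a] = r
    # guard against an indefinite matrix from many overlapping pairs
    w = np.linalg.eigvalsh(R)
    if w.min() < 1e-8:
        R += np.eye(spec.n_genes) * (1e-8 - w.min())
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def simulate_cohort(spec: CohortSpec):
    """Draw an expression matrix and survival cohort with known ground truth.

    Returns ``(expression, clinical, truth)``:

    * ``expression`` — DataFrame, genes (rows ``g000``...) x patients
      (columns ``p0000``...), standard-normal marginals;
    * ``clinical`` — DataFrame with ``patient_id, time, event``;
    * ``truth`` — DataFrame per informative gene: true cutoff value and
      quantile, log hazard ratio, direction.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_genes
    R = _copula_correlation(spec)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((p, n))
    Y = L @ Z  # genes x patients, correlated standard normals

    gene_ids = [f"g{i:03d}" for i in range(p)]
    patient_ids = [f"p{k:04d}" for k in range(n)]
    expression = pd.DataFrame(Y, index=gene_ids, columns=patient_ids)

    # hazards: threshold effects multiply the baseline rate
    log_hazard = np.full(n, np.log(spec.baseline_hazard_rate))
    truth_rows = []
    for g in spec.informative_genes:
        values = Y[g.gene]
        cut = float(np.quantile(values, g.cutoff_quantile))
        if g.direction == PRO_ONCOGENIC:
            high = values > cut
        else:
            high = values < cut
        log_hazard = log_hazard + np.where(high, g.log_hr, 0.0)
        truth_rows.append(
            {
                "gene_id": gene_ids[g.gene],
                "gene_index": g.gene,
                "cutoff_value": cut,
                "cutoff_quantile": g.cutoff_quantile,
                "log_hr": g.log_hr,
                "direction": g.direction,
            }
        )
    hazard = np.exp(log_hazard)
    t_event = rng.exponential(1.0 / hazard)

    if spec.censoring_rate > 0:
        # censoring rate c solving mean_k h_k/(h_k + c) = 1 - censoring_rate
        target = 1.0 - spec.censoring_rate

        def event_fraction(c):
            return float(np.mean(hazard / (hazard + c))) - target

        hi = float(hazard.max()) * (1.0 / target)
        while event_fraction(hi) > 0:
            hi *= 10.0
        c_rate = brentq(event_fraction, 1e-12, hi)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame(
        {"patient_id": patient_ids, "time": time, "event": event}
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "gene_index", "cutoff_value",
            "cutoff_quantile", "log_hr", "direction",
        ],
    )
    return expression, clinical, truth


def simulate_growth(a, b, sigma, timepoints, seed=0) -> pd.DataFrame:
    """Exponential tumor-volume series v(t) = (a - b) exp(a t) with
    multiplicative log-normal noise of log-SD ``sigma``.

    ``sigma = 0`` reproduces the curve exactly. Slow-growth patterns
    (``a <= 0``) are allowed; non-finite parameters are not.
    """
    for name, val in (("a", a), ("b", b), ("sigma", sigma)):
        if not np.isfinite(val):
            raise ValueError(f"parameter {name} must be finite")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("timepoints must be a nonempty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be nonnegative and increasing")
    mean = (a - b) * np.exp(a * t)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(0.0, sigma, size=len(t)))
    else:
        noise = 1.0
    return pd.DataFrame({"time": t, "volume": mean * noise})


def simulate_foci(n_foci, x0, b, background_fraction=0.0, max_size=120_000.0,
                  seed=0) -> np.ndarray:
    """Sample metastatic focus areas from a log-normal core plus a uniform
    background floor.

    ``(1 - background_fraction) * n`` areas are log-normal with log-SD ``b``
    and *modal* size ``x0`` — the density (hence the size-frequency
    histogram) peaks at ``x0``, which is the quantity the shifted log-normal
    frequency fit estimates.  The remainder are uniform on ``(0, max_size]``
    and stand in for the constant baseline of that model.  All areas are
    positive.
    """
    if n_foci < 1:
        raise ValueError("n_foci must be positive")
    if x0 <= 0 or b <= 0:
        raise ValueError("x0 and b must be positive")
    if not 0.0 <= background_fraction < 1.0:
        raise ValueError("background_fraction must lie in [0, 1)")
    if max_size <= 0:
        raise ValueError("max_size must be positive")
    rng = np.random.default_rng(seed)
    n_bg = int(round(background_fraction * n_foci))
    n_core = n_foci - n_bg
    # log-normal with mode x0: mu = ln(x0) + b^2 puts the density peak at x0
    core = x0 * np.exp(b * b + b * rng.standard_normal(n_core))
    bg = max_size * rng.uniform(size=n_bg)
    bg = np.maximum(bg, np.finfo(float).tiny)
    return np.concatenate([core, bg])
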