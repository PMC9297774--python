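"""End-to-end pipeline: per-gene cutoff screen -> cross-cohort selection ->
weighted-voting signature on the training cohort -> stratification of every
cohort -> Kaplan–Meier tables and event-enrichment of the extreme risk
groups.  All intermediates are written as TSV; the run is deterministic
given the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .ddg1d import DDgUnivariate, select_prognostic_genes
from .enrichment import enrichment_test
from .survival import km_estimate
from .swvg import apply_signature, build_signature

log = logging.getLogger("survddg")


@dataclass
class PipelineConfig:
    """Paths and thresholds driving a pipeline run.

    ``cohorts`` maps cohort name -> {"expression": path, "clinical": path};
    the first cohort is the training cohort for the signature.
    """

    cohorts: dict
    out_dir: str
    statistic: str = "wald"
    strict_p: float = 0.05
    relaxed_p: float = 0.15
    max_relaxed: int = 2
    mode: str = "3group"
    n_min: int = 3
    min_group_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name, thr in (("strict_p", self.strict_p),
                          ("relaxed_p", self.relaxed_p)):
            if not 0.0 < thr < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full stratification pipeline; returns the results bundle and
    writes every stage's table under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohorts = {}
    for name, paths in config.cohorts.items():
        expr = sio.read_expression(paths["expression"])
        clin = sio.read_clinical(paths["clinical"])
        X, time, event = sio.align_cohort(expr, clin)
        cohorts[name] = {"X": X, "time": time, "event": event, "clinical": clin}
        log.info("cohort %s: %d patients, %d genes, %d events",
                 name, len(X), X.shape[1], int(event.sum()))

    # per-gene 1D screen per cohort
    screens = {}
    for name, c in cohorts.items():
        ddg = DDgUnivariate(statistic=config.statistic,
                            min_group_frac=config.min_group_frac)
        ddg.fit(c["X"], (c["time"], c["event"]))
        screens[name] = ddg
        rows = []
        for r in ddg.results_:
            if r is None:
                continue
            rows.append({
                "gene_id": r.gene_id, "cutoff": r.cutoff, "p_value": r.p_value,
                "beta": r.beta, "pattern": r.pattern,
                "n_low_risk": r.group_sizes[1], "n_high_risk": r.group_sizes[2],
            })
        pd.DataFrame(rows).to_csv(out / f"ddg1d_{name}.tsv", sep="\t", index=False)

    # cross-cohort selection (single-cohort runs keep strict-P genes)
    if len(cohorts) >= 2:
        per_cohort = {
            name: {r.gene_id: r for r in screens[name].results_ if r is not None}
            for name in cohorts
        }
        geneset = select_prognostic_genes(
            per_cohort, strict_p=config.strict_p,
            relaxed_p=config.relaxed_p, max_relaxed=config.max_relaxed,
        )
        selected = geneset.genes
        geneset.p_table.to_csv(out / "selection_p_table.tsv", sep="\t",
                               index_label="gene_id")
    else:
        name = next(iter(cohorts))
        selected = [r.gene_id for r in screens[name].results_
                    if r is not None and r.p_value <= config.strict_p]
    log.info("selected %d prognostic genes: %s", len(selected), selected)
    (out / "selected_genes.txt").write_text("\n".join(selected) + "\n")

    # signature on the training cohort
    train_name = next(iter(cohorts))
    train = cohorts[train_name]
    train_results = [r for r in screens[train_name].results_
                     if r is not None and r.gene_id in selected]
    model = build_signature(
        train_results, train["time"], train["event"], mode=config.mode,
        n_min=config.n_min, min_group_frac=config.min_group_frac,
    )
    sio.write_signature_model(model, out / "signature_model.tsv")
    model.trace.to_csv(out / "signature_trace.tsv", sep="\t", index=False)

    # stratify every cohort, KM tables, enrichment of extreme groups
    stratifications = {}
    enrich_rows = []
    for name, c in cohorts.items():
        strat = apply_signature(model, c["X"])
        stratifications[name] = strat
        tidy = c["clinical"].copy()
        tidy["score"] = strat.scores
        tidy["risk_group"] = strat.labels
        tidy.to_csv(out / f"stratification_{name}.tsv", sep="\t", index=False)
        curves = km_estimate(c["time"], c["event"], strat.labels)
        sio.write_km_curves(curves, out / f"km_{name}.tsv")
        hi = strat.labels == strat.labels.max()
        lo = strat.labels == 1
        enr = enrichment_test(
            int(c["event"][hi].sum()), int(hi.sum()),
            int(c["event"][lo].sum()), int(lo.sum()),
        )
        enrich_rows.append({
            "cohort": name, "events_high": enr.events_high, "n_high": enr.n_high,
            "events_low": enr.events_low, "n_low": enr.n_low,
            "fold_change": enr.fold_change, "p_value": enr.p_value,
        })
    pd.DataFrame(enrich_rows).to_csv(out / "event_enrichment.tsv", sep="\t",
                                     index=False)

    return {
        "screens": screens, "selected_genes": selected, "model": model,
        "stratifications": stratifications,
        "enrichment": pd.DataFrame(enrich_rows),
    }
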