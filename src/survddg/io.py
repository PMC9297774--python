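"""Tab-separated readers and writers for expression and clinical tables.

TSV is used everywhere (gene identifiers are never comma-safe), UTF-8, no
quoting dialects.  Expression tables are genes x patients with the gene id
in the first column; clinical tables are one patient per row with
``patient_id, time, event`` (and an optional ``event_type`` label such as
DFS / DMFS / OS, carried as metadata only).  Values are left untransformed:
whether the matrix is log-scale is the caller's decision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_expression(path) -> pd.DataFrame:
    """Read a genes x patients expression TSV (first column = gene id).

    Duplicate gene ids and non-numeric cells are rejected with the
    offending coordinates named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient ids in {path}: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ValueError(
            f"non-numeric expression value at gene {gene!r}, patient {col!r}: "
            f"{df.loc[gene, col]!r}"
        )
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        raise ValueError(f"missing expression value in gene {gene!r}")
    return numeric.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with columns ``patient_id, time, event``
    (optional ``event_type``)."""
    df = pd.read_csv(path, sep="\t")
    required = ["patient_id", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids in {path}: {dup}")
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any() or (time < 0).any():
        bad = df.loc[time.isna() | (time < 0), "patient_id"].tolist()
        raise ValueError(f"invalid (negative/non-numeric) times for patients {bad}")
    event = pd.to_numeric(df["event"], errors="coerce")
    if not event.isin([0, 1]).all():
        bad = df.loc[~event.isin([0, 1]), "patient_id"].tolist()
        raise ValueError(f"event indicator must be 0/1; offending patients {bad}")
    out = df.copy()
    out["time"] = time.astype(float)
    out["event"] = event.astype(int)
    return out


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def align_cohort(expression: pd.DataFrame, clinical: pd.DataFrame):
    """Align an expression matrix (genes x patients) with a clinical table.

    The two patient-id sets must be identical; columns are reordered to the
    clinical order.  Returns ``(X, time, event)`` with ``X`` patients x
    genes.
    """
    expr_ids = set(expression.columns)
    clin_ids = set(clinical["patient_id"])
    if expr_ids != clin_ids:
        only_e = sorted(expr_ids - clin_ids)[:5]
        only_c = sorted(clin_ids - expr_ids)[:5]
        raise ValueError(
            "expression and clinical patient ids differ "
            f"(expression-only: {only_e}, clinical-only: {only_c})"
        )
    X = expression[clinical["patient_id"].tolist()].T
    return X, clinical["time"].to_numpy(), clinical["event"].to_numpy()


def write_km_curves(curves: dict, path) -> None:
    """Write per-group Kaplan–Meier curves as a tidy TSV
    (group, time, at_risk, events, survival)."""
    frames = []
    for g, df in curves.items():
        d = df.copy()
        d.insert(0, "group", g)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_signature_model(model, path) -> None:
    """Serialise a SignatureModel to a plain-text key-value file."""
    def num(x):
        return "" if x is None else repr(float(x))

    lines = [
        f"mode\t{model.mode}",
        f"n_opt\t{model.n_opt}",
        f"objective\t{num(model.objective)}",
        f"g_c\t{num(model.g_c)}",
        f"g_c1\t{num(model.g_c1)}",
        f"g_c2\t{num(model.g_c2)}",
    ]
    for i, g in enumerate(model.genes):
        lines.append(
            "gene\t" + "\t".join([
                g, num(model.p_values[i]), num(model.cutoffs[i]),
                model.patterns[i], num(model.weights[i]),
            ])
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_signature_model(path):
    """Read a signature serialised by :func:`write_signature_model`."""
    from .swvg import SignatureModel

    meta = {}
    genes, pvals, cuts, pats, weights = [], [], [], [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "gene":
                _, g, p, c, pat, w = parts
                genes.append(g)
                pvals.append(float(p))
                cuts.append(float(c))
                pats.append(pat)
                weights.append(float(w))
            else:
                meta[parts[0]] = parts[1] if len(parts) > 1 else ""
    import pandas as pd

    def opt(key):
        return float(meta[key]) if meta.get(key) else None

    return SignatureModel(
        genes=tuple(genes), p_values=tuple(pvals), cutoffs=tuple(cuts),
        patterns=tuple(pats), weights=tuple(weights), mode=meta["mode"],
        n_opt=int(meta["n_opt"]), g_c=opt("g_c"), g_c1=opt("g_c1"),
        g_c2=opt("g_c2"), objective=float(meta["objective"]),
        trace=pd.DataFrame(),
    )
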