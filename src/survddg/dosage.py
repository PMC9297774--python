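"""Gene-dosage fold-change table from raw genotype expression counts.

Input: per-gene RNA-seq raw counts for four genotype columns of the
conditional-knockout mouse experiment — heterozygous (fl/wt) and homozygous
(fl/fl) animals, each with (Cre-) control and (Cre+) knockout.  Derived per
gene:

* fold-change depletion within each zygosity, control / knockout;
* the homozygous / heterozygous ratio of those fold changes, computed from
  the UNROUNDED values (rounding first changes the printed ratios);
* a treatment-effect flag: "Yes" when BOTH zygosities changed more than
  1.5-fold in either direction (fc > 1.5 or fc < 1/1.5, strict).

Reported values are rounded half-up to two decimals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

REQUIRED_COLUMNS = ("gene", "het_control", "het_ko", "homo_control", "homo_ko")
DEFAULT_THRESHOLD = 1.5


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (banker's rounding avoided)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fold_change_depletion(control_count, ko_count) -> float:
    """Within-zygosity depletion: control / knockout counts."""
    if ko_count <= 0:
        raise ValueError("knockout count must be positive for a fold change")
    if control_count < 0:
        raise ValueError("counts must be nonnegative")
    return control_count / ko_count


def dosage_ratio(homo_fc: float, het_fc: float) -> float:
    """Homozygous / heterozygous fold-change ratio, from unrounded inputs."""
    if het_fc == 0:
        raise ValueError("heterozygous fold change must be nonzero")
    return homo_fc / het_fc


def treatment_effect_flag(het_fc, homo_fc, threshold=DEFAULT_THRESHOLD) -> str:
    """"Yes" iff both fold changes moved more than ``threshold``-fold in
    either direction (strict inequalities)."""

    def changed(fc):
        return fc > threshold or fc < 1.0 / threshold

    return "Yes" if changed(het_fc) and changed(homo_fc) else "No"


def build_dosage_table(counts: pd.DataFrame,
                       threshold=DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Apply the three dosage computations to every gene.

    ``counts`` needs columns ``gene, het_control, het_ko, homo_control,
    homo_ko``.  Returns one row per gene with 2-decimal reported values
    ``het_fc, homo_fc, ratio`` and the ``treatment_effect`` flag, plus the
    unrounded values under ``*_raw``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table is missing columns: {missing}")
    rows = []
    for rec in counts.itertuples(index=False):
        het = fold_change_depletion(rec.het_control, rec.het_ko)
        homo = fold_change_depletion(rec.homo_control, rec.homo_ko)
        ratio = dosage_ratio(homo, het)
        rows.append(
            {
                "gene": rec.gene,
                "het_fc": round_half_up(het),
                "homo_fc": round_half_up(homo),
                "ratio": round_half_up(ratio),
                "treatment_effect": treatment_effect_flag(het, homo, threshold),
                "het_fc_raw": het,
                "homo_fc_raw": homo,
                "ratio_raw": ratio,
            }
        )
    return pd.DataFrame(rows)


def load_wave_complex_counts() -> pd.DataFrame:
    """Raw RNA-seq genotype counts for the WAVE-complex gene panel of the
    conditional Abi1-knockout mouse tumors (bundled reference input)."""
    with resources.files("survddg.data").joinpath("wave_complex_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
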