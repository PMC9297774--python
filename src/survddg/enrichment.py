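"""Enrichment of (metastatic) events in predicted risk groups.

Fold change of event proportions between the high- and low-risk groups,
with an exact test of the two binomial proportions.  The conditional
(Fisher / hypergeometric) exact test is the default; an unconditional
Barnard test is available behind a flag.  One-sided toward enrichment by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    events_high: int
    n_high: int
    events_low: int
    n_low: int
    fold_change: float
    p_value: float
    alternative: str
    test: str


def enrichment_test(events_high, n_high, events_low, n_low,
                    alternative="greater", test="fisher") -> EnrichmentResult:
    """Exact test of event-proportion enrichment in the high-risk group.

    ``fold_change = (events_high/n_high) / (events_low/n_low)``; a zero
    low-risk proportion gives an infinite fold change (the P-value is still
    computed).  ``alternative`` is ``greater`` (enrichment, default),
    ``less`` or ``two-sided``; ``test`` is ``fisher`` (conditional) or
    ``barnard`` (unconditional).
    """
    for name, v in (("events_high", events_high), ("n_high", n_high),
                    ("events_low", events_low), ("n_low", n_low)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    events_high, n_high = int(events_high), int(n_high)
    events_low, n_low = int(events_low), int(n_low)
    if n_high < 1 or n_low < 1:
        raise ValueError("group sizes must be at least 1")
    if events_high > n_high or events_low > n_low:
        raise ValueError("event counts cannot exceed group sizes")

    p_high = events_high / n_high
    p_low = events_low / n_low
    fc = float("inf") if (p_low == 0 and p_high > 0) else (
        0.0 if p_high == 0 and p_low == 0 else
        (p_high / p_low if p_low > 0 else float("inf"))
    )
    if p_high == 0 and p_low == 0:
        fc = float("nan")

    table = [[events_high, n_high - events_high],
             [events_low, n_low - events_low]]
    if test == "fisher":
        _, p = stats.fisher_exact(table, alternative=alternative)
    elif test == "barnard":
        res = stats.barnard_exact(table, alternative=alternative)
        p = res.pvalue
    else:
        raise ValueError("test must be 'fisher' or 'barnard'")
    return EnrichmentResult(
        events_high=events_high, n_high=n_high,
        events_low=events_low, n_low=n_low,
        fold_change=fc, p_value=float(p),
        alternative=alternative, test=test,
    )
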