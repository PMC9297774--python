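# Methods notes

## Statistical engine

All cutoff and design searches are scored by a univariate Cox
proportional-hazards fit of a binary (or recoded binary) group covariate.
The partial likelihood uses the **Breslow** tie convention — each tied
event contributes its own factor with the full risk set — which differs
from the Efron default of general-purpose survival libraries; on tie-free
data the two coincide, which is how the engine is cross-checked against
lifelines in the test suite (tied data are checked against direct scalar
maximisation of the Breslow log-likelihood). Newton iteration runs to
|Δβ| < 1e-8 (max 50 steps). A monotone likelihood (complete separation)
does not raise: β is capped at ±20 and the fit flagged non-converged, so a
scan can step over degenerate candidates. The Wald statistic is (β̂/se)²
on χ²(1); the k-group log-rank statistic is computed on the same risk
tables and referred to χ²(k−1). P-values are floored at 1e-300 so the
−log P voting weights stay finite.

Because a single gene scan evaluates hundreds of candidate splits, the
scan path builds the per-event-time risk tables for *all* candidates at
once and runs the Newton iterations jointly (vectorised over candidates).
A regression test asserts that this path reproduces per-candidate scalar
fits exactly.

## 1D-DDg

*Candidate grid.* The grid is the set of midpoints between consecutive
distinct sorted values that fall inside the gene's [q10, q90]
linear-interpolation quantile window. Midpoints mean no observation ever
equals a cutoff, removing the boundary ambiguity of a strict `value > c`
split; if a caller supplies an exact-match cutoff anyway, `> c` goes to
one side and `≤ c` to the other. A constant gene yields an empty grid and
is reported non-informative rather than raising.

*Constraints and tie-breaks.* Candidates leaving either side below 10% of
patients are skipped (harmonised with the voting-cutoff constraint).
Ties in the minimised P break toward the cutoff closest to the median.

*Risk labels.* Assigned post hoc from group mean observed time (lower
mean ⇒ high risk, code 2), so pro-oncogenic and suppressor-like genes are
discovered symmetrically; the reported β is always high-vs-low risk and
hence nonnegative in well-posed fits.

*Multiplicity.* The minimised P is reported raw — deliberately, for
fidelity to the method being implemented — and is therefore optimistically
biased (under the null, the per-gene pass rate at 0.05 is far above 5%).
The guard is the cross-cohort reproducibility filter: requiring P ≤ 0.05
in every cohort multiplies approximately independent pass rates, which the
suite verifies empirically. Up to two genes may enter relaxed (P ≤ 0.15 in
exactly one cohort), ranked by worst-cohort P.

## 2D-DDg

The design space is every merger of the four cutoff-quadrants into two
nonempty regions: 7 designs up to label swap (a reconstruction — the
catalogue is defined here, not inherited). Cutoffs come from the 1D scans
per axis, so with one degenerate axis the search collapses exactly to the
other axis's 1D result. The rotation gate is Kendall τ at α = 1e-4
(Spearman selectable); the rotation
x̄ = (x + β̂(y−α̂))/s, ȳ = (−β̂x + (y−α̂))/s with s = √(1+β̂²) is a proper
isometry (asserted to 1e-9 in the tests), and rotated-axis cutoffs are
reported together with the line parameters so out-of-sample application is
reproducible. A rotated off-line coordinate whose spread is below 1e-10 of
the data scale is treated as degenerate (numerically constant).

## SWVg

Weights w_j = −log P_j / Σ −log P_m are base-invariant; base 10 is used
for reporting. Votes are recoded high-risk 2 → 0 before scoring, so a
score near 1 means unanimously low risk and **patients above the voting
cutoff land in the low-risk group** — the printed two-group rule and the
recoding description conflict in the source method on this orientation,
and the recoding description governs here. Scores are clipped to [0,1] to
absorb float jitter in the weight sum. Grid searches use 0.01 steps on
[0.20, 0.80] (two groups) and [0.20, 0.44] × [0.56, 0.80] (three groups);
objectives are the log-rank P and the sum of the three pairwise log-rank
P respectively, with every group ≥ 10% of patients. Deterministic
tie-breaks: cutoff nearest 0.5 (two-group); widest intermediate band, then
most symmetric pair (three-group). The stepwise search over N (from 3 up)
retains the full trace; weights are taken from the training cohort's 1D
P-values.

## Synthetic cohorts

The generator emulates exactly the structure the methods assume and no
more: standard-normal per-gene marginals (the methods are scale-free, so
the microarray intensity scale is immaterial), a Gaussian copula for
requested rank correlations (Pearson parameter r = 2·sin(πρ/6) to hit a
target Spearman ρ), exponential survival with constant baseline hazard
multiplied by exp(log-HR) on the high-risk side of each informative gene's
quantile cutoff, and independent exponential censoring whose rate is
solved (Brent) so the marginal event fraction matches 1 − censoring_rate.
The ground truth (cutoff value/quantile, log-HR, direction per gene) is
returned alongside the data. Not modelled: microarray noise, batch
effects, probe-level structure, non-proportional hazards, informative
censoring — so passing recovery tests demonstrates correctness of the
machinery under its own assumptions, not robustness to real-data
violations of them.

Default study conditions used by the tests and the acceptance script:
cutoff recovery at n = 600, one informative gene, log-HR 1.0, cutoff at
the median, 50 seeds; signature transfer at n = 400, five genes of which
three informative (log-HR 1.0 / 0.8 / −0.8, quantiles 0.5 / 0.4 / 0.6,
one suppressor-like), 30% censoring, 25 train/test pairs.

## Kinetics and foci models

*Exponential growth.* f(t; a, b) = (a − b)·exp(a·t), with (a − b) the
initial volume; an additive form f = a − b·exp(a·t) is available behind
`model="additive"` for comparison (the two appear interchangeably in this
literature; the first matches the stated parameter interpretation and is
the default). Levenberg–Marquardt with the analytic Jacobian, five
log-spaced starting rates plus a log-linear-regression start; SEs from the
Jacobian at the optimum, per-parameter t-tests on n − 2 df. The residual
sum at the returned optimum is never above that of any start (multi-start
invariant in the suite).

*Foci sizes.* Two binning rules: `round_kilo` (bin = area/1000 rounded
half-up — ties away from zero, since the original software's convention is
unknowable) and `width5000` (bin k = ((k−1)·5000, k·5000], k ≤ 20, bin 21
open above 100000 µm²). The shifted log-normal frequency curve
y0 + a·exp(−½(ln(x/x0)/b)²) is fitted to counts against bin-centre sizes
in the rule's natural units (bin index for `round_kilo`, (k−½)·5000 with
102500 for the open bin); which x-coordinate the original fits used is not
recorded, so this is fixed here as the package's convention. Bounds keep
x0, b > 0 and a ≥ 0; initialisation y0 = min count, x0 = modal bin centre,
a = count range, b ∈ {0.5, 1, 2} multi-start. A fitted amplitude
indistinguishable from zero (flat histogram) leaves x0 unidentifiable and
is flagged non-converged rather than raised. The generator draws focus
areas log-normally parameterised by the **modal** size (μ = ln x0 + b²),
because the frequency curve's x0 is the histogram peak; a uniform
background component stands in for the y0 floor.

*Distribution comparison.* Unpaired samples are compared with the
Mann–Whitney rank test by default; the paired signed-rank variant sits
behind `paired=True`. (The source context names the signed-rank test for
what are unpaired samples; the unpaired test is the defensible default and
the discrepancy is surfaced here.)

## Enrichment and dosage

"Exact test of two binomial proportions" is implemented as the conditional
Fisher exact test (one-sided toward enrichment by default, two-sided and
unconditional Barnard variants behind flags); results carry the test used.
The dosage table computes the homozygous/heterozygous ratio from
*unrounded* fold changes — rounding first demonstrably changes the
reported ratios — and flags a treatment effect only when **both**
zygosities changed more than 1.5-fold (strictly) in either direction; the
source rows cannot discriminate a conjunction from a disjunction, so the
literal "heterozygous and homozygous" wording is followed.

## Known limitations

- Minimised-P cutoffs are biased toward significance; no per-gene
  correction is applied (by design — see above). Interpret single-cohort
  scan P-values descriptively.
- The Cox engine handles a single categorical covariate only; no
  continuous covariates, time-varying effects or baseline-hazard
  estimation.
- 2D designs are axis-aligned quadrant unions; no ≥3-gene joint domains
  or nonlinear boundaries.
- The three-group grid search is exhaustive (625 pairs × 3 log-rank
  tests per N) and is the slowest step of signature building.
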