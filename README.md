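# survddg

Survival stratification for multigene prognostic signatures by
**data-driven cutoff grouping** (1D-DDg, 2D-DDg) and **statistically
weighted voting grouping** (SWVg), with companion models for tumor-growth
kinetics, metastatic-foci size distributions, risk-group event enrichment
and gene-dosage fold-change tables.

The package is aimed at biostatisticians and computational biologists who
have a gene-expression matrix (genes × patients) and per-patient survival
data (time, event indicator — DFS, DMFS or OS clocks) and want to build and
transfer a threshold-based multigene risk classifier, together with a
synthetic-cohort generator so every stage can be validated against known
ground truth.

## The methods

**1D-DDg.** For gene *i* with log-expression *y[i,k]* across patients *k*,
each candidate cutoff *c* splits the cohort into two groups
(*x[k] = 1* if *y[i,k] > c*, else 2). The split is scored by a univariate
Cox proportional-hazards fit,

    log h_k(t | x_k, β) = α(t) + β · x_k ,

via the Breslow partial likelihood, with the Wald statistic
*W = (β̂/se)²* (log-rank selectable). Candidates are the midpoints between
consecutive distinct observed values inside the gene's 10th–90th quantile
window; the cutoff minimising the P-value wins, subject to each group
holding ≥ 10% of patients. Risk labels are assigned afterwards from group
mean survival (lower mean survival ⇒ "high risk"), which classifies each
gene as *pro-oncogenic* (high expression = high risk) or
*tumor-suppressor-like*. Genes reproducible across cohorts
(P ≤ 0.05 in all cohorts, with up to two admissions at P ≤ 0.15 in one)
form the prognostic set.

**2D-DDg.** Two genes' 1D cutoffs split the expression plane into four
quadrants; all 7 two-colourings of the quadrants (up to label swap) are
scored with the same Cox machinery and the best admissible design kept.
For strongly correlated pairs (Kendall τ, P < 1e-4) the plane is first
rotated onto the pair's least-squares regression line — an isometry
(x̄ = (x + β̂(y − α̂))/√(1+β̂²), ȳ = (−β̂x + (y − α̂))/√(1+β̂²)) — and the
cutoffs re-derived on the rotated axes.

**SWVg.** Selected genes vote per patient (their 1D groupings); gene *j*'s
vote carries weight *w_j = −log P_j / Σ_m −log P_m*. After recoding
(high-risk vote 2 → 0) the per-patient score *G ∈ [0,1]* is the weighted
fraction of low-risk votes, so **high score = low risk**. A voting cutoff
*G_c* ∈ [0.20, 0.80] (step 0.01) yields two groups; a pair
*G_c1* ∈ [0.20, 0.44], *G_c2* ∈ [0.56, 0.80] yields low / intermediate /
high risk, minimising the log-rank P (or the sum of pairwise log-rank P),
with every group ≥ 10% of patients. The gene count *N* is optimised
stepwise from the most significant gene down.

**Companion models.** Exponential tumor growth
*f(t; a, b) = (a − b)·exp(a·t)*; shifted log-normal focus-size frequency
*f(x) = y0 + a·exp(−½(ln(x/x0)/b)²)* fitted to binned focus areas
(two binning rules: nearest-integer of area/1000, or 5000-µm² bins capped
at bin 21); Fisher-exact enrichment of events between risk groups; and the
gene-dosage table (control/knockout fold changes per zygosity, their
homozygous/heterozygous ratio, and a strict >1.5× both-zygosities
treatment-effect flag).

## Worked example

```python
import survddg as s

genes = (s.InformativeGene(0, 0.5, 1.0),                      # pro-oncogenic
         s.InformativeGene(1, 0.4, 0.8),
         s.InformativeGene(2, 0.6, -0.8, "suppressor-like"))
Xtr, ctr, truth = s.simulate_cohort(s.CohortSpec(400, 5, genes, seed=3))
Xte, cte, _     = s.simulate_cohort(s.CohortSpec(400, 5, genes, seed=10003))

clf = s.SWVgClassifier(mode="3group").fit(Xtr.T, ctr[["time", "event"]])
m = clf.model_
print(m.n_opt, m.genes, [round(float(w), 3) for w in m.weights], m.g_c1, m.g_c2)

labels = clf.predict(Xte.T)
stat, p = s.logrank_test(cte["time"], cte["event"], labels)
print(f"log-rank chi2 = {stat:.2f}, P = {p:.3g}")
```

prints

```
5 ('g000', 'g002', 'g001', 'g003', 'g004') [0.431, 0.241, 0.218, 0.065, 0.045] 0.2 0.75
log-rank chi2 = 104.31, P = 2.23e-23
```

i.e. the stepwise search kept all 5 genes — the three truly informative
ones carry 89% of the voting weight, the two noise genes almost none —
placed the voting cutoffs at 0.20/0.75, and the trained signature
stratifies an *independent* cohort from the same generating process with
a 3-group log-rank P ≈ 2e-23.
The bundled gene-dosage panel reproduces, e.g.

```python
t = s.build_dosage_table(s.load_wave_complex_counts()).set_index("gene")
t.loc["Abi1", ["het_fc", "homo_fc", "ratio", "treatment_effect"]]
# het_fc 1.96, homo_fc 15.4, ratio 7.86, treatment_effect Yes
```

A command-line interface mirrors the library
(`survddg simulate | ddg1d | ddg2d | swvg | swvg-apply | enrich |
kinetics | dosage-table | pipeline`).

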