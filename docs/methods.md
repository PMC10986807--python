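# Methods

This note records the statistical model behind each pipeline stage, what
the synthetic-data generator does and does not emulate, the defaults and
why they were chosen, and the numerical decisions that make results
reproducible bit-for-bit.

## Study design being modelled

A prospective biomarker study of TNF-inhibitor response in RA: cases with
high disease activity (DAS28 > 5.1) give serum at baseline and after
3 months of treatment; clinical outcomes (DAS28 and its four components,
EULAR response, remission) are recorded at baseline, 3 and 6 months; a
small healthy-control group anchors the differential-expression filter;
an independent, smaller cohort supports replication. The analysis is
strictly lagged and cross-sectional: proteins at baseline are regressed
against outcomes at 3 and 6 months, proteins at 3 months against
outcomes at 6 months. No repeated-measures or mixed-effects modelling is
attempted — each (protein, outcome, lag) triple is its own regression.

## Clinical scores

DAS28 uses the canonical four-component CRP variant with the additive
constant: `0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.36*ln(hsCRP+1) +
0.014*VAS-GH + 0.96` (hsCRP in mg/L, VAS-GH in mm). An unadjusted
variant without the constant exists in the literature; the
constant-bearing form is used throughout and this choice is flagged here
because only the component list, not the formula, is usually reported.
Remission is strict (`DAS28 < 2.6`). EULAR classification: good if the
attained score is ≤ 3.2 and the improvement exceeds 1.2; none if the
improvement is ≤ 0.6, or the attained score is > 5.1 with improvement
≤ 1.2; moderate otherwise. "Poor" response for logistic modelling is the
"none" category. hsCRP values of 0 are floored at 0.1 mg/L (assay limit
convention) before entering `ln(CRP+1)`; the formula itself is defined
at 0.

## Synthetic cohort generator

Defaults are the study conditions: 180 discovery cases, 58 validation
cases, 14 controls, 482 proteins of which 216 are differentially
expressed (about a third shifted down, the rest up), 10 proteins with
planted outcome effects, log2-scale intensity SD 1.0, DE shift 1.0 log2
unit, 5% missing cells, and a target month-3 remission fraction of 0.30
(a realistic remission rate on a first TNF inhibitor). Intensities are
Gaussian per protein on the log2 scale (log-normal raw), since
protein-level intensity distributions from data-independent-acquisition
MS are approximately log-normal; the case-vs-control shift is additive
on the log2 scale, and month-3 intensities follow an AR(1)-style
within-patient correlation (ρ = 0.6) with the same marginal variance.

Planted effects cycle over six templates (remission at 3 m and 6 m from
baseline protein; VAS-GH and hsCRP at 3 m/6 m from baseline or month-3
protein). Effect sizes are expressed per protein SD: 0.5 outcome-noise
SDs for linear effects, −1.0 log-odds for remission effects. The
`TruthLedger` stores every effect on the *fitted model's raw scale*
(coefficient per log2-intensity unit, with the centring constant), so
recovery tests compare like with like. The validation cohort is drawn
from the same ledger with an independent sub-seed.

Outcome generation works backwards from internal consistency, which is
the delicate part of the design. Remission status is sampled first from
an exact logistic model: intercept (calibrated population-wide by
bisection so the mean remission probability equals the target fraction;
an unreachable target raises an error) + fixed confounder effects +
planted log-odds terms. VAS-GH and hsCRP are then generated from linear
models on their measured scales that include a remission offset
(remitters have lower global-health scores and CRP — without this the
component-level DAS28 floor would contradict sampled remission for about
a third of remitters). Finally the tender/swollen joint counts are
solved, as integers in [0, 28], so that the DAS28 *computed from the
four components* falls strictly on the sampled side of the 2.6 cut-off;
a small deterministic adjustment loop absorbs integer rounding. The
derived remission flag therefore equals the sampled one, the logistic
truth is exact, and DAS28, its components, remission and EULAR class are
mutually consistent for every patient. The cost of this construction is
that DAS28, TJC and SJC cannot carry *directly* planted protein effects
(they inherit them through the remission pathway), so parameter-recovery
guarantees are stated for VAS-GH, hsCRP and remission only. A remitters'
feasibility nudge trims VAS-GH for the ~1–2% of remitter rows whose
CRP+VAS floor would otherwise exceed 2.6; this slightly perturbs the
VAS-GH linear model for those rows and is the main reason VAS-GH
coverage is approximate rather than exact.

One protein is special: P02741 (C-reactive protein). Its intensity at
each timepoint is log2 of the measured hsCRP plus assay noise (SD 0.55
log2 units), giving a SWATH-vs-ELISA Pearson correlation around 0.85 —
the technical-validation stage measures exactly this.

Missingness is missing-completely-at-random by default (no dropout
mechanism is identifiable from the emulated study); an
abundance-dependent left-censoring option exists because real MS dropout
is intensity-dependent. Pre-masking values are kept as a shadow copy so
imputation error is measurable.

What the generator does *not* emulate: peptide-level data, retention
times, batch effects, processing-delay artefacts, protein–protein
intensity correlations, and non-Caucasian or bDMARD-experienced
populations. Passing tests therefore demonstrate that the analysis
machinery is correct and calibrated under its stated assumptions, not
that those assumptions hold in any particular real cohort.

## Preprocessing

Median centring only (each sample shifted so its median matches the
grand median of sample medians): quantile normalization would flatten
exactly the case/control differential structure the DE filter needs.
Imputation defaults to k-nearest-neighbour (k = 5, Euclidean distance
over co-observed proteins, rescaled by the number of shared proteins)
because it exploits between-sample correlation; the fallback and the
alternative method is half-minimum (per-protein minimum observed minus
one log2 unit), which respects left-censoring. A cell whose protein is
observed in fewer than k other samples falls back to half-minimum and
is logged; proteins missing in more than 50% of samples (configurable)
are dropped before imputation. Observed cells are never altered, and a
provenance layer records the origin of every cell. Discovery and
validation matrices are processed independently — replication realism
outweighs any normalization benefit of pooling.

## Differential-expression filter

Welch's unequal-variance t-test, baseline cases vs controls (month-3
samples excluded: the filter targets the untreated disease state).
Retention uses the *raw* P < 0.05 — deliberately unadjusted, because
this step is dimensionality reduction, not inference; the multiplicity
control lives in the screen. DE is computed on the imputed matrix.

## Two-stage screen

Stage 1 is univariate by default. The BH family is one
(outcome, protein-timepoint, outcome-timepoint) triple per stage: this
keeps each family homogeneous (one test statistic, one sample size) and
matches how per-outcome results are naturally reported. Both choices
are genuinely open — a confounder-adjusted stage 1 is available behind
`stage1_adjusted=True`, and the family definition is a documented
constant — but the defaults above are what the funnel counts refer to.
Stage 2 refits survivors with the full 14-covariate confounder set;
final hits are stage-2 BH-adjusted P < 0.05 within the same family
definition. hsCRP as an outcome is modelled on its measured mg/L scale
(so its coefficients are large compared to other outcomes); a log-scale
option exists but is off by default.

Logistic effects are reported as odds ratios with Wald 95% CIs.
Complete or quasi-complete separation is detected (divergent
coefficient/standard-error heuristics, optimizer failure) and the row is
flagged unusable rather than reporting a divergent estimate; a
non-converged Newton fit is retried with BFGS before giving up.
Covariate columns that are constant in the analysis sample (e.g. an
empty comorbidity stratum in a 58-patient validation cohort) are dropped
from that fit and logged — refusing the fit outright would make small
cohorts untestable. Replication refits the identical model specification
on the validation cohort and requires BH-adjusted P < 0.05 *and*
direction agreement with discovery.

Under null simulations the per-family probability of any final hit is
at or below the BH level by construction (the two stages compound), and
planted effects at the default sizes are detected with high power at
n = 180; both properties are asserted by the test suite over many seeded
replicates rather than stated as facts here.

## Enrichment

One-sided hypergeometric (Fisher exact, "greater") over-representation
against an explicit background, BH across sets. The background is a
first-class argument because p-values depend on it strongly: the
interactome node set is used when validating subnetworks, the measured
protein panel when interpreting regression hits. No rank-based combined
scores — they depend on service-internal permutation baselines that
cannot be re-derived locally.

## Network module detection

Connectivity significance of a candidate node with degree k and ks links
into the current module (size s0, graph size N), with integer seed
weight α applied as: N' = N+(α−1)s0, s0' = αs0, k' = k+(α−1)ks,
ks' = αks; p is the hypergeometric tail P(X ≥ ks') for
X ~ HG(N', s0', k'). The weighting convention (seed links *and* seed
nodes count α-fold) is stated explicitly because variant readings exist.
The greedy expansion adds the smallest-p candidate each iteration; ties
break on larger ks, then larger degree, then lexicographic node id — a
fully deterministic rule imposed so module construction is exactly
reproducible. Candidates are restricted to nodes with at least one
module link (a ks = 0 node has p = 1 and cannot win; the restriction is
an optimization with provably identical output, asserted against a
brute-force oracle in the tests). Isolated candidates get p = 1 by
convention.

Numerics: binomial coefficients are evaluated in log space (gammaln) so
genome-scale interactomes (10⁴–10⁵ nodes) do not overflow; for small
weighted problems (N' ≤ 400) the tail is computed in exact rational
arithmetic instead, so a floating-point near-tie can never reorder the
greedy choice — this is what makes the addition sequence bit-identical
to the enumeration oracle.

Grid search: for each α, one DIAMOnD run to max(n_grid); modules at
smaller n are prefixes (greedy nestedness), so the whole grid costs
|alpha_grid| runs. Every (n, α) is scored by the hypergeometric overlap
p between the module and the biological-validation gene list (here: the
member genes of significantly enriched sets); the minimum wins, ties
resolved by smaller n (parsimony), then smaller α. Default grids
n ∈ {25, 50, …, 200}, α ∈ {1..10} bracket plausible optima for
hit lists of a handful of seeds; both are configurable. Seeds absent
from the interactome are dropped with a logged warning.

## Pipeline and reproducibility

All randomness flows from one master seed through named substreams (one
per stage), so adding or re-running a stage never perturbs another.
Artifacts are plain TSV/GMT/JSON with fixed float formatting; the
manifest records the config, the seed, per-stage funnel counts
(proteins → retained → stage-1 → stage-2 → replicated → module) and a
SHA-256 per artifact. Two runs with the same config and seed produce
byte-identical outputs; this is asserted end-to-end in the tests.

## Problem sizes used by the test suite

The acceptance-level tests run at these scales, chosen to exercise the
full mechanism while keeping the suite quick on a single CPU: oracle
equivalence on 100 random graphs of ≤ 15 nodes plus exhaustive tail
checks to N = 25; screen calibration on 50 null cohorts of 180 cases ×
100 proteins; parameter recovery on 100 cohorts of 180 cases × 40
proteins with 6 planted effects; module recovery on 50 interactomes of
400 nodes with a 25-node planted neighbourhood; determinism on a reduced
end-to-end configuration. The `scripts/acceptance.py` run uses the full
default study dimensions.

## Known limitations

- The generator's outcome model is the analysis model (plus the
  remission-consistency construction); it cannot reveal
  model-misspecification behaviour.
- Proteins are simulated independently given the planted structure;
  real co-expression would change the effective multiplicity of the
  screen.
- EULAR-poor response carries no directly planted effects, so its rows
  are only exercised under the null and via the remission pathway.
- Wald logistic intervals are first-order; at n = 58 with 14 covariates
  they are approximate, which is visible as slightly conservative
  replication behaviour.
- The DIAMOnD seed-weighting convention follows the published
  description of the algorithm; other implementations differ in whether
  N and s0 are inflated, and module membership can differ near ties for
  α > 1.
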