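# Methods

This note documents the statistical models, the synthetic-data model, the
numerical choices, and the known limitations of `cortisurv`.

## Cortisol slope estimation

The diurnal slope is ordinary least squares of log cortisol concentration on
hours since waking, pooling all days for a patient into one regression (no
per-day averaging): the sampling design — five fixed times per day over
three days — identifies a single within-patient slope, and pooling uses all
15 points with their actual times. The natural log is the default transform;
the base only rescales the slope, so downstream hazard-ratio directions are
unaffected (`log_base` is configurable). The +45-minute awakening sample is
included by default and can be excluded by flag. Patients with fewer than 3
usable samples, or no variation in collection time, are flagged missing and
excluded by the complete-case policy of the survival stage, mirroring the
usual "complete saliva subset" of cohort analyses. R² is reported as 0 when
the outcome is constant (the usual 0/0 convention).

Units: the time base is hours since waking; the slope unit is therefore
log-cortisol per hour. The synthetic generator calibrates the *marginal
per-hour slope distribution* directly at mean −0.7, SD 0.6 — abstract
"slope units" chosen so the fitted slope distribution reproduces the
descriptive statistics such cohorts report. No claim is made that −0.7/hour
is physiological; the pipeline is unit-agnostic and hazard ratios are
reported per slope unit (an SD-standardised column is a one-line rescale).

## Cox proportional-hazards engine

The log partial likelihood, its gradient, and the observed information are
computed exactly, with Efron's correction for tied event times by default
(lower bias than Breslow when ties are present; Breslow is available and is
used by the brute-force oracle tests). Maximisation is Newton–Raphson with
step-halving, starting at β = 0, declaring convergence when the gradient
norm falls below 1e−8. Two safeguards address monotone likelihoods
(separation): the iteration stops if any |β_j|·sd(x_j) exceeds 10, and a
"converged" solution whose SD-scaled standard error exceeds 5 is re-flagged
as non-convergent. Both checks are scale-invariant. Non-converged fits
refuse to report hazard ratios.

Inference is Wald: HR = exp(β), CI = exp(β ± 1.959964·SE), two-sided normal
p-values — the reporting convention of clinical tables (HR to 2 decimals,
CI to 1). The baseline cumulative hazard is the Breslow estimator at the
fitted β; adjusted survival curves are S(t|x) = exp(−Λ₀(t)·exp(xβ)), drawn
by convention at ±1 SD of the cortisol slope with other covariates at
reference values.

The mediation comparison is the nested-model attenuation used in
epidemiology: fit the exposure model with and without the putative mediator
and report 1 − β_adj/β_unadj on the log-hazard scale with both Wald
p-values. This is descriptive; it is not a formal causal-mediation
estimand.

Risk staging counts seven binary clinical factors (Karnofsky < 80%,
corrected calcium ≥ 10, low haemoglobin, high LDH, prior radiotherapy, ≥2
metastatic sites, ≤1 year from diagnosis to registration): 0–1 low, 2
intermediate, ≥3 high. Laboratory thresholds (sex-specific haemoglobin, 1.5×
the LDH upper limit) belong to data preparation and live in configuration.

## Differential expression

Quantile normalisation forces every sample to the mean empirical
distribution; tied values within a sample receive the mean of the reference
over their rank range (as in the limma implementation). Exact idempotence
and exact equality of column multisets hold for tie-free (continuous) data;
tie collapsing makes them approximate otherwise.

Covariate control is a per-gene linear model of log2 expression on the
group indicator plus covariates, categorical covariates entering as
indicators against their most frequent level; the adjusted difference is
the group coefficient and its p-value a two-sided t-test. With no
covariates this reduces exactly to the difference of group means.
Rank-deficient designs fail loudly, naming the collinear columns.

The call rule couples a symmetric fold threshold (≥1.5 up, ≤1/1.5 down, on
the adjusted log2 difference — the symmetric reading of "at least a 50%
difference" in both directions) with Benjamini–Hochberg q ≤ 0.05;
either-only modes exist behind flags because array studies sometimes report
fold-only calls. BH is the FDR procedure throughout the package. No
moderated-variance (empirical-Bayes) testing is attempted; with planted
2-fold effects at log2 noise 0.2 the per-gene t-test is already far from
its detection boundary, which is why the planted counts are recovered
exactly.

Extreme-group selection takes the top-k CES-D scorers at or above the
screening cutoff (16) and matches low scorers from the bottom of the
distribution within exact sex × smoking × risk-group strata, nearest age
first, expanding the lowest-scorer candidate pool only as far as matching
requires. With identical covariates this reduces to rank selection.

## Promoter TF-activity analysis

TRANSFAC flat files are parsed to position frequency matrices (pure
normalisation, pseudocount 0). The site score is the information-weighted
matrix similarity

    score(s) = Σᵢ Iᵢ f_i(sᵢ) / Σᵢ Iᵢ max_b f_i(b),
    Iᵢ = ln 4 + Σ_b f_i(b) ln f_i(b),

which is 1 exactly on a consensus and lies in [0, 1]. A fully uniform
matrix (all Iᵢ = 0) scores 1 by convention and is flagged degenerate.
Ambiguous bases contribute their expected frequency under a uniform base
(0.25·Iᵢ) by default; a skip-site policy is available. Both strands are
scanned at every offset; overlapping hits count; no de-duplication.

Counts are accumulated over three nested promoter windows (−300, −600,
−1000 to +200 bp of the TSS; smaller windows are suffixes of larger ones,
so counts are monotone under containment) × three stringencies (0.80, 0.90,
0.95; counts monotone in stringency). Activity per motif is the mean over
the nine combinations of the fold-difference in mean sites per promoter,
target vs background (all scanned genes minus the target set by default; a
down-regulated-set comparator is available). A symmetric density offset of
`0.5·(1/n_target + 1/n_background)/2` is added to both group means so an
all-zero combination gives fold 1 rather than a division by zero or a
group-size artefact; for calibrated fixtures (hundreds of promoters,
densities ≈ 2/promoter) the offset is ~0.002 sites/promoter and negligible.
Significance is a two-sided one-sample t-test of the nine log folds against
zero (df 8) — chosen to match the mean ± SE, p reporting shape of
promoter-scan studies — with BH correction across motifs; the nine
combinations are correlated, so this p-value is heuristic, and a
permutation alternative is the cleaner choice when it matters.

Density is sites per promoter, not per bp: windows differ in length, but
each combination compares equal-length windows between groups, so the
choice only rescales within a combination.

The shipped motif library is a **synthetic** toy set — sharp consensus
matrices (match probability 0.91) named after the inflammatory and myeloid
factor families such analyses target. They are not database matrices;
supply a real TRANSFAC file for production use. Related consensi
cross-react (a planted NF-κB-like signal can lift a STAT-like motif), which
mirrors real motif-family behaviour and is why folds are read jointly with
q-values.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail per term
with BH across terms; annotations (GMT) are taken as given, with no
ontology-graph propagation — a documented limitation. The universe defaults
to all assayed genes.

## Synthetic cohort model

The generator plants the causal structure the pipeline is meant to detect:

- **Patients** (default n = 202): a depressed indicator at prevalence 0.23;
  CES-D drawn per group (non-depressed N(7.5, 4.5²) truncated below the
  cutoff, depressed N(21, 4.5²) truncated above), calibrated so the cohort
  mean ≈ 10 and the extreme 15-vs-16 subgroup means land near 25 and 3;
  demographics and seven risk factors from simple independent parametric
  families (matching demographic realism is a non-goal).
- **Cortisol**: latent per-hour slope with marginal mean −0.7, SD 0.6, the
  depressed group flattened by +0.3 slope units (the base distribution is
  adjusted so the marginals stay at the configured values); log-linear
  series at the five daily times with residual SD 0.25; no
  awakening-response bump by default (a `car_bump` flag exists); bedtime
  fixed at +16 h since waking, configurable, because only "bedtime" is ever
  stated in such designs.
- **Survival**: exponential baseline hazard (Weibull shape configurable)
  0.35/yr at the mean linear predictor; log-hazard ln(1.88) per slope unit
  plus a direct depressed effect ln(1.4) (total marginal depression effect
  ≈ 1.7 with the mediated path); censoring uniform on (0, 6 yr) for 90% of
  patients (standing in for staggered accrual plus dropout) and
  administrative at 6 yr otherwise. These constants were fixed once, by
  solving the censoring integral for a ~64% event fraction with observed
  death times averaging ≈ 1.4 yr and ranging to ≈ 6 yr.
- **Expression** (default 5000 genes): per-gene baseline N(7, 1) on the log2
  scale, 116 up- and 57 down-regulated transcripts planted at ±log2(2) on
  the high-CES-D group, small random covariate effects, residual log2 noise
  0.2, exponentiated to the positive array scale.
- **Promoters**: 1200 bp of i.i.d. uniform A/C/G/T with the TSS 200 bp from
  the 3′ end, an exact NF-κB-like 10-bp consensus planted at Poisson mean 2
  sites/promoter (background) and 2 × 1.75 (up-regulated genes), uniform
  non-overlapping positions.

All randomness derives from one integer seed through spawned numpy
`SeedSequence` streams per stage; a fixed seed reproduces byte-identical
bundles and files. Every latent quantity (true slopes, linear predictors,
event times before censoring, planted gene sets, planted site counts) is
recorded in `truth.json`.

What the generator does *not* emulate: questionnaire item structure,
assay-specific noise (heteroscedastic array variance, cortisol assay floor
effects), correlated demographics, linkage between promoters and real gene
identity, and non-uniform promoter base composition. Passing recovery tests
therefore demonstrates the *estimators* are correct and calibrated under
the assumed models, not that real data meet those assumptions.

## Calibration benchmarks and problem sizes

`cortisurv.benchmarks` (used by the test suite and `scripts/acceptance.py`)
runs recovery at these sizes, chosen to keep Monte Carlo error well inside
the tolerances while remaining desk-scale:

- Cox recovery: cohorts of n = 3000 with exponential baseline 0.3/yr and
  uniform censoring to roughly a third censored; a single binary-covariate
  cohort at 23% prevalence carries MC SD ≈ 0.10 on the hazard ratio, so
  recovered log hazard ratios are averaged over replicate cohorts (5
  continuous, 10 binary), which measures systematic accuracy at ≈ 0.03 HR
  precision without changing the estimand.
- Wald CI coverage: 500 replicates of n = 150.
- DE recovery: the full 5000-gene, 116/57, 15-vs-16 fixture (single
  realisation; the planted effects sit ~8 SDs from the call boundary, so
  counts are stable).
- TF-activity recovery: 120 target + 500 background promoters of 1200 bp,
  averaged over 3 replicate fixtures (Poisson planting over 120 promoters
  is the dominant noise source). At detection stringency 0.80 a random
  10-mer matching ≥8 of 10 consensus positions scores exactly ≥ 0.80, so
  uniform background contributes chance hits that pull the three
  0.80-stringency combinations toward 1 while the 0.90/0.95 combinations
  sit at the planted ratio; the nine-combination mean consequently recovers
  ≈ 1.70 for a planted 1.75× density ratio. This dilution is a property of
  the score/stringency definition on uniform background, not an estimator
  bias.

## Known limitations

- No time-varying covariates, frailty, or stratified baselines in the Cox
  engine; no formal causal-mediation estimands.
- The t-test across the correlated 9-combination folds is heuristic (see
  above).
- Quantile normalisation's defining properties are exact only for tie-free
  data.
- The greedy matcher does not optimise a global distance; with sparse
  strata it can fail where an optimal matcher would succeed (it reports the
  offending strata).
- Hypergeometric enrichment ignores the ontology graph and gene-length or
  expression-level bias.
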