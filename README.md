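# cortisurv

Psycho-oncology cohort studies repeatedly observe that depressive symptoms
and a flattened diurnal cortisol rhythm predict shorter survival in advanced
cancer, with pro-inflammatory leukocyte gene expression as a plausible
biological route. Testing that chain requires four analyses that rarely live
in one place: per-patient diurnal cortisol slopes, proportional-hazards
survival models with a mediation comparison, covariate-adjusted fold-change
differential expression, and promoter-based transcription-factor activity
inference. `cortisurv` implements the whole chain, together with a synthetic
cohort generator that plants known effects at every stage, so each analysis
can be validated end to end against ground truth before it ever touches real
data.

It is aimed at biostatisticians and computational biologists who work with
metastatic renal cell carcinoma (or similar) cohorts: patient tables with
CES-D depression scores and clinical risk factors, timed salivary cortisol
series, survival follow-up, leukocyte expression arrays, and promoter
sequences.

## The models

**Diurnal cortisol slope.** Each patient collects five saliva samples per
day (waking, +45 min, +8 h, +12 h, bedtime) for three days. The slope is the
pooled OLS estimate b in

    ln(cortisol) = a + b · t + ε,    t = hours since waking,

per patient. Flatter (less negative) b indicates a blunted
hypothalamic–pituitary–adrenal rhythm.

**Survival.** A Cox proportional-hazards model fitted from the partial
likelihood up: Newton–Raphson with Efron (default) or Breslow handling of
tied event times, Wald standard errors from the inverse observed
information, a Breslow baseline cumulative hazard Λ₀(t) for
covariate-adjusted curves S(t | x) = exp(−Λ₀(t)·eˣᵝ), and a nested-model
mediation comparison reporting the log-hazard attenuation
1 − β_adjusted/β_unadjusted when the cortisol slope enters a model already
containing the depression indicator. Clinical risk staging follows the
standard seven-factor rule (0–1 factors low, 2 intermediate, ≥3 high risk).

**Differential expression.** Arrays are quantile normalised, log2
transformed, and each gene is regressed on the high/low CES-D group
indicator plus covariates (age, sex, ethnicity, education, marital status,
BMI, risk group). A transcript is called regulated when its adjusted fold
change passes 1.5× (up) or 1/1.5 (down) *and* its Benjamini–Hochberg
q-value is ≤ 0.05.

**TF activity (TELiS-style).** TRANSFAC-format position-weight matrices are
scored against promoter windows with the information-weighted
matrix-similarity score (1.0 on a consensus site), both strands, over a
3 × 3 grid of windows (−300, −600, −1000 … +200 bp around the TSS) and
detection stringencies (0.80, 0.90, 0.95). A factor's activity statistic is
the mean, over the nine combinations, of the fold-difference in sites per
promoter between up-regulated and background genes, with a t-test on the
log folds.

## Worked example

```
printf 'cohort:\n  n_genes: 2000\n  n_up: 116\n  n_down: 57\n' > cfg.yaml
cortisurv all --config cfg.yaml --seed 1 --out run1
cat run1/report.txt
```

(Without `--config` the defaults run the full 5000-gene cohort, which takes
a few minutes in the motif-scanning stage.) The run above prints:

```
cortisurv pipeline report (seed 1)

Cohort: 202 patients, 28% CES-D >= 16, 59% deceased
Cortisol slope: mean -0.65 (SD 0.55), n=202
Univariate Cox: cesd_ge16 HR=2.04, slope HR=2.01, risk_intermediate HR=1.39, risk_high HR=0.81
Mediation: cesd_ge16 HR 2.18 -> 1.86 with slope in the model (21% log-HR attenuation; p 0.000 -> 0.002)
Differential expression: 116 up, 57 down
TF activity (mean 9-combination fold): ... NFKB_SYN 1.72x ...
```

Reading it: the simulated cohort reproduces the intended marginals (about a
quarter depressed, roughly two-thirds deceased, slope centred near −0.7);
both the depression indicator and the cortisol slope carry univariate
hazard ratios near 2; adding the slope to the depression model attenuates
the depression log-hazard by ~21%, the mediation signature the generator
plants; the DE stage recalls exactly the 116 up- and 57 down-regulated
transcripts planted at 2-fold; and the NF-κB-like motif planted at 1.75×
density in up-regulated promoters is recovered at 1.72× (q < 0.001). Other
motifs in the toy library show only small-count noise.

Every stage is also a library function — `fit_cortisol_slope`, `fit_cox`,
`hr_table`, `adjusted_survival`, `compare_mediation`, `quantile_normalize`,
`adjusted_differential_expression`, `call_de`, `scan_count`,
`build_count_table`, `tf_activity`, `hypergeom_enrich` — operating on plain
pandas/numpy objects; see the docstrings and `docs/methods.md`.

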