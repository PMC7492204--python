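# cdaf

Survival analysis of **clinical disease activity-free (cDAF)** status in
relapsing-remitting multiple sclerosis (RRMS) cohorts that switched from a
platform injectable therapy to high-dose (44 µg tiw) subcutaneous interferon
beta-1a. The package is aimed at biostatisticians and MS researchers who
need a reproducible pipeline for:

* **endpoint derivation** from longitudinal Kurtzke functional-system (KFS)
  and EDSS records — qualifying relapses (≥ 2-grade rise in one KFS or
  ≥ 1-grade in two, excluding bowel/bladder and cerebral/mental), sustained
  disability progression (EDSS +1.0 confirmed 3 months later), and the
  composite cDAF = min(time to relapse, time to progression), with censoring
  at early termination or end of observation;
* **index-relapse phenotyping** — monosymptomatic (one core system affected)
  vs polysymptomatic (two or more), the cohort's primary prognostic factor;
* **survival analysis** — Kaplan-Meier curves S(t) with landmark
  probabilities at months 6/12/18/24, the k-group log-rank test, and Cox
  proportional hazards λ(t|x) = λ₀(t)·exp(βᵀx) fitted by Newton iteration
  with Efron tie handling, Wald CIs exp(β̂ ± 1.96·SE) and the partial-
  likelihood score test at β = 0;
* a **dual-gated survival CART**: greedy recursive partitioning of the cDAF
  outcome where each split must be significant by *both* the Cox score test
  and the log-rank test (α = 0.05) and leave ≥ 5 subjects per child;
* a **calibrated synthetic cohort generator** (piecewise-exponential relapse
  / progression / dropout processes with proportional-hazards covariate
  effects) so the whole pipeline is testable without patient-level data.

## Worked example

```python
from cdaf import (CartConfig, build_tree, cox_fit, default_config,
                  endpoint_dataset, generate_cohort, km_estimate)

cohort = generate_cohort(default_config(seed=1))      # 300 synthetic subjects
d = endpoint_dataset(cohort, "cDAF")                  # (time, event, covariates)

curve = km_estimate(d)
print([round(curve.prob_at(m), 3) for m in (6, 12, 18, 24)])
# [0.86, 0.713, 0.636, 0.587]

print(cox_fit(d, ["poly_index"]).summary().round(3))
#              coef  se(coef)     HR  HR 95% CI low  HR 95% CI high  Wald p
# covariate
# poly_index  0.828     0.193  2.289          1.567           3.342     0.0

tree = build_tree(d, CartConfig(model_variant="A"))
print(tree.summary())
# n=300, events=112, cDAF@24m=0.587
#   split: poly_index <= 0 (score p=1.051e-05, log-rank p=1.049e-05)
#   [left ] n=162, events=45, cDAF@24m=0.697
#   [right] n=138, events=67, cDAF@24m=0.452
#     split: dominant_symptom in {pyramidal} (score p=0.002008, log-rank p=0.002017)
#     ... (deeper nodes elided)
```

Reading the output: 58.7% of this cohort remains free of clinical disease
activity at month 24; a monosymptomatic index relapse carries a hazard ratio
of 2.29 (95% CI 1.57–3.34) relative to polysymptomatic for *remaining*
active-free (equivalently, polysymptomatic subjects reach disease activity
~2.3× faster); and the tree's first split — accepted by both significance
gates — is exactly that phenotype, with month-24 cDAF probabilities of 0.70
(mono) vs 0.45 (poly) in its two branches.

The same pipeline runs from the shell, against simulated or on-disk CSV
cohorts (`patients.csv`, `visits.csv`, `relapses.csv`):

```sh
cdaf all --simulate --seed 1 --output out/        # full pipeline + manifest
cdaf validate --input out/                        # schema/eligibility checks
cdaf report --input out/                          # print fitted trees
```

Outputs: `endpoints.csv`, `table1.csv` (baseline group comparison with
t/chi-square/Wilcoxon/median tests), `km_curves.csv`, `fits.json`
(univariate hazard ratios and strongest cut-points), `tree_A.json` /
`tree_B.json` (model variants with disease duration vs age at first
symptom), and `manifest.json` with seeds and SHA-256 digests.

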