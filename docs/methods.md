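# Methods

## Scope and model

The package analyses two-year clinical outcomes of relapsing-remitting
multiple sclerosis (RRMS) patients who switched from a platform injectable
therapy (im/sc interferon beta, glatiramer acetate) to high-dose (44 µg tiw)
subcutaneous interferon beta-1a. Three right-censored endpoints are derived
per subject from longitudinal Kurtzke functional-system (KFS) and EDSS
records:

* **relapse-free** — time to the first post-baseline *qualifying relapse*:
  new or worsening symptoms lasting > 24 h, preceded by ≥ 30 days of clinical
  stability, without concurrent fever/infection, producing a ≥ 2-grade
  increase in one KFS or ≥ 1-grade increases in two or more KFS, where
  bowel/bladder and cerebral/mental changes never count;
* **progression-free** — time to *sustained disability progression*: an EDSS
  increase ≥ 1.0 over baseline observed at a scheduled visit and confirmed at
  an assessment 3 months later (± 4 weeks);
* **cDAF** (clinical disease activity-free) — the composite: the earlier of
  the two component events.

Subjects without an event are censored at min(early-termination month, last
assessment, horizon); the default horizon is 24 months.

The primary prognostic factor is the phenotype of the *index relapse* (the
last relapse before the treatment switch): *monosymptomatic* if exactly one
of the five core systems (pyramidal, cerebellar, brainstem, sensory/pain,
visual/optic) worsened, *polysymptomatic* if two or more did; bowel/bladder
and cerebral/mental accompaniment never changes the phenotype.

Argmax rules (most-affected baseline KFS, dominant symptom of the index
relapse) break ties by a fixed priority order — pyramidal > cerebellar >
brainstem > sensory > visual > bowel/bladder > cerebral/mental > other — a
deterministic stand-in for investigator arbitration. The most-affected-KFS
categories brainstem, bowel/bladder, cerebral/mental and "other" are pooled
into "others" because of their low frequency.

## Statistical machinery

**Baseline comparisons.** Pooled-variance two-sample t (df = n₁+n₂−2), also
computable directly from printed (mean, SD, n) summaries; Welch available as
an option. Pearson chi-square *without* continuity correction (required to
reproduce the published sex-table p of 0.35; the Yates-corrected value is
≈ 0.42). Wilcoxon rank-sum with midranks and tie-corrected normal
approximation (exact enumeration below 15 per group without ties). Mood's
median test as a 2×2 chi-square of counts above vs ≤ the pooled median, no
continuity correction.

**Survival.** Kaplan-Meier product-limit curves (events before censorings at
tied times; landmark probabilities read off the right-continuous step
function at months 6/12/18/24). Unweighted k-group log-rank accumulated from
per-event-time hypergeometric observed-minus-expected contributions. Cox
proportional hazards by Newton maximisation of the partial likelihood with
Efron's tie correction (Breslow mode retained; for a binary covariate without
ties the Breslow-mode score statistic at β = 0 equals the log-rank chi-square
to machine precision, which the test suite uses as a cross-operation oracle).
Wald 95% CIs use z = 1.959964 on the log scale; the score test at β = 0 is
reported alongside.

**Cut-point search.** For a candidate variable the best dichotomization is
the one minimising the single-covariate Cox score-test p over a
scale-appropriate grid: the single split for binary factors, every interior
threshold for ordinal scores (relapse counts 1|2–4, 1–2|3–4, 1–3|4; EDSS
half-points), the observed decile grid for continuous variables, and
one-vs-rest partitions for nominal factors. Both sides must contain at least
the minimum node size. No multiplicity correction is applied across
candidates — deliberately mirroring per-test reporting; see *Known
limitations*.

**Dual-gated survival CART.** Greedy recursion on the cDAF dataset: at each
node the strongest variable/split by score-test p is selected (ties broken by
the fixed declaration order of candidates); the split is accepted only if
score p < α **and** the log-rank p on the induced children < α **and** both
children have ≥ `min_node_size` (default 5) subjects; otherwise the branch
terminates. Defaults: α = 0.05, horizon 24 months, no pruning or
cross-validation — the stopping rule is purely significance-based, with
`max_depth` as a safety cap only. Because disease duration and age at first
symptom are linear functions of age at baseline, they never enter together:
variant A offers disease duration, variant B age at first symptom; the
pipeline builds both. Every node carries KM cDAF probabilities at all four
landmark months rather than a single headline month.

## Synthetic cohort generator

No subject-level data are publicly available, so a seeded generator emulates
the study's structure; it is first-class, tested code.

* **Covariates.** 300 subjects by default; 74.7% female; 46.7%
  polysymptomatic. Group-wise normal ages (baseline 36.4 ± 10.0 vs
  40.0 ± 10.0 years; onset 28.4 ± 9.7 vs 32.5 ± 9.2), prior-therapy
  multinomial (49/18.3/17.7/15%), group-wise categorical distributions for
  2-year relapse count, dominant index-relapse symptom and most-affected
  baseline KFS taken from the published group counts. The published table
  reports only medians/ranges for EDSS, so the group-wise half-point EDSS
  distributions were constructed once to match the printed medians (2.0 vs
  3.5), ranges and the printed coarse EDSS bins of the full cohort; the
  relapse-count distributions were chosen so that the 160/140 mixture
  reproduces the printed totals 145/93/50/12. DMT duration is log-normal
  (σ = 0.85) around the group medians 2.6/2.0 years, clipped to the printed
  range 0.1–14.3.
* **Events.** Relapses are a recurrent inhomogeneous-Poisson process and
  progression a single event, both with piecewise-constant hazards on
  [0,6), [6,12), [12,18), [18,24] months, drawn by inversion of the
  cumulative hazard scaled by exp(Σ log-HR · covariate). The multiplier may
  reference derived threshold indicators (e.g. a mono-group relapse-count
  indicator) so tree-recovery experiments can plant branch-specific effects.
  Per-group baseline hazards are solved from the published 6-monthly KM
  profiles: the total cDAF hazard of each segment comes from the cDAF
  profile, its relapse component from the relapse-free profile capped at the
  total, and progression receives the remainder. The three published curves
  are not jointly reproducible under independent component processes (the
  same subjects appear in all three), so the cDAF curve — the primary
  endpoint — is the one matched exactly in expectation.
* **Observation process.** Scheduled visits at months 6/12/18/24 with
  uniform ± 4-week jitter; a latent progression surfaces at the first
  scheduled visit on/after its onset, with the EDSS elevated from that visit
  onward and a confirmation assessment 3 months later. Early termination is
  an independent exponential tuned to 22.3% by month 24 (uniform across
  groups by default, per-group override available); terminated subjects get
  a final assessment at the termination month. Relapse onsets are observed
  at their actual dates, progression only at visits — as in the protocol.
* **Randomness.** One root seed expands into named substreams (covariates,
  events, dropout, visits), so extending one substream leaves the others
  unchanged; identical (config, seed) gives byte-identical CSV output.

What the generator does *not* emulate: MRI activity, neutralizing-antibody
dynamics, informative censoring, secondary-progressive transitions,
EDSS↔KFS internal consistency, or within-subject correlation of relapse
phenotypes over time. Passing tests therefore demonstrate correctness of the
derivation rules and estimators under a proportional-hazards world with
independent censoring, not robustness to those real-data features.

## Experiment sizes and numerical choices

Simulation experiments use: parameter recovery — 50 replicates of n = 2000
with a planted ln 2 log-HR on the poly indicator (95% CI coverage and mean
coefficient bias); planted tree recovery — 50 replicates of n = 2000 with
root HR 2.0 and a nested count-threshold HR 1.8 inside the mono branch,
using a relapse-count distribution shared across groups so the planted root
effect is not confounded with the baseline-table correlation between count
and phenotype; null trees — 50 replicates of n = 300 with no covariate
effects; calibrated cohorts — 10 replicates of n = 300 at the study's own
size. Newton iterations stop when the log-partial-likelihood change
< 1e-10 and the score norm < 1e-6 (max 50 iterations, step-halving on
non-improvement); covariates are centred before fitting; non-convergence is
flagged but estimates are still returned. Degenerate inputs (constant
covariates, zero events, empty nodes) raise typed errors or yield explicit
no-split/skip results rather than NaNs.

## Known limitations

* The cut-point search performs many correlated score tests per node at the
  nominal α without multiplicity control. Consequently the tree's false-split
  rate under a global null is far above α: with ~50 candidate
  dichotomizations at the root, the minimum p falls below 0.05 in most null
  datasets (roughly nine in ten n = 300 null cohorts grow at least one
  split).
  The score and log-rank gates are asymptotically the same test for a binary
  split, so the dual gate does not mitigate this. The procedure is kept as
  specified because it reproduces the reported analysis; users wanting
  honest type-I control should apply their own correction to the reported
  per-split p-values.
* In planted two-level recovery experiments, a nested effect inside one
  branch necessarily raises that branch's average hazard and so dilutes the
  root-level contrast; with the effect sizes used here the root variable's
  marginal advantage over the nested count threshold is modest, and the tree
  occasionally (roughly a fifth to a quarter of replicates) picks the count
  threshold at the root instead. When the root is recovered, the nested
  split is recovered with it.
* Progression is detected only at scheduled visits, so generated progression
  times are right-shifted relative to their latent onsets; this slightly
  biases the earlier landmark probabilities upward and attenuates hazard
  ratios that act through the progression component (the relapse component,
  which dominates, is unaffected).
* Landmark probabilities are KM-based, not raw fractions; with heavy early
  censoring the two can differ noticeably.
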