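# devconn

Predicting early-childhood motor and executive-function development from
resting-state brain functional connectivity — on fully synthetic
longitudinal cohorts.

## The problem

In preschool children (3–6 years), motor skills and executive functions
mature together, and baseline functional-connectivity patterns carry
information about which children will develop faster over the following
year. Studying that question requires a pipeline that (a) turns region-level
fMRI signals into connectivity and graph-topology features, (b) builds
behavioral composites and binary developmental outcomes, (c) trains a
multimodal classifier under a strictly leakage-free cross-validation
protocol with fold-internal multiple imputation, and (d) characterizes
developmental trajectories and feature importance. Real pediatric
neuroimaging data of this kind are rarely shareable, so `devconn` pairs the
full analysis stack with a calibrated synthetic-cohort generator: every
stage is testable end to end, and recovery of known generator truths
substitutes for unavailable ground truth.

It is intended for methodologists who want a reproducible reference
implementation of this analysis style, and for anyone who needs realistic
synthetic longitudinal brain–behavior cohorts with dialable effect sizes.

## What it implements

- **Synthetic cohorts** (`devconn.simulate`): a three-wave cohort (baseline
  N, 6- and 12-month follow-ups) with per-participant P×P connectivity
  matrices structured into 7 canonical networks (SomMot, Vis, DorsAttn,
  VentAttn, Default, Control, Limbic/Subcortical). Block means follow
  age trajectories (e.g. sensorimotor–ventral-attention connectivity rising
  0.15 → 0.22 across 3–5 y, control–default segregation 0.11 → 0.07);
  younger children are "scanned" asleep and older ones awake with a visual
  confound. Behavioral scores (MABC-2-like percentiles, six
  executive-function measures) are drawn from per-age-group norms. A scalar
  latent factor η couples baseline connectivity to 12-month behavioral
  change with configurable effect size; attrition is monotone and
  missingness is missing-at-random given observed auxiliaries (SES, head
  motion, scan state).
- **Connectivity** (`devconn.connectivity`): Pearson FC matrices from time
  series, fixed row-major upper-triangle vectorization (P=360 → 64,620
  features), and the motion QC rule (exclude if mean FD > 0.5 mm or > 20%
  of volumes above the per-volume cutoff).
- **Graph metrics** (`devconn.graph`): 12 scalar topology features per
  thresholded matrix — global/local efficiency, Onnela clustering,
  characteristic path length, small-worldness σ = (C/C₀)/(L/L₀), Louvain
  modularity Q, participation coefficient, within-module degree, their
  null-ensemble z-scores against degree-preserving rewired graphs, and a
  hub-prevalence score.
- **Composites** (`devconn.composites`): reliability-weighted EF composite
  (α_WM·z_WM + α_IC·z_IC + α_CF·z_CF)/(α_WM+α_IC+α_CF), rescaled to mean
  100 / SD 15; median-split binary 12-month outcomes (never imputed).
- **Model** (`devconn.fusion`): a four-channel fusion network —
  connectivity Conv1D→pool→dense, graph-metric dense 32→16, motor and
  cognitive dense(32) encoders, concatenated into a 128→64→32 dropout head
  with a single logit. Trained with Adam (lr 0.001, batch 32), early
  stopping (patience 10 of 100 epochs) and best-weight restoration, in the
  statsmodels style: `FusionClassifier(...).fit()` returns a
  `FusionResults` with `predict_proba` and `summary()`. Ablations:
  `connectivity_only`, `behavioral_only`.
- **Validation** (`devconn.validation`): stratified (age band × outcome)
  70/15/15 holdout and 5-fold CV; fold-internal multiple imputation (m=20,
  chained conditional models with posterior draws, auxiliaries as
  predictors) and z-scaling fit on training folds only; accuracy / rank
  AUC / F1.
- **Importance** (`devconn.importance`): grouped permutation importance
  (accuracy drop in percentage points, 100 shuffles, 5-point substantive
  threshold) and Kendall's W concordance of fold rankings.
- **Trajectories** (`devconn.trajectories`): per-participant growth slopes,
  the dual >1-SD accelerated/slower classification, partial correlations
  with Fisher-z intervals, a natural-cubic-spline (df=3, knots at 48 and 60
  months) random-intercept model compared to a linear-age model by the
  ΔAIC > 10 rule, and within/between-network change contrasts with paired
  t-tests and BH correction.

## Worked example

```python
import devconn as dc
from devconn.pipeline import make_prediction_task, run_cv

spec = dc.CohortSpec(n_baseline=200, n_regions=90, seed=3,
                     effect_size_connectivity=1.0, effect_size_outcome=1.0)
cohort = dc.simulate_cohort(spec)
print(cohort.table["wave"].value_counts().sort_index().to_dict())

task = make_prediction_task(cohort, outcome="motor", n_null=10, seed=3)
reports = run_cv(task, variants=("multimodal", "behavioral_only"),
                 k=5, m=5, m_train=5, seed=3)
for variant, rep in reports.items():
    row = rep.frame.query("scope == 'overall'").iloc[0]
    print(f"{variant:16s} accuracy {row.accuracy_mean:.3f} ± {row.accuracy_sd:.3f} "
          f"AUC {row.auc_roc_mean:.3f}")
```

Output:

```
{1: 200, 2: 177, 3: 158}
multimodal       accuracy 0.753 ± 0.054 AUC 0.849
behavioral_only  accuracy 0.659 ± 0.087 AUC 0.699
```

The wave counts show the configured retention (88.7% / 78.9% of 200,
round-half-up). Under a high-signal cohort (latent factor loading fully on
connectivity and outcome change), the multimodal model recovers the
injected brain–behavior coupling (accuracy well above chance), while the
behavioral-only ablation is limited by the shared-ability factor that masks
the latent signal in baseline behavior — the expected ordering when
connectivity carries the predictive signal.

A command-line pipeline wraps the same stages
(`devconn simulate|features|composites|cv|importance|trajectories|report`),
driven by a YAML config with a master seed and per-stage seed fan-out;
re-running with the same config reproduces byte-identical artifacts.

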