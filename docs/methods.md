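# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the package's own simulations can show.

## Synthetic cohort generator

### What it emulates

A three-wave developmental cohort of children aged 3–6 years: baseline
N (default 256), follow-ups at 6 and 12 months, retention 88.7% / 78.9%
(round-half-up counts, monotone dropout), wave-level missingness 11.3% /
21.1%. Age-group composition, sex ratio, and SES distribution
(low/middle/high = 0.203/0.551/0.246) follow typical urban preschool
samples. Mean framewise displacement falls with age (0.32/0.28/0.24/0.21 mm
for 3/4/5/6-year-olds, gamma-distributed so it stays positive). Children
younger than exactly 60 months are generated as scanned during natural
sleep; older children as awake with video, which adds a configurable
visual-network connectivity increment (the scan-state confound).

### Connectivity

Regions are partitioned into 7 contiguous near-equal networks (SomMot, Vis,
DorsAttn, VentAttn, Default, Control, LimbicSubcort). Each participant-wave
matrix is: block mean + symmetric participant-level block jitter
(SD 0.06) + edge noise (SD 0.10), clipped to (−1, 1), unit diagonal. Block
means encode the developmental structure:

| block | age profile | default |
|---|---|---|
| SomMot–VentAttn | linear ramp 3→5 y | 0.15 → 0.22 |
| SomMot–LimbicSubcort | young/old step at 60 mo | 0.12 → 0.16 |
| Control–Default | young/old step | 0.11 → 0.07 |
| DorsAttn–VentAttn | inverted-U peaking at 54 mo | max 0.17 |
| within SomMot / Vis | longitudinal increment per 12 mo | +0.07 / +0.05 |
| Control–Default (wave) | longitudinal increment | −0.04 |
| within LimbicSubcort | longitudinal increment | +0.01 |

The within-network sensorimotor trajectory and the SomMot–VentAttn ramp are
separate dials because published summaries of "sensorimotor strengthening"
ambiguously refer to either; the generator exposes both.

Time series are multivariate Gaussian draws whose population correlation is
the participant's target matrix (Cholesky of the eigenvalue-clipped
nearest-PD repair when needed, with a warning); the sample FC of a long
series converges to the target.

### Latent coupling and behavioral scores

A scalar standard-normal latent factor η per child drives the
predictability of development:

- connectivity: sensorimotor-centred blocks (within-SomMot, SomMot–VentAttn,
  SomMot–LimbicSubcort) are shifted by `0.06 · effect_size_connectivity · η`;
- behavior, in z units relative to the age-group norm:
  `z = λ₀·η + a·ability + c·trait + 0.5·ε + direction·(months/12)·effect_size_outcome·η`
  with λ₀ = 0.3·effect_size_outcome and the stable remainder split 70/30
  between a child-general ability factor and a task-specific trait, so the
  baseline variance is exactly 1 and configured norms are matched in
  expectation (percentile clipping at 0/100 introduces a sub-point bias at
  extreme age-group means).

Norms are anchored at the *baseline* age group; later waves add a common
per-measure growth rate derived from the norm endpoints
((mean at 6 y − mean at 3 y)/36 months). This keeps the deterministic part
of every child's 12-month change identical, so that with effect size 0 the
change score carries no baseline information — if instead each wave were
drawn from current-age norms, the flattening of norm gains toward age 6
would make the median-split outcome encode age, and age is readable from
connectivity. The baseline cross-section remains calibrated to the
configured per-age-group norms.

The growth term makes 12-month change ≈ common gain + effect_size·η +
noise (noise SD ≈ 0.71 in z units), so with effect size 1 the best
achievable accuracy of a median-split change classifier is ≈ 0.80 — the
signal ceiling, not 1.0. The shared ability factor is deliberate:
behavioral baselines reflect η only weakly (λ₀) and their common variance
cannot be averaged away across tasks, which is what makes the
behavioral-only ablation weaker than connectivity-based models on
high-signal cohorts.

One association survives at zero effect size by construction: baseline
scores correlate negatively (≈ −0.2) with median-split change labels,
because the baseline measurement noise enters the change score with a
negative sign — ordinary regression to the mean, present in any analysis
that both uses a baseline score as a feature and anchors the change score
on it. Null calibration of the evaluation protocol therefore uses the
connectivity-informed model, whose features are genuinely independent of
the outcome under the null; a behavioral or multimodal model scores
slightly above chance on a null cohort without any leakage, and that is
the scientifically correct behavior.

The 16 motor / 12 cognitive feature inventory pads the named measures
(fine/gross/balance/total percentiles; digit span, visuospatial span,
go/no-go, ANT, DCCS switch cost, FIST, three NEPSY-II subtests, EF
composite) with filler subscores that are explicitly synthetic derivatives
(parent score + noise); the full inventory of a real battery is not
published, so fillers are labeled as such. The EF composite column is drawn
directly from its age-group norms rather than recomputed from the task
columns; the reliability-weighted composite function itself is exercised
and tested separately.

Missingness above the dropout-implied floor is injected cell-wise among
retained records with probability a logistic function of observed
auxiliaries only (FD, SES, scan state) — MAR by construction, calibrated to
the configured wave-level totals. Under the default rates the dropout alone
accounts for the configured totals, so item-level masking activates only
for higher configured rates.

### What the generator does not emulate

No spatial geometry, no physiological/scanner noise, no voxel data, no
heavy-tailed motion artifacts, no multi-factor latent structure, no
outcome-dependent (MNAR) missingness. Passing tests therefore show that the
pipeline is correct and calibrated under the stated generative assumptions,
not that the effect sizes transfer to real cohorts.

## Graph features

Matrices are proportionally thresholded (negative weights zeroed, top 15%
of possible edges kept by weight, ties broken by fixed edge order) —
proportional thresholds equalize density across subjects. Distances are
1/weight. The 12 scalars, in fixed order: global efficiency (mean inverse
shortest-path length), local efficiency (mean neighbor-subgraph
efficiency), mean Onnela weighted clustering, characteristic path length
(mean finite distance, warning when disconnected), small-worldness
(C/C₀)/(L/L₀), Louvain modularity Q, its null z, mean participation
coefficient 1 − Σ(κᵢₘ/kᵢ)², its null z, mean within-module strength
fraction, its null z, and hub score (fraction of nodes with nodal
within-module-strength z > 1). Community detection is igraph's C Louvain
implementation, seeded and with canonicalized label order. The null
ensemble (default 50, minimum 10) uses Maslov–Sneppen double-edge swaps (5
per edge) on the binary topology with the weight multiset shuffled onto the
rewired edges; z = (obs − null mean)/null SD, reported 0 with a warning
when the null SD vanishes.

Two summaries are deliberate package choices because no subject-level
definition is standard: the within-module degree *scalar* is the mean
within-module strength fraction (its ensemble z is the companion feature —
keeping the pair non-degenerate), and the hub score uses the classic
nodal z > 1 rule.

## Fusion classifier

Channel encoders: connectivity Conv1D (default 128 filters, kernel 7,
stride 1, max-pool 4 — all configurable) → dense(64); graph metrics dense
32→16; motor and cognitive dense(32). Concatenation feeds a 128→64→32 head
with ReLU + inverted dropout (default rate 0.3) and a single logit. Binary
cross-entropy, Adam (lr 0.001, batch 32), ≤100 epochs, early stopping on
validation loss with patience 10 and best-weight restoration. The network
is implemented directly in numpy (float64), which keeps it fully seeded and
dependency-light; ablation variants instantiate only their channels, so
unused inputs provably cannot affect predictions.

The graph channel is a dense 32→16 stack over the 12 scalar metrics: the
model consumes the printed feature inventory (64,620 + 12 + 16 + 12), and a
message-passing layer over a 12-vector has no graph to pass messages on.

### Desk-scale configuration

The package's own simulation studies (tests and the reproduction script)
run a reduced configuration chosen once: P=90 regions (4,005 connectivity
features), 8 conv filters at stride 4, 80-epoch cap with patience 15,
dropout 0.15, null ensembles of 10, cohorts of n=200, and m_train=5
networks per fold (1 under null conditions, where ensembling cannot create
signal). These are the problem sizes at which the calibration claims are
made; the full-scale defaults (P=360, 128 filters, stride 1, dropout 0.3,
n_null=50) are supported throughout.

## Evaluation protocol

Cross-validation is the primary evaluation (fold-wise mean ± SD), because
that is how performance of this design is normally summarized; the 70/15/15
holdout (floor-rule sizes: 179/38/39 at N=256) is a separate utility.
Strata are age band (3–4 vs 5–6 y) × outcome class; strata smaller than k
are pooled, and the pool folds into the largest stratum if still
undersized. Within each training fold: multiple imputation (m=20 default;
sklearn's iterative chained conditional models with posterior draws,
restricted to the behavioral channels — connectivity features are complete
at baseline by construction — with age, sex, SES, FD and scan state as
predictors), then z-scaling, all parameters fit on the training fold only
and applied unchanged to the test fold. Outcome labels are never imputed;
a label column reaching the imputable block is a hard error. Of the m
completed sets, m_train networks are trained (each with a stratified 15%
inner early-stopping split, degrading gracefully to coarser stratification
or training-loss monitoring in tiny folds) and test-fold probabilities are
pooled by averaging — probability pooling replaces Rubin's rules, which do
not apply to network weights.

Metrics: accuracy at threshold 0.5, AUC as the Mann–Whitney rank statistic
with ties counted half, F1 for class 1 (0 when no positives are
predicted). Age-stratified rows are reported per fold when the subgroup has
both classes and at least 4 members.

## Importance and trajectories

Permutation importance jointly row-shuffles a feature group in the
(preprocessed) test fold, n_perm=100 by default; importance is the drop in
accuracy in percentage points (AUC optional), averaged across folds, with
the >5-point substantive flag and Kendall's W (with tie correction) of the
fold-wise group rankings. Default groups: the four channels plus the
connectivity block pairs.

Growth slopes are per-participant OLS of score on months since baseline
(exactly reproducible, identical to the two-point slope with two waves; an
optional shrinkage dial pulls them toward the grand mean). Accelerated
development requires both domain slopes above mean + 1 SD of the
classified sample; slower requires both below mean − 1 SD; zero-SD slopes
degrade to all-typical with a warning. Partial correlations residualize on
an intercept plus expanded covariates (SES as two dummies against a low
reference) via least squares with a pseudo-inverse fallback and rank
warning; CI by Fisher z with SE = 1/√(n−k−3), p from t on n−k−2 df. The
spline model is `value ~ ns(age, df=3) + sex + SES + mean_FD + scan_state +
(1|participant)`, natural cubic basis by the truncated-power construction
with interior knots at 48 and 60 months and boundary knots at the data
range, fit by maximum likelihood (statsmodels MixedLM; lbfgs with
bfgs/powell fallbacks) so AICs are comparable across fixed-effect
structures; AIC = −2ℓ + 2p with p = fixed effects + 2 variance parameters;
the spline is preferred iff ΔAIC > 10. Network change contrasts average
within-block (upper-triangle) or between-block cells per participant-wave
and report paired t statistics with Benjamini–Hochberg adjustment.

## Numerical and design choices

- Fisher z transform is off by default (the pipeline feeds raw r); the flag
  exists. Constant time series are a hard error naming the region — silent
  NaNs would poison every downstream metric.
- Proportional threshold count = round(density · P(P−1)/2), capped at the
  number of positive weights.
- Median-split ties go to class 0 (determinism requires a fixed rule).
- EF composite weights default to the per-domain means of the task
  reliabilities (WM mean(0.82, 0.78), IC mean(0.85, 0.81), CF mean(0.79,
  0.76)); sample-estimated alphas are supported via `cronbach_alpha`.
  Within-sample z-scores or published-norm z-scores may feed the composite;
  the caller chooses, and the rescale reference sample is explicit.
- Holdout sizes use the floor rule with per-stratum largest-remainder
  allocation adjusted to exact totals.
- Attrition counts use round-half-up, which reproduces 227/202 from
  0.887/0.789 at N=256.
- The master seed fans out to pipeline stages as
  `(seed·10007 + stage_index) mod 2³¹−1`; all artifacts embed a config hash
  and no timestamps, so identical runs are byte-identical.

## Known limitations

Accuracy of the compact network on n≈200 cohorts is fold-noisy (SD across
folds ≈ 0.05–0.08); ensembling across imputation-replicate networks is what
stabilizes it. The null-ensemble z-scores at n_null=10 are themselves noisy
(that size is a floor, not a recommendation). MixedLM occasionally needs
the optimizer fallback chain on degenerate random-intercept variance. The
generator's behavioral norms are point calibrations; between-wave
correlation structure beyond the single ability factor is not modeled.
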