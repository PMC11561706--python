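# Methods

## Problem setting

An epigenetic aging clock is a regression of chronological age on CpG
methylation beta values (fractions of methylated reads, in [0, 1]).
Deviations of its predictions from chronological age are routinely
interpreted as biological-age acceleration or rejuvenation. That reading is
only defensible when the query samples are drawn from (approximately) the
clock's training distribution. `clockshift` quantifies how far that
assumption holds: it detects covariate shift between dataset pairs, measures
the disagreement among model families, tests dataset interchangeability by
the inverse train-test procedure, and attaches per-prediction epistemic
uncertainty through a Gaussian-process clock.

## Covariate-shift diagnostics

For a training/query pair restricted to a CpG panel, each CpG receives a
two-sided two-sample Kolmogorov–Smirnov test of identical beta distributions.
P-values are Benjamini–Hochberg adjusted across the panel (step-up:
`p'_(i) = min_{j≥i} p_(j)·m/j`, capped at 1) and a CpG counts as shifted when
its adjusted p falls below `q = 0.01`. The headline number is the rejected
fraction; a Wilson 95% interval accompanies it as an added honesty measure
(the interval is an extension, not part of the underlying procedure). KS
p-values use the exact distribution when `min(n, m) ≤ 25` and the asymptotic
one otherwise; the KS test is under-powered at small n, so the PCA view
(below) should be read alongside it.

The default panel is the `k` CpGs most |Pearson-r|-correlated with age in
the training set (ties broken by CpG id), a surrogate for published clock
CpG sets; any accurate age-predicting subset serves the purpose, and clock
coefficient files can be supplied for real data. Whole-matrix testing is
available explicitly (`cpgs=None`).

PCA is fitted on the merged, column-mean-centered pair without variance
scaling — beta values share one scale, and rescaling would inflate
near-constant CpGs. Zero-variance columns are dropped first.

## Linear clocks

The de novo clock is a Lasso regression of age on beta values — the
single-hyperparameter equivalent of the ElasticNet construction used by most
published clocks. The regularization strength is chosen by 5-fold
cross-validated MSE over 100 log-spaced alphas spanning three decades down
from `alpha_max` (the smallest alpha with empty support on the centered
data), then the model is refit on all training data at the chosen alpha.
Features are not standardized: beta values already share [0, 1], and
standardization would reweight low-variance CpGs. A constant-age training
set is refused; an all-zero coefficient vector is legal output (the clock
then predicts the training mean).

Performance is summarized by MAE, median AE, `R² = 1 − SS_res/SS_tot`, and
Pearson r with its two-sided p. A constant prediction vector leaves r
undefined; it is reported as NaN with an explicit flag rather than silently
patched. Age units (years for human-like cohorts, months for mouse-like
ones) are carried as metadata and never converted implicitly.

`compare_model_families` exposes model-choice uncertainty: each family
(built-in: Lasso and k-nearest-neighbors; any object with `fit`/`predict`
plus an optional grid participates) is tuned by grid-search 5-fold CV on
MSE, scored on a held-out set, and asked for its rejuvenation delta — the
difference of mean predicted age between two labeled groups of a time
course (negative = rejuvenation). Families that fail to fit are recorded as
failed, never fatal. Random forests, SVR and boosting are deliberately not
bundled: they are off-the-shelf components that plug into the same contract.

## Inverse train-test procedure (ITTP)

Model 1 (Lasso, CV alpha) is fitted on `(X_tr, Y_tr)` and applied to the
query features, giving `Ŷ`. Model 2 — same family, enforced — is fitted on
`(X_query, Ŷ)` at full floating precision (rounding predicted ages would
inject avoidable noise) and applied back to `X_tr`; its agreement with
`Y_tr` is the step-2 metric. CpG universes are intersected before any fit so
both models see one feature space.

*Case 1* (query has ages): step-1 metrics are computable; the pair is
`interchangeable` iff both steps exceed `R² > 0.25` (the default threshold,
configurable). If only step 2 passes, the verdict is `one_way` — the query
still carries the information needed to predict the training ages; if step 1
passes and step 2 fails, the strict conjunction yields
`not_interchangeable`. Step-1/step-2 R² gaps above 0.3 are flagged without
changing the verdict. *Case 2* (unlabeled query): the verdict rests on step
2 alone. Constant intermediary predictions short-circuit to
`not_interchangeable` with reason "degenerate intermediary predictions".
The verdict is a pure function of the recorded metrics and threshold
(`derive_verdict`), so reports can be re-audited.

A structural caveat of any synthetic evaluation: model 2's targets are by
construction an exact linear function of the query features, so whenever the
query retains variation on model 1's support, model 2 can *imitate* model 1
and transfer back to the training set. Interchangeability therefore fails
only when the query genuinely loses the age-bearing variation (e.g. beta
values saturated at 0/1) — which is exactly the OOD situation the procedure
is meant to expose; moderate uniform offsets do not break it.

## Gaussian-process clock

Ages are modeled as `y_i = f(x_i) + ε_i`, `ε_i ~ N(0, σ²)`,
`f ~ GP(0, k)` with the RBF covariance
`k(x_i, x_j) = s²·exp(−‖x_i − x_j‖²/(2l²))`; the white-noise term σ²
carries the aleatoric component. Targets are centered on the training mean
and the offset added back at prediction (ages are positive; a raw zero-mean
prior would bias every estimate). Features enter the kernel unscaled.

Hyperparameters `(s², l, σ²)` maximize the exact log marginal likelihood
`log N(y_c; 0, Σ + σ²I)` via L-BFGS-B in log-parameter space with analytic
gradients, one heuristic start (`s² = var(y)`, `l =` median pairwise
distance, `σ² = var(y)/10`) plus seeded log-uniform restarts (default 5)
within bounds `s² ∈ [1e−2, 1e5]`, `l ∈ [1e−2, 1e3]`, `σ² ∈ [1e−4, 1e4]`.
Covariance factorizations are Cholesky with diagonal jitter escalating
tenfold from 1e−10 to at most 1e−6 before declaring failure.

Predictions use the closed-form conditional: `μ* = k*ᵀ(Σ+σ²I)⁻¹y_c + ȳ`,
`(σ*)² = k(x*,x*) − k*ᵀ(Σ+σ²I)⁻¹k*`. The reported variance is
**latent-only** (σ² excluded), matching the posterior form above and giving
the interpretable ceiling `(σ*)² → s²` for queries far from all training
points; `include_noise=True` adds σ² for observation-level intervals.
Variances are clamped at 0 (clamps counted and logged). Credible intervals
are `μ ± 2·σ*`. Because the RBF kernel fixes the *rate* at which uncertainty
grows with distance, the model can understate uncertainty near the training
cloud and saturate far from it; the ceiling is an assumption, not a
guarantee.

## Group tests

For two single predictions with variances: `z = (μ₂−μ₁)/√(v₁+v₂)`, two-sided
normal p. For groups, a random-effects meta-regression of predicted ages on
an intercept plus a binary group indicator: observation i has variance
`v_i + τ²`, τ² estimated by REML Fisher scoring
(`U = ½(yᵀP²y − tr P)`, `I = ½ tr P²`, `P = W − WX(XᵀWX)⁻¹XᵀW`) with
non-negativity projection, convergence at `|Δτ²| < 1e−8` or 100 iterations.
The effect is the indicator coefficient (sign convention: group B − group A)
with Wald normal inference by default — mirroring standard meta-analysis
tooling — and a Knapp–Hartung t correction behind a flag. With one
observation per group τ² is unidentified: it is pinned to 0 with a warning,
which reduces the test *exactly* to the two-prediction z-test. The
implementation was cross-checked against an independent REML meta-regression
implementation (R `metafor`) to ~1e−7 on a frozen dataset. The design matrix
uses per-sample rows; an aggregate per-group mode is deliberately not the
default. Mann–Whitney U (exact for `min(n,m) ≤ 8` without ties, otherwise
normal approximation with tie correction) serves point-estimate clocks.

## Synthetic data

The generators define the study conditions; they emulate the statistical
structure of the real datasets, not their biology.

* **Aging cohorts** — ages uniform on 20–80 years (defaults); each of
  `n_age_cpgs` age-linked CpGs follows
  `beta = clip(b0 + slope·age + ε, 0, 1)`, `ε ~ N(0, noise_sd²)`,
  `noise_sd = 0.03`; remaining CpGs are age-independent noise around random
  baselines. Slope magnitudes are uniform on 0.004–0.010 beta/year with
  random sign — 0.24–0.6 beta over the age range, the change magnitude seen
  at CpGs selected into published clocks, so each age-CpG individually
  carries clock-grade signal (|r| ≈ 0.92–0.99 at the default noise). Weaker
  slopes would make the age-linked set undetectable in principle at these
  sample sizes and would not represent an "accurate age-predicting subset".
  Baselines of age-CpGs are placed so the noiseless trajectory stays in
  [0.05, 0.95], keeping boundary clipping rare. Beta values are clipped, not
  logit-transformed, to stay on the beta scale and exercise boundary
  behavior. CpG-level parameters are a function of the config seed alone and
  sample-level draws of an optional `sample_seed`, so independent cohorts
  from one process are expressible. True age-CpG identities are stored in
  `attrs` for support-recovery tests — synthetic-only information that real
  data does not carry.
* **Covariate/response shifts** — a chosen fraction of CpGs receives a fixed
  or `N(0, offset_sd²)` beta offset, either signed or pushed toward the
  nearer of the 0/1 attractors; ages can be biased additively (response
  shift). Zero offsets are the identity; untouched columns are bitwise
  unchanged; columns driven constant by clipping are flagged.
* **Reprogramming courses** — day-0 samples from the aging process at one
  donor age; later days drift toward the nearer beta attractor by
  `drift_per_day · day` on a configurable CpG fraction. Ages are absent by
  construction (the unknown under study); the day is the group label.
* **Anthropometric toy cohorts** — (age, height, weight) with jointly normal
  height/weight per age, ages uniform on 0–276 months, 1000 samples per
  cohort by default. Mean curves are linear in age with age-growing SDs —
  synthetic stand-ins for tabulated growth references, not interpolations of
  them. The shifted cohort is systematically shorter (adult mean ≈ 130 cm vs
  174 cm) and correspondingly lighter, so both covariate distributions
  differ visibly; a control-trained height/weight clock then under-predicts
  its ages, the canonical covariate-shift artifact.

What the generators do **not** emulate: array/RRBS platform effects,
beta-value heteroscedasticity and spatial CpG correlation, cell-composition
confounding, sex chromosomes, nonlinear age trajectories, or any mechanistic
methylation dynamics. Passing tests demonstrate the statistical machinery on
data satisfying the clocks' own assumptions; they do not certify behavior on
real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest sizes chosen as
sufficient for their statistical purpose: aging cohorts of 100–300 samples ×
150–1000 CpGs, GP fits at n ≤ 200, 20 replicate null pairs for KS
calibration, 2000 replicates for meta-regression type-I error, 5–10 seeds
for recovery/verdict sweeps. GP hyperparameter recovery simulates from a
known kernel (s² = 4, l = 0.5, σ² = 0.1, n = 200) with inputs uniform on
[0, 5]² so roughly ten length-scales per axis make all three parameters
identifiable from a single draw. Exact-equality checks (posterior vs dense
inverse, BH vs brute force) use 1e−8/exact tolerances; hand-computable cases
(one-point GP posterior, KS D on separated supports, MWW on separated
triples) are asserted at machine precision.

The pipeline derives per-stage seeds from one global seed via a stable CRC
hash of the stage name, so stages are individually reproducible and reports
are byte-identical across runs (no timestamps enter the report).

## Known limitations

* The GP clock is exact (dense Cholesky), O(n³) in training samples —
  appropriate for the few-hundred-sample cohorts of this problem class, not
  for biobank scale; no sparse approximation is provided.
* Lasso support recovery at CV-minimum alpha is intrinsically variable when
  many informative CpGs are mutually redundant (single-fit recall of the
  true set has SD ≈ 0.05 at the default conditions); recovery statements are
  therefore made about means over replicate simulations.
* The KS+PCA diagnostics detect marginal distribution shifts per CpG; joint
  or correlation-structure shifts with unchanged marginals will pass them.
* Wald inference for the meta-regression is slightly anti-conservative at
  very small group counts; the Knapp–Hartung option exists for that regime.
* Published clocks are applied only as user-supplied linear coefficient
  tables; nonlinear age transforms of some clocks are out of scope.
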