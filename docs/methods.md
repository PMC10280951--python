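# Methods

This note records the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
scenarios do and do not establish about real data.

## Second-order Gaussian knockoffs

For a feature matrix X (n × p) the sampler estimates μ (column means) and
Σ, then samples knockoffs X̃ row-wise from

    X̃ | X = x  ~  N( μ + (x − μ) Σ⁻¹(Σ − diag(s)),
                      2 diag(s) − diag(s) Σ⁻¹ diag(s) ),

which makes the joint second moments of [X, X̃] equal to the exchangeable
target G = [[Σ, Σ − diag(s)], [Σ − diag(s), Σ]]. Because X̃ is generated
without reference to the outcome, a knockoff retains each feature's
association with the other features but none with the outcome beyond them
— the construction that makes conditional (rather than marginal)
importance measurable. These are *second-order* knockoffs: only means and
covariances are matched, which is exact for jointly Gaussian features and
an approximation otherwise. Binary or ordinal columns are handled by the
same Gaussian approximation and their knockoffs are left continuous (no
rounding); this mirrors how the construction is applied to mixed clinical
features in practice, and the synthetic generator is continuous Gaussian
for the same reason.

**Decorrelation vector.** Default rule is equicorrelated: on the
correlation scale every coordinate is s = min(2·λ_min(corr(Σ)), 1),
rescaled by the variances. It is closed-form, dependency-free, and the
documented default of the standard second-order generator. An SDP rule
(maximize Σ s_j subject to G ⪰ 0, 0 ≤ s_j ≤ 1) is exposed but requires
cvxpy; without a solver it falls back to the equicorrelated point with a
warning — the fallback is always SDP-feasible, so results degrade
gracefully rather than failing. s = 0 is the degenerate copy limit
(X̃ = X exactly), used as a sanity check.

**Covariance conditioning.** Σ is the convex combination
(1 − γ)·Ŝ + γ·diag(Ŝ). γ defaults to the analytic Ledoit–Wolf intensity
and is doubled until λ_min(Σ) > 1e−8, which handles p-close-to-n regimes
(the motivating studies run p ≈ 157 at n ≈ 4500). Eigenvalues of the
conditional covariance in [−1e−10, 0) are treated as numerical zeros and
clipped before factorization; anything lower is an error. Constant
(zero-variance) columns are rejected by name — knockoffs are undefined for
them.

**One draw per study.** Knockoffs are generated once for the full sample —
training and testing rows together, before splitting — and reused across
all groups of a study; RF₂ differs between groups only in which columns
are swapped. Generating before the split follows the procedure this
package reproduces; the mild train/test information sharing it implies
(the knockoff model sees test rows' features, never outcomes) is accepted
and documented rather than silently changed.

## Bootstrap forests

`BootstrapForest` is classic bagging: T trees (default 500), each fit on a
size-n resample drawn with replacement, with `mtry` candidate features per
split (default ⌊√p⌋) and a minimum terminal node size (default 5 in
regression mode, 1 in classification mode, matching common forest
software). The bootstrap is drawn by the package and recorded as an n × T
multiplicity table, because the out-of-bag machinery needs exact
membership: participant i's *sub-forest* is the set of trees whose
resample excluded i; for n ≥ 50 and T ≥ 100 every participant is OOB
somewhere with overwhelming probability, and the mean OOB fraction
approaches (1 − 1/n)ⁿ → e⁻¹ ≈ 0.368. Tree growing itself is scikit-learn's
CART with variance splitting (regression) or Gini (classification); split
randomness is seeded per tree from a spawned substream, so one base seed
reproduces the entire ensemble. Regression mode on a 0/1 outcome (a
probability machine; scores are mean tree outputs in [0, 1]) is the
default used for tuning and knockoff importance; classification mode
(majority vote) exists for the OOB importance reproduction. Classification
is `score ≥ threshold ⇒ 1` everywhere, including the Youden scan.

## Out-of-bag permutation importance

For feature j: per participant i with a non-empty sub-forest, P_i is the
indicator that the sub-forest's aggregated prediction of i's own
observation is correct at the implicit 0.5 cut; P_i* is the same after
x_ij is replaced by a value drawn uniformly from the observed column
(excluding i's own row, drawn independently per participant); the VIMP is
the mean of P_i − P_i* over contributing participants, averaged over
`n_repeats` (default 5) independent substitution draws. A synchronized
column-permutation variant is available behind `method="permute"` for
parity with the permutation option of standard forest software.
Participants in-bag for every tree are skipped and counted
(`n_contributing`), never imputed. Substitution streams are seeded from
(base seed, feature index), so features are independent but the whole
table replays from one seed. A feature never split on cannot move any
prediction, so its VIMP is exactly zero; the implementation is tested for
exact equality against a brute-force walk over every (participant, tree,
substitution) triple.

This estimator is the package's *negative control*: it measures the role
of a feature in the specific fitted forest, and a null feature correlated
with a causal one is used by many trees, so its OOB VIMP is inflated —
increasingly so as the correlation grows (tested as a monotone trend over
ρ ∈ {0, 0.5, 0.9}).

## Knockoff importance

For a named group of features: RF₁ is trained on the true training
features; RF₂ on the same rows with every group member replaced by its
knockoff column; on the held-out test rows RF₁ scores the true features
and RF₂ the group-swapped features, both classified at the same threshold.
Reported VIMPs are aggregate metric differences — VIMP_sens =
sens(RF₁) − sens(RF₂), VIMP_spec and VIMP_acc likewise. The aggregate
difference equals the mean of per-participant correctness deltas over the
relevant class (positives for sensitivity, negatives for specificity, all
test rows for accuracy); the per-participant deltas are retained on each
result so that reading is reproducible. This class-restricted reading
reconciles per-participant averaging with sensitivity/specificity
restriction, and gives the exact identity

    VIMP_acc = π · VIMP_sens + (1 − π) · VIMP_spec,

with π the test-set prevalence (enforced to 1e−12 in tests). RF₂ uses an
independent seed derived from the base seed and the group's qualified name
(a SHA-256 of "level/group", so results do not depend on Python's hash
randomization); tying RF₂'s seed to RF₁'s would understate the
Monte-Carlo variation between forests. Undefined metrics (no positives or
no negatives in the test truth) raise rather than returning a silent 0.

A study (`run_study`) trains RF₁ once and reuses it across all groups of
all hierarchy levels; per-group failures are recorded in an `error` column
while remaining groups run. Replicate mode re-runs split, forests, and
knockoff draw R times and reports per-group means and sample standard
deviations, acknowledging that single-split VIMPs vary across iterations.
A report filter keeps only groups with both VIMP_sens > 0 and
VIMP_spec > 0, the restriction conventionally applied when plotting
grouped results.

**Threshold.** Default `"auto"` selects the Youden cut from RF₁'s
out-of-bag scores on the training rows — out-of-sample with respect to
each row, without spending a further split. An explicit threshold (e.g. a
published operating point such as 0.03) can be supplied instead.

## Tuning and threshold selection

The grid search evaluates mtry = max(1, ⌊x·p⌋) and min node size =
max(1, round(Nʸ)) over x, y ∈ {0.1, …, 1.0} (10 × 10 by default) with
stratified k-fold CV (default k = 10; per-fold class counts differ by at
most one). The score is RMSE of held-out regression scores against the 0/1
outcome, pooled over folds (pooling is invariant to fold-size imbalance,
unlike per-fold averaging). N in the node-size formula is the full sample
size by default (`node_size_n="fold"` switches to the per-fold training
size). Ties break toward smaller mtry, then smaller node size. The
rounding rules (floor for mtry, round for node size, both floored at 1)
are stated here because the formulas alone do not determine them.

`youden_threshold` scans candidates = {0, 1} ∪ midpoints of consecutive
sorted unique scores — sufficient because J is piecewise constant between
observed scores — and returns the smallest maximizer of
J = sensitivity + specificity − 1 (maximizing sensitivity among
maximizers; conservative for screening). `youden_threshold_cv` reports
per-fold thresholds with mean and sample SD (denominator k − 1); a fold
whose held-out labels collapse to one class is an error naming the fold.
For rare outcomes the scores of a regression forest concentrate near the
prevalence, so the selected cut sits far below 0.5 (≈ 0.05 at 2.7%
prevalence in the acceptance run) — one reason accuracy at 0.5 is a poor
lens for imbalanced problems.

## Synthetic scenarios

`simulate_features` draws i.i.d. rows from N(0, R) with R assembled from
named blocks (identity, exchangeable, AR(1)); non-positive-definite blocks
are rejected with the offending block named. `simulate_outcome` draws
Bernoulli(logistic(α + Σ β_j x_ij)) with α solved by Brent's method
against a Gauss–Hermite quadrature (201 nodes) expectation of the logistic
under a normal approximation to the linear predictor, so the expected
prevalence hits the target to ~1e−13; with no effects this reduces to
α = logit(prevalence). One base seed spawns independent substreams for
the feature and outcome stages, so either can be redrawn alone.

`make_bias_scenario` builds the correlated-null construction: X1 ⟂ X2
causal with stated log-odds, corr(X2, X3) = ρ with X3's generating
coefficient exactly zero, plus independent noise features, and a grouping
that marks the roles. `make_domain_scenario` builds a two-level nested
domain hierarchy with signal confined to named domains.

Defaults: prevalence 0.027 is the rare-outcome emulation target; the
demonstration and test scenarios use 0.2–0.3, since at feasible n a 2.7%
outcome leaves sensitivity-based metrics too unstable to be informative
(a rare outcome needs very large samples for stable sensitivity).
Demonstration scales used by the acceptance checks: the correlated-null
contrast runs 20 replicates at n = 3000, ρ = 0.9, β = (1, 1), prevalence
0.2 with 500-tree forests; null calibration runs 30 replicates at
n = 2000, p = 10 with 100-tree forests; the acceptance script uses
300-tree forests and 10 replicates for the same contrast.

**What the scenarios do not emulate:** non-Gaussian marginals, mixed
binary/ordinal measurement, missingness and imputation, within-domain
nonlinear dependence, and cohort-scale feature counts. Passing tests
establish the algorithms' correctness and their qualitative contrast under
Gaussian conditions; they do not certify behaviour under real mixed-type
clinical data, where the Gaussian knockoff is an approximation.

## Numerical conventions and limitations

- PSD tolerance: eigenvalues ≥ −1e−10 are accepted and clipped to zero in
  the sampling factorization; the joint matrix G gets a multiplicative
  back-off on s (factors of 1 − 1e−6) if it dips below tolerance.
- All randomness flows through numpy `SeedSequence` spawning; identical
  configuration and base seed give byte-identical output files
  (demonstrated end-to-end over simulate → tune → knockoffs → grouped
  VIMP).
- The per-participant OOB accuracy indicator has coarse resolution when
  classes are imbalanced: the sub-forest aggregate must cross 0.5 for a
  participant to register, so VIMP magnitudes are small and
  replicate-level Monte-Carlo spread (forest + data draw, ~2e−3 at the
  demonstration scale) is of the same order as the inflation gap for a
  single correlated null at β = 1. Replicate-median comparisons are
  stable at that scale; per-replicate rank events ("X3 beats all noise
  features") are not, and need stronger signal or more aggressive
  correlation to be near-certain per replicate.
- Knockoff VIMPs from a single 80/20 split inherit split-to-split
  variation; replicate mode exists precisely to quantify it. No formal
  inference (tests, confidence intervals) is attached to VIMPs — the
  package reports magnitudes, replicate spreads, and sign frequencies.
- Forest persistence is a versioned pickle archive; load verifies the
  version and restores predictions bit-for-bit. It is a runtime artifact,
  not an interchange format.
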