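# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Cross-sectional networks

Each wave's network is a Gaussian graphical model over the p = 11 symptom
scores: edge weights are partial correlations obtained by standardizing the
off-diagonal of the inverse correlation matrix, `w_ij = −K_ij/√(K_ii K_jj)`
with `K = C⁻¹`. Two estimators are provided.

**Nonregularized (default).** A direct inversion of the correlation matrix,
following the recommendation that lasso regularization is unnecessary and
can distort edge weights for psychometric data at moderate n/p. The full
weight matrix is reported; no edge is pruned. An optional two-sided Fisher-z
test per edge (α = 0.05, no multiplicity correction) is available but off by
default — the main output is the unpruned network, and display thresholding
(drop |w| ≤ 0.1 when drawing a dense figure) is reporting-only and never
changes the model.

**EBIC graphical lasso.** An L1-penalized precision estimate over a
log-spaced grid of 100 penalties from `λ_max` (the largest absolute
off-diagonal correlation, above which the solution is diagonal) down to
`λ_max/100`, scored by the extended BIC
`−2·loglik + E·log n + 4γ·E·log p` with `loglik = (n/2)(log det K − tr(CK))`
and `E` the number of nonzero upper-triangle precision entries. γ defaults
to 0.5, the conventional sparsity-leaning setting. The coordinate-descent
solver is scikit-learn's `graphical_lasso` (dual-gap tolerance 1e−5); the
EBIC scoring, grid, and selection are this package's own. Because the EBIC
is evaluated on the *penalized* precision, the selected model tends to carry
a few near-zero spurious edges alongside the shrunken true ones; by default
the selected partial correlations below `√(log p / n)` — the rate at which
thresholded graphical-lasso estimates are sign-consistent — are zeroed
(`edge_threshold=False` disables this). On sparse 11-node truths at
n = 2000 this lifts support-recovery F1 from ≈0.82–0.93 to ≈0.97–1.0.

**Correlation input.** Spearman by default (the scores are 5-point ordinal),
computed as the product–moment correlation of average ranks; Pearson is
available and is the conventional input of the comparison test below.
Rank-based matrices can be indefinite, so an automatic repair clips
eigenvalues at 1e−8 and rescales to unit diagonal before any inversion; the
`repaired` flag is carried into all downstream metadata. Polychoric
correlations, arguably more principled for ordinal items, are out of scope.

**Node predictability** is computed under a Gaussian working model on
standardized variables: `R²_j = 1 − 1/K_jj`, identical to the OLS R² of node
j on all others (verified against that oracle to 1e−8). This deliberately
differs from mixed-graphical-model predictability estimated by
node-specific regularized regressions: that estimator can return exactly
zero for a weakly connected node, whereas the Gaussian R² is small but
positive. Predictability values from the two approaches are therefore
comparable in pattern, not digit-for-digit.

## Network comparison test

The NCT statistic is the absolute difference in global strength
(`S = Σ_{i<j}|w_ij|`) between two samples, with networks re-estimated from
scratch inside every permutation. Two null schemes:

* **paired** (default when both samples carry the same subject ids in the
  same order): each subject's two wave vectors are swapped independently
  with probability ½ — the exchangeability null appropriate when the same
  patients are measured twice;
* **unpaired**: all rows pooled and re-split at the original sizes, the
  independent-groups null.

The p-value is `(1 + #{permuted ≥ observed})/(1 + n_perm)`, never exactly
zero. The internal estimator defaults to EBIC-glasso on Pearson input (the
convention of the reference implementation of this test) and is switchable
to the nonregularized Spearman estimator; the choice is recorded in the
result. Calibration does not depend on the internal estimator — the
acceptance checks run the nonregularized one, whose closed-form inversion
makes 400 replicates × 250 permutations cheap on one CPU — and the measured
type-I error at α = 0.05 sits inside [0.03, 0.08].

## Panel graphical VAR

With three waves per subject, the temporal model is estimated by pooling
all consecutive transitions (t0→t1, t1→t2) and fitting multivariate least
squares of wave-t scores on wave-(t−1) scores with intercepts. This is a
pooled Granger-regression formulation — closed-form, with Wald standard
errors — not a latent-variable ML/SEM decomposition into within- and
between-person networks; it estimates the same temporal matrix under the
stationarity assumption, but does not separate stable between-person
variance from within-person dynamics. Consequences and options:

* `centering="subject_mean"` removes each subject's across-wave mean, but
  with T = 3 induces Nickell-type downward bias in the autoregressive
  diagonal (demonstrated in the test suite); the default is therefore
  `centering="none"`, which is unbiased when between-person variance is
  absent and conservative about what three waves can identify.
* `standardize=True` z-scores each symptom on the pooled data, making B
  invariant to per-symptom affine rescaling.
* `check_stationarity` reports the spectral radius of B; a radius ≥ 1
  flags explosive fitted dynamics. Mean-nonstationarity (symptom means fall
  over treatment) biases the pooled fit; the study-shaped generator has
  declining means on purpose, and the parameter-recovery checks use a
  constant-mean configuration that matches the model assumptions.

The contemporaneous network is `precision_to_pcor` of the inverse residual
correlation matrix. Per-coefficient Wald tests (t distribution,
`df = N − p − 1`) give the directed edge list; no multiplicity correction by
default, Holm optional. B is stored `[outcome, predictor]`; all exports
label edges `from` (predictor) → `to` (outcome).

## Bootstrap stability

Edge accuracy: nonparametric bootstrap over subjects (default ≥100
resamples), 2.5%/97.5% quantile intervals per edge; a resample on which
estimation fails (e.g. a zero-variance column) is redrawn and counted.
Centrality stability: case-drop subsampling over a grid of drop proportions
(default 5%–75% in 5% steps); at each proportion the Spearman correlation
between subsampled and full-sample node strength is recorded, and the
CS-coefficient is the largest proportion at which that correlation is
≥ 0.7 in ≥ 95% of resamples (0.7/0.95 follow the standard guidelines; the
correlation is Spearman because an 11-entry centrality vector is short and
tie-prone). An undefined correlation — a constant strength vector, as when
a sparse estimator returns an empty network — counts as a failure, which is
what drives the CS below the grid on unstructured data. Two structural
caveats the tests document: with a near-overlap subsample (5% drop) any
smooth estimator's centrality correlates mechanically with the full sample,
so unstructured data only yields CS < 0.05 under a sparse estimator; and a
truth with near-tied node strengths has an unstable strength *ranking* by
construction, so the structured-data check uses a generator with
well-separated centralities (`hub_chain_pcor`).

## Synthetic generator

Per subject: a stable person effect `μ_i ~ N(0, diag(between_sd²))`, a
wave-0 latent state drawn from the stationary distribution of the VAR
(discrete Lyapunov solution), then
`y_t = m_t + μ_i + B(y_{t−1} − m_{t−1} − μ_i) + ε_t`, `ε_t ~ N(0, Σ)` with
Σ implied by the configured contemporaneous partial correlations at unit
partial variances (`K = I − P` off-diagonal, `Σ = K⁻¹`). Latents are cut at
thresholds (default 0.5, 1.5, 2.5, 3.5) into scores 0–4. The study-shaped
default (`study_config`) is 100 subjects × 3 waves × 11 symptoms named as
on the YMRS, acute-episode wave-0 means (e.g. elevated mood ≈ 3.6, reduced
sexual interest ≈ 0.8) declining linearly to 25% by discharge — mimicking a
treated inpatient episode, including its deliberate mean-nonstationarity.
Defaults for the truth structures are a ring-plus-shortcuts contemporaneous
network (weights 0.2–0.25) and an autoregressive temporal matrix (diagonal
0.4 with a few cross-lags), spectral radius < 1 enforced at construction.

What the generator does **not** emulate: item-specific measurement error,
informative missingness, floor/ceiling asymmetries beyond what thresholds
induce, treatment heterogeneity, and polychoric-style latent non-normality.
Passing tests show the estimators recover known latent-Gaussian structure
through ordinal discretization — not that any specific clinical dataset
satisfies those assumptions. Discretization attenuates associations
(ordinal Spearman ≲ latent Pearson), which the tests check in expectation.

## Numerical conventions and degenerate inputs

* Scores are validated as integers in [0, 4]; violations are reported with
  subject/wave/symptom labels, never clipped. Missing data: listwise
  deletion per wave (the only policy); a wave with fewer than p + 2
  complete subjects is an error.
* Descriptive SD uses the n − 1 denominator. Spearman ties get average
  ranks.
* PSD repair: eigenvalue clip at 1e−8 + diagonal rescale; precision entries
  below 1e−10 are structural zeros when counting E for the EBIC.
* Permutation p-values are +1-corrected. All resampling uses
  `numpy.random.default_rng` with explicit seeds; identical seeds give
  bit-identical results everywhere.
* The pipeline isolates stage failures: a wave whose network cannot be
  estimated is recorded in `report.failures` while the remaining waves,
  comparisons and the temporal model still run.

## Problem sizes used in validation

The acceptance checks run at the sizes the properties are stated for:
200 random 11×11 matrices for oracle equivalence; 400 replicates × 250
permutations (n = 100) for NCT calibration and 40 replicates (n = 300) for
power; n = 5000 subjects (10 000 transitions) for temporal recovery;
n = 2000 for EBIC support recovery and structured-data stability; and the
100 × 3 × 11 study-shaped fixture for the end-to-end workflow.
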