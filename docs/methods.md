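# Methods

## Model and likelihood

The observation model is a Gaussian-emission latent Markov (hidden Markov)
model for panels of bounded test scores. For subject *i* with sequence
*y*ᵢ₁…*y*ᵢT on a 0–100 scale, the latent state sequence follows a
first-order chain with initial distribution δ (length *r*) and a single
time-homogeneous transition matrix **P** (*r*×*r*, row-stochastic) shared
by all subjects and waves; state *k* emits N(μₖ, σₖ²). A missing wave
contributes an emission likelihood of one, i.e. is marginalized exactly —
this is what the "native missing" path uses; the default path multiply
imputes first (below). Subjects are independent given the parameters, so
the cohort log-likelihood is the sum of per-subject forward recursions.

The forward–backward E-step uses per-step scaling plus a per-cell max-shift
of the emission matrix, which keeps every intermediate in (0, 1] and the
log-likelihood exact to machine precision; sequences up to T ≈ 10⁴ are safe
from underflow. Posterior state probabilities (gamma) and posterior
transition probabilities (xi) are renormalized slices of the scaled
quantities.

Time-homogeneity and state-specific (not shared) emission variances are
modeling choices: one transition kernel per scenario is the natural summary
when the substantive question is "how do learners move between stages", and
per-state SDs let low- and high-performing stages have different score
dispersion.

## Estimation

Baum–Welch EM with closed-form Gaussian M-steps. Numerical choices:

- **Initialization**: sorted scores are split into *r* quantile blocks;
  block means/SDs initialize the emissions; transition starts at 0.8 on the
  diagonal with the remainder uniform; δ uniform. Restarts (default 5 for
  direct fits; the pipeline uses 3) jitter the initial means with seeded
  Gaussian noise of half the pooled score SD; the best final log-likelihood
  wins. Everything is driven by one integer seed.
- **Convergence**: relative log-likelihood change below 1e−8, capped at 500
  iterations. The per-iteration log-likelihood path is retained so the EM
  ascent property is testable on every fit.
- **SD floor** of 0.5 points prevents degenerate zero-variance spikes at
  repeated score values. Requesting more states than there are distinct
  observed scores raises a degeneracy error.
- **Label switching** is resolved by relabeling states in ascending order
  of fitted emission mean, so state 0 is always the lowest-scoring stage.

State-count selection fits every *r* in a grid (default 3–6) and picks the
minimum of the chosen criterion (default BIC) among converged fits. The
parameter count is *p* = (*r*−1) + *r*(*r*−1) + 2*r* = *r*² + 2*r* − 1 and
the BIC sample size *n* is the number of non-missing score observations
(the likelihood is observation-level; with N subjects fully observed at T
waves, *n* = NT).

## Score bands

The cutoff between adjacent states *k*, *k*+1 is the root of
N(b; μₖ, σₖ) = N(b; μₖ₊₁, σₖ₊₁) lying between the two means: the midpoint
of the means when σₖ = σₖ₊₁, otherwise the root of the corresponding
quadratic (with a midpoint fallback if no root separates the means, which
cannot occur for well-separated unimodal fits). Boundaries are kept
unrounded internally; rendering as `[0, b₁], (b₁, b₂], …, (b_{r−1}, 100]`
rounds to integers for display only.

## Per-subject steady states

A subject's transition matrix sums their posterior expected transition
counts per origin state and adds `shrinkage` (default 0.5)
pseudo-transitions distributed as the population row, then normalizes rows.
With only T−1 ∈ {5, 9} observed transitions per subject, raw rows can be
degenerate or empty; the shrinkage guarantees a well-defined stationary
distribution while preserving between-subject variation, and a row with
essentially zero expected occupancy falls back to the population row.
Expected counts (not a hard Viterbi decode) are used because they carry the
full posterior uncertainty of short sequences.

The stationary distribution solves π**A** = π, Σπ = 1 directly when the
solution is unique (rank of **A** − I equals *r* − 1); otherwise the Cesàro
average (1/K)Σₖ start·**A**ᵏ is returned, which exists for every stochastic
matrix (identity dynamics return the start vector; the 2-state flip matrix
returns (0.5, 0.5)). The start vector is the subject's posterior state
distribution at wave 1 — it only matters on the Cesàro path.

Subjects are grouped by the modal state of π (ties break toward the lower
state, the conservative direction for flagging risk); for 4-state models
the two middle stages can be reported combined. `flag_at_risk` marks
subjects whose long-run Novice probability exceeds 0.5. Cohort aggregation
reports both the mean of subject steady states and the stationary
distribution of the pooled population matrix — two defensible aggregates
that agree closely but not exactly — side by side.

## Outcome regression

Per state *k*: OLS of the outcome on πᵢₖ/0.10 and the baseline covariate
with intercept, so coefficients are "outcome points per 10-percentage-point
increase". Separate per-state models are the default because the *r*
probabilities sum to one — a joint model with intercept is rank-deficient;
a joint parameterization dropping a reference state is available
(`fit_joint_outcome_regression`). CIs are normal-theory (t-based) at 95%.
Group summaries report n, mean, sample SD (n−1) and failures below the
pass threshold (default 194).

## Missing data

Default path: chained-equations multiple imputation (scikit-learn
`IterativeImputer` with `sample_posterior=True`, Bayesian-ridge working
model) over the wave columns plus the covariate, m = 10 completed copies,
draws clipped to [0, 100], observed cells bit-identical to the input.
Only wave scores are imputed, never the covariate or outcome. The model is
then fit on each completed copy; the state count is selected on the first
copy (the grid is the expensive stage and the selection is stable across
copies); parameters are averaged after mean-ordering ("pooled model"); the
pooled model drives posteriors and steady states per copy, subject
stationary vectors are averaged across copies, and per-state regression
estimates are combined with Rubin's rules (pooled point = mean; total
variance = within + (1 + 1/m)·between; t reference with Rubin degrees of
freedom, collapsing to the within-imputation df when the between-imputation
variance vanishes). On a complete cohort the imputation stage is an exact
no-op, so the MI and non-MI pipelines produce identical bundles.

A note on imputation accuracy: a missing wave's score given the other nine
waves has an irreducible conditional spread of roughly the emission SD even
under the true model, and the best linear predictor (which is what chained
equations fit) has residual SD ≈ 8 points under the default truth. Proper
posterior draws then add that predictive noise back, so per-draw RMSE
against withheld truth is ≈ √2 × the mean-predictor RMSE by construction.
The tests assert exactly these calibration properties rather than a
tighter bound no draw-based imputer could meet.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis is designed
for: 358 subjects, 10 waves, MCAR cell missingness at 1 − 0.862^(1/10) ≈
1.48% so that ≈86.2% of sequences are complete, four states, population
transition rows (.58, .42, 0, 0), (.09, .76, .14, 0)/0.99,
(0, .19, .60, .21), (0, 0, .31, .69), covariate mean 506.2 (SD 6.2). The
initial distribution (0.50, 0.30, 0.15, 0.05) encodes that learners start
mostly in the lower stages. Emission means 38/50/62/76 with a common SD of
5 points are calibrated constructs (no published values exist): with equal
SDs the equal-density boundaries are the exact midpoints 44/56/69. Scores
are clipped to [0, 100] rather than truncated-normal sampled; with the
default parameters the boundary mass is negligible (≳7 SDs).

Each subject's outcome is intercept + **e**·πᵢ* + 0.5·(covariate − 506.2) +
N(0, 17), where πᵢ* — recorded in the truth record — is an equal-weight
blend of the population stationary distribution and the subject's realized
path occupancy. The blend induces identifiable between-subject variation in
true steady states (a pure population stationary vector would be constant
across subjects and the regression unidentifiable). The state effects
**e** = (−45, −10, 30, 65) points per unit probability and noise SD 17 are
calibrated so the marginal outcome has mean ≈230.5, SD ≈21, ≈4% failures
below 194 and a ≈40-point gap between Novice- and Competent-dominant
groups; the intercept is solved at construction from the expected steady
mixture. What the generator does **not** emulate: two distinct exam forms
with different scalings, time-varying transition kernels, informative
(non-MCAR) missingness, and discreteness/skew of real score distributions.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to those real-data departures.

## Pipeline and reproducibility

One `PipelineConfig` (YAML-loadable; CLI flags override keys) drives a run:
read → validate → (impute) → truncate to the scenario's first k waves →
grid selection → bands → per-subject posteriors → steady states → groups →
regressions → summaries. All artifacts (selection table, model JSON, bands,
per-subject steady CSV, cohort summary, regression CSV, group summaries,
tidy long trajectory table, run metadata) are written with fixed float
formatting and no timestamps, so identical configs and seeds produce
byte-identical bundles; wall-times go to the logger, not into artifacts.
The default test suite and the acceptance script run everything at the
study's own scale (N = 358, T = 10) or smaller; the heaviest check — BIC
grid selection on ten cohorts — uses 3 EM restarts per fit, which the
restart-stability of the quantile initialization makes ample.

## Known limitations

- Transition kernels are time-homogeneous; genuine curricular shocks
  (e.g. a changed test blueprint mid-sequence) would be absorbed into the
  average kernel.
- Per-subject matrices built from ≤9 transitions lean on the shrinkage
  prior; the shrinkage weight (0.5) trades bias toward the population
  matrix against variance and is not estimated from data.
- The per-state regressions are descriptive associations, not causal or
  validated prediction models.
- BIC selection among non-converged fits is undefined; rows that fail to
  converge are excluded from the minimum (and reported as such in the
  table).
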