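"""Regress the licensing-exam outcome on steady-state probabilities.

For each latent state, fits outcome ~ steady-state probability (per 10
percentage points) + baseline covariate, and prints the per-state
coefficients with 95% CIs, plus outcome summaries by trajectory group.
"""

import numpy as np

from lmtraject import em_fit, fit_state_outcome_regression, generate_cohort
from lmtraject.outcome_analysis import summarize_outcome_by_group
from lmtraject.pipeline import _subject_posteriors
from lmtraject.steady_states import compute_subject_steady_states, state_names

data, _ = generate_cohort(n_subjects=358, n_waves=10, missing_rate=0.0, seed=1)
fit = em_fit(data, r=4, seed=0)
subjects = compute_subject_steady_states(
    data.subject_ids, _subject_posteriors(data, fit.model), fit.model
)
probs = np.stack([s.stationary for s in subjects])

names = state_names(4)
for k, name in enumerate(names):
    est = fit_state_outcome_regression(data.outcome, probs, data.covariate, k,
                                       state_label=name)
    print(f"{name:>20}: {est.coefficient:+.2f} points per +10% "
          f"(95% CI {est.ci_low:+.2f} to {est.ci_high:+.2f}, p={est.p_value:.3g})")

print("\noutcome by trajectory group (modal steady state):")
groups = [s.combined_group for s in subjects]
for gs in summarize_outcome_by_group(data.outcome, data.outcome_pass_threshold,
                                     groups):
    print(f"  {gs.group:>20}: n={gs.n:3d} mean={gs.outcome_mean:.1f} "
          f"SD={gs.outcome_sd:.1f} failures={gs.n_failures}")
# A negative Novice coefficient means more long-run Novice probability
# predicts a lower exam score; Competent should carry a positive sign.
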