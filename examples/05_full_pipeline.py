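"""Run the full pipeline for both study scenarios and compare them.

Scenario 1 uses only the first six test waves (early-warning: can at-risk
subjects be spotted at the end of year one?); scenario 2 uses all ten.
Writes a report bundle per scenario and prints the headline numbers.
"""

from lmtraject import generate_cohort
from lmtraject.pipeline import PipelineConfig, run_pipeline
from lmtraject.steady_states import state_names
from lmtraject.synthetic_cohort import DEFAULT_MISSING_RATE, default_truth

data, _ = generate_cohort(default_truth(), n_subjects=358, n_waves=10,
                          missing_rate=DEFAULT_MISSING_RATE, seed=1)

for tag, k in (("six_waves", 6), ("ten_waves", None)):
    cfg = PipelineConfig(first_k_waves=k, output_dir=f"bundle_{tag}",
                         m_imputations=5, em_restarts=3, em_seed=0,
                         imputation_seed=0)
    bundle = run_pipeline(cfg, data=data.copy())
    names = state_names(bundle.model.r)
    print(f"\n=== {tag}: selected r={bundle.selection.selected_r}, "
          f"bands {bundle.bands.render()}")
    mean_pi = bundle.summary.mean_stationary
    print("mean steady state: " + ", ".join(
        f"{names[i]} {100 * mean_pi[i]:.1f}%" for i in range(len(names))))
    for est in bundle.regressions:
        print(f"  {est.state:>20}: {est.coefficient:+.2f} pts per +10% "
              f"(95% CI {est.ci_low:+.2f} to {est.ci_high:+.2f})")
# With all ten waves the cohort has had longer to improve, so more mass sits
# in the upper states than in the six-wave early-warning scenario.
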