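"""Generate a synthetic progress-testing cohort and inspect its structure.

Builds a 358-subject, 10-wave cohort from the default four-state generative
truth (latent knowledge states Novice .. Competent emitting 0-100 test
scores), writes it to CSV, and prints the completeness and outcome summary.
"""

from lmtraject import generate_cohort, validate_cohort, write_cohort
from lmtraject.synthetic_cohort import DEFAULT_MISSING_RATE, default_truth

truth = default_truth()
data, record = generate_cohort(truth, n_subjects=358, n_waves=10,
                               missing_rate=DEFAULT_MISSING_RATE, seed=1)
write_cohort(data, "cohort.csv")

report = validate_cohort(data)
print(f"subjects: {report.n_subjects}, waves: {report.n_waves}")
print(f"complete sequences: {100 * report.fraction_complete:.1f}%")
print(f"outcome mean {data.outcome.mean():.1f}, "
      f"failures below {data.outcome_pass_threshold:.0f}: "
      f"{(data.outcome < data.outcome_pass_threshold).sum()}")
print(f"true mean steady state: {record.steady_truth.mean(axis=0).round(3)}")
# The last line is the cohort-average long-run state profile the estimators
# downstream should approximately recover.
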