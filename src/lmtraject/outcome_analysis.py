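"""Outcome regression on steady-state probabilities and group summaries.

Each latent state gets its own ordinary-least-squares model: the continuous
outcome is regressed on that state's steady-state probability — rescaled to
a per-10-percentage-point unit so a coefficient reads "points of outcome
per 10% more long-run probability of the state" — controlling for the
baseline covariate, with an intercept and normal-theory 95% confidence
intervals. (A joint model over all states with an intercept would be
rank-deficient because the probabilities sum to one; a joint variant that
drops a reference state is available behind a flag.) Estimates computed on
multiply imputed datasets are combined with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CoefficientEstimate",
    "GroupSummary",
    "fit_state_outcome_regression",
    "fit_joint_outcome_regression",
    "pool_mi_estimates",
    "summarize_outcome_by_group",
]

PER_10PCT = 0.10  # probability units per reported coefficient unit


@dataclass
class CoefficientEstimate:
    """Per-state regression coefficient on the per-10-percentage-point scale."""

    state: str
    coefficient: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    covariate_coefficient: float
    n: int


@dataclass
class GroupSummary:
    group: str
    n: int
    outcome_mean: float
    outcome_sd: float
    n_failures: int
    failure_rate: float


def fit_state_outcome_regression(
    outcome,
    stationary_probs,
    covariate,
    state,
    state_label: str | None = None,
) -> CoefficientEstimate:
    """OLS of outcome on one state's steady probability (per 10%) + covariate.

    ``state`` indexes a column of the (N, r) ``stationary_probs`` matrix.
    Raises a degeneracy error when the chosen state's probabilities are
    constant across subjects.
    """
    y = np.asarray(outcome, dtype=float)
    probs = np.asarray(stationary_probs, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = y.size
    if n <= 3:
        raise ValueError("need more than 3 subjects")
    p_state = probs[:, state]
    if np.ptp(p_state) < 1e-12:
        raise ValueError(f"state {state} probabilities are constant; cannot regress")

    x = sm.add_constant(np.column_stack([p_state / PER_10PCT, cov]))
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int(alpha=0.05)
    return CoefficientEstimate(
        state=state_label if state_label is not None else str(state),
        coefficient=float(fit.params[1]),
        se=float(fit.bse[1]),
        df=float(fit.df_resid),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(fit.pvalues[1]),
        covariate_coefficient=float(fit.params[2]),
        n=n,
    )


def fit_joint_outcome_regression(outcome, stationary_probs, covariate,
                                 reference_state: int = 0) -> pd.DataFrame:
    """Joint OLS on all states but one (the reference), plus covariate.

    Coefficients are contrasts against the reference state, per 10
    percentage points. Provided as the alternative parameterization; the
    per-state models are the default reporting route.
    """
    y = np.asarray(outcome, dtype=float)
    probs = np.asarray(stationary_probs, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    r = probs.shape[1]
    keep = [k for k in range(r) if k != reference_state]
    x = sm.add_constant(np.column_stack([probs[:, keep] / PER_10PCT, cov]))
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for pos, k in enumerate(keep, start=1):
        rows.append(
            {"state": k, "coefficient": float(fit.params[pos]),
             "ci_low": float(ci[pos][0]), "ci_high": float(ci[pos][1]),
             "p_value": float(fit.pvalues[pos])}
        )
    return pd.DataFrame(rows)


def pool_mi_estimates(estimates: Sequence[CoefficientEstimate]) -> CoefficientEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    Pooled point = mean of points; total variance = mean within-imputation
    variance + (1 + 1/m) x between-imputation variance; the 95% CI uses a t
    reference with Rubin's degrees of freedom. With one imputation, or zero
    between-imputation spread, the input inference is returned unchanged
    apart from the averaged point estimate.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    if len({e.state for e in estimates}) != 1:
        raise ValueError("cannot pool estimates for different states")
    m = len(estimates)
    if m == 1:
        return estimates[0]
    points = np.array([e.coefficient for e in estimates])
    within = float(np.mean([e.se**2 for e in estimates]))
    between = float(np.var(points, ddof=1))
    qbar = float(points.mean())
    total = within + (1.0 + 1.0 / m) * between
    se = np.sqrt(total)
    if between < 1e-14 * max(within, 1.0):
        df = float(np.mean([e.df for e in estimates]))
    else:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
    tcrit = stats.t.ppf(0.975, df) if df > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(qbar) / se, df) if se > 0 else (0.0 if qbar else 1.0)
    return CoefficientEstimate(
        state=estimates[0].state,
        coefficient=qbar,
        se=float(se),
        df=float(df),
        ci_low=float(qbar - tcrit * se),
        ci_high=float(qbar + tcrit * se),
        p_value=float(p),
        covariate_coefficient=float(np.mean([e.covariate_coefficient for e in estimates])),
        n=estimates[0].n,
    )


def summarize_outcome_by_group(outcome, pass_threshold, groups) -> list:
    """Per-group n, mean, sample SD and failure counts below the threshold.

    Empty groups never arise from label vectors; a group with a single
    member gets an undefined (NaN) SD. Groups are returned in first-seen
    order of the label vector.
    """
    y = np.asarray(outcome, dtype=float)
    groups = np.asarray(groups)
    if y.size != groups.size:
        raise ValueError("outcome and groups lengths differ")
    out = []
    seen = list(dict.fromkeys(groups.tolist()))
    for g in seen:
        sel = y[groups == g]
        n = sel.size
        fails = int((sel < pass_threshold).sum())
        out.append(
            GroupSummary(
                group=str(g),
                n=n,
                outcome_mean=float(sel.mean()) if n else float("nan"),
                outcome_sd=float(sel.std(ddof=1)) if n > 1 else float("nan"),
                n_failures=fails,
                failure_rate=fails / n if n else float("nan"),
            )
        )
    return out


def estimates_to_frame(estimates: Sequence[CoefficientEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"state": e.state, "coefficient_per_10pct": e.coefficient,
             "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
             "p_value": e.p_value, "covariate_coefficient": e.covariate_coefficient,
             "n": e.n}
            for e in estimates
        ]
    )


def group_summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": s.group, "n": s.n, "outcome_mean": s.outcome_mean,
             "outcome_sd": s.outcome_sd, "n_failures": s.n_failures,
             "failure_rate": s.failure_rate}
            for s in summaries
        ]
    )
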