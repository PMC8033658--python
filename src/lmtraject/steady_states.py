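"""Per-subject transition matrices, stationary distributions and groups.

A subject's long-run ("steady-state") profile is the stationary
distribution of a subject-specific transition matrix built from posterior
expected transition counts, shrunk toward the population matrix. Subjects
are grouped by the modal state of their stationary vector using the
knowledge-stage names Novice, Advanced Beginner I/II and Competent (for a
four-state model), with the two middle stages optionally combined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .latent_markov import LatentModel, SubjectPosterior

STATE_NAMES_4 = ["Novice", "AdvancedBeginnerI", "AdvancedBeginnerII", "Competent"]
COMBINED_MIDDLE_4 = "AdvancedBeginnerI&II"

__all__ = [
    "SubjectSteadyState",
    "CohortSteadySummary",
    "state_names",
    "subject_transition_matrix",
    "stationary_distribution",
    "assign_group",
    "cohort_steady_summary",
    "compute_subject_steady_states",
]


def state_names(r: int) -> list:
    """Dreyfus-style stage names for r=4, generic ``State k`` otherwise."""
    if r == 4:
        return list(STATE_NAMES_4)
    return [f"State{k + 1}" for k in range(r)]


def _combined_names(r: int) -> list:
    if r == 4:
        return [STATE_NAMES_4[0], COMBINED_MIDDLE_4, STATE_NAMES_4[3]]
    return state_names(r)


@dataclass
class SubjectSteadyState:
    subject_id: str
    subject_transition: np.ndarray
    stationary: np.ndarray
    group: str
    combined_group: str
    flag_at_risk: bool


@dataclass
class CohortSteadySummary:
    mean_stationary: np.ndarray
    group_counts: dict
    combined_group_counts: dict
    n_subjects: int


def _check_row_stochastic(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if (m < -atol).any() or (np.abs(m.sum(axis=1) - 1.0) > atol).any():
        raise ValueError("matrix must be row-stochastic")
    return m


def subject_transition_matrix(
    posterior: SubjectPosterior,
    population: LatentModel,
    shrinkage: float = 0.5,
) -> np.ndarray:
    """Subject transition matrix from posterior expected transition counts.

    Row i is the normalized sum of the subject's expected transitions out of
    state i across waves, plus ``shrinkage`` pseudo-transitions distributed
    as the population row. A row with essentially no expected occupancy
    falls back to the population row, so the result is always
    row-stochastic even for short sequences.
    """
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    if posterior.xi.shape[0] < 1:
        raise ValueError("posterior must cover at least 2 waves")
    counts = posterior.xi.sum(axis=0) + shrinkage * population.transition
    totals = counts.sum(axis=1)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        if totals[i] < 1e-12:
            out[i] = population.transition[i]
        else:
            out[i] = counts[i] / totals[i]
    return out


def stationary_distribution(matrix: np.ndarray, start=None) -> np.ndarray:
    """Limiting occupancy distribution of a row-stochastic matrix.

    When pi = pi @ P with sum(pi) = 1 has a unique solution (rank of P - I
    equals r - 1) it is found by a direct linear solve. Otherwise — for
    reducible chains such as the identity — the Cesaro average
    (1/K) * sum_k start @ P^k is returned, which always exists; ``start``
    defaults to uniform.
    """
    p = _check_row_stochastic(matrix)
    r = p.shape[0]
    if start is None:
        start = np.full(r, 1.0 / r)
    start = np.asarray(start, dtype=float)
    if start.shape != (r,) or abs(start.sum() - 1.0) > 1e-8 or (start < -1e-12).any():
        raise ValueError("start must be a length-r probability simplex")

    if np.linalg.matrix_rank(p - np.eye(r)) == r - 1:
        a = np.vstack([p.T - np.eye(r), np.ones(r)])
        b = np.zeros(r + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        if (pi > -1e-9).all():
            pi = np.clip(pi, 0.0, None)
            pi /= pi.sum()
            if np.max(np.abs(pi @ p - pi)) < 1e-8:
                return pi

    # Cesaro fallback: running average of start @ P^k
    v = start.copy()
    avg = start.copy()
    for k in range(1, 100_000):
        v = v @ p
        new_avg = avg + (v - avg) / (k + 1)
        if np.max(np.abs(new_avg - avg)) < 1e-10:
            avg = new_avg
            break
        avg = new_avg
    return avg / avg.sum()


def assign_group(stationary: np.ndarray, risk_threshold: float = 0.5):
    """Modal-state group label, combined label, and at-risk flag.

    Group = argmax state of the stationary vector (ties break to the lower
    state, the conservative choice); the combined label merges the two
    middle states of a four-state model; ``flag_at_risk`` is True when the
    probability of the lowest (Novice) state exceeds ``risk_threshold``.
    """
    pi = np.asarray(stationary, dtype=float)
    r = pi.size
    k = int(np.argmax(pi))  # argmax takes the first (lowest) index on ties
    names = state_names(r)
    group = names[k]
    if r == 4 and k in (1, 2):
        combined = COMBINED_MIDDLE_4
    else:
        combined = group
    return group, combined, bool(pi[0] > risk_threshold)


def compute_subject_steady_states(
    subject_ids: Sequence[str],
    posteriors: Sequence[SubjectPosterior],
    population: LatentModel,
    shrinkage: float = 0.5,
    risk_threshold: float = 0.5,
) -> list:
    """Full per-subject pipeline: transition matrix -> stationary -> group.

    The stationary solve's fallback start vector is the subject's posterior
    state distribution at the first wave (only consulted for reducible or
    periodic subject chains).
    """
    out = []
    for sid, post in zip(subject_ids, posteriors):
        a = subject_transition_matrix(post, population, shrinkage=shrinkage)
        pi = stationary_distribution(a, start=post.gamma[0])
        group, combined, risk = assign_group(pi, risk_threshold=risk_threshold)
        out.append(
            SubjectSteadyState(
                subject_id=sid, subject_transition=a, stationary=pi,
                group=group, combined_group=combined, flag_at_risk=risk,
            )
        )
    return out


def cohort_steady_summary(subjects: Sequence[SubjectSteadyState]) -> CohortSteadySummary:
    """Average stationary vector and group membership counts."""
    if not subjects:
        raise ValueError("empty subject list")
    r = subjects[0].stationary.size
    if any(s.stationary.size != r for s in subjects):
        raise ValueError("subjects must share the same state count")
    mean = np.mean([s.stationary for s in subjects], axis=0)
    mean = mean / mean.sum()
    group_counts = {name: 0 for name in state_names(r)}
    combined_counts = {name: 0 for name in _combined_names(r)}
    for s in subjects:
        group_counts[s.group] += 1
        combined_counts[s.combined_group] += 1
    return CohortSteadySummary(
        mean_stationary=mean,
        group_counts=group_counts,
        combined_group_counts=combined_counts,
        n_subjects=len(subjects),
    )


def steady_states_to_frame(subjects: Sequence[SubjectSteadyState]) -> pd.DataFrame:
    r = subjects[0].stationary.size
    names = state_names(r)
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update({f"p_{name}": s.stationary[k] for k, name in enumerate(names)})
        row.update(
            {"group": s.group, "combined_group": s.combined_group,
             "flag_at_risk": s.flag_at_risk}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def transition_edges_json(matrix: np.ndarray, r: int, path, min_prob: float = 0.0) -> None:
    """Export a transition matrix as a JSON edge list (from, to, probability)."""
    names = state_names(r)
    edges = [
        {"from": names[i], "to": names[j], "probability": float(matrix[i, j])}
        for i in range(r)
        for j in range(r)
        if matrix[i, j] > min_prob
    ]
    with open(path, "w") as fh:
        json.dump(edges, fh, indent=2)
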