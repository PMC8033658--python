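"""Cohort data model, CSV I/O, validation and multiple imputation.

A cohort is a rectangular panel: one row per subject, an ordered set of
repeated test-score waves on a bounded 0-100 scale (missing allowed), a
baseline admission covariate and a continuous licensing-exam outcome with a
pass threshold. Missing wave scores are handled by chained-equations
multiple imputation with posterior draws, producing ``m`` completed copies
of the cohort that agree with the source on every observed cell.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

DEFAULT_PASS_THRESHOLD = 194.0

__all__ = [
    "CohortDataset",
    "ValidationReport",
    "ImputedSet",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "impute_missing",
]


class SchemaError(ValueError):
    """A required column is absent or the schema mapping is malformed."""


class CohortValidationError(ValueError):
    """Observed data violate the cohort invariants (e.g. score out of range)."""


@dataclass
class CohortDataset:
    """Subjects x waves score panel with covariate and outcome.

    Parameters
    ----------
    subject_ids : list of str
        Unique subject identifiers, one per row of ``scores``.
    scores : (N, T) float array
        Test scores on the 0-100 scale; ``np.nan`` marks a missing wave.
    wave_labels : list of str
        Ordered (chronological) wave names, length T.
    covariate : (N,) float array
        Baseline admission score (MCAT-like), in points.
    outcome : (N,) float array
        Licensing-exam score (Step-1-like), in points.
    outcome_pass_threshold : float
        Minimum passing outcome score, in points.
    """

    subject_ids: list
    scores: np.ndarray
    wave_labels: list
    covariate: np.ndarray
    outcome: np.ndarray
    outcome_pass_threshold: float = DEFAULT_PASS_THRESHOLD

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.wave_labels = list(self.wave_labels)
        n, t = self.scores.shape
        if t < 2:
            raise CohortValidationError("a cohort needs at least two waves")
        if len(self.subject_ids) != n:
            raise CohortValidationError("subject_ids length does not match scores")
        if len(set(self.subject_ids)) != n:
            raise CohortValidationError("subject_ids must be unique")
        if len(self.wave_labels) != t:
            raise CohortValidationError("wave_labels length does not match scores")
        if self.covariate.shape != (n,) or self.outcome.shape != (n,):
            raise CohortValidationError("covariate/outcome lengths must equal N")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_waves(self) -> int:
        return self.scores.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean (N, T) array, True where the score is observed."""
        return ~np.isnan(self.scores)

    @property
    def n_observed(self) -> int:
        """Total count of non-missing score cells."""
        return int(self.mask.sum())

    def copy(self) -> "CohortDataset":
        return copy.deepcopy(self)

    def is_complete(self) -> bool:
        return bool(self.mask.all())


@dataclass
class ValidationReport:
    n_subjects: int
    n_waves: int
    fraction_complete: float
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class ImputedSet:
    """``m`` completed copies of a cohort, identical at observed cells."""

    completed: list
    m: int
    seed: int
    method_label: str = "chained-equations regression (posterior draws)"


def _default_schema(columns: Sequence[str]) -> dict:
    waves = [c for c in columns if c.startswith("wave_")]
    return {
        "subject_id": "subject_id",
        "waves": waves,
        "covariate": "covariate",
        "outcome": "outcome",
    }


def read_cohort(
    path,
    schema: Mapping | None = None,
    pass_threshold: float = DEFAULT_PASS_THRESHOLD,
) -> CohortDataset:
    """Read a cohort CSV (one row per subject) into a :class:`CohortDataset`.

    ``schema`` maps logical names to column names: keys ``subject_id``,
    ``covariate``, ``outcome`` and ``waves`` (an ordered list of wave
    columns). Without a schema, columns named ``wave_*`` are taken as waves
    in file order — chronology is essential to the Markov structure.
    Empty cells in wave columns are read as missing. Raises
    :class:`SchemaError` for absent columns and
    :class:`CohortValidationError` for scores outside [0, 100].
    """
    df = pd.read_csv(path)
    sch = dict(schema) if schema is not None else _default_schema(df.columns)
    required = ["subject_id", "covariate", "outcome", "waves"]
    for key in required:
        if key not in sch:
            raise SchemaError(f"schema is missing the {key!r} entry")
    cols = [sch["subject_id"], sch["covariate"], sch["outcome"], *sch["waves"]]
    absent = [c for c in cols if c not in df.columns]
    if absent:
        raise SchemaError(f"missing required column(s): {absent}")
    if not sch["waves"]:
        raise SchemaError("schema lists no wave columns")

    scores = df[sch["waves"]].to_numpy(dtype=float)
    data = CohortDataset(
        subject_ids=[str(s) for s in df[sch["subject_id"]]],
        scores=scores,
        wave_labels=list(sch["waves"]),
        covariate=df[sch["covariate"]].to_numpy(dtype=float),
        outcome=df[sch["outcome"]].to_numpy(dtype=float),
        outcome_pass_threshold=pass_threshold,
    )
    report = validate_cohort(data)
    bad = [v for v in report.violations if v[1] == "score"]
    if bad:
        raise CohortValidationError(f"score(s) outside [0, 100]: {bad}")
    return data


def write_cohort(data: CohortDataset, path) -> None:
    """Write a cohort to CSV in the dialect :func:`read_cohort` accepts."""
    df = pd.DataFrame({"subject_id": data.subject_ids})
    for j, w in enumerate(data.wave_labels):
        df[w] = data.scores[:, j]
    df["covariate"] = data.covariate
    df["outcome"] = data.outcome
    df.to_csv(path, index=False, float_format="%.10g")


def validate_cohort(data: CohortDataset) -> ValidationReport:
    """Report cohort shape, completeness and invariant violations.

    Violations are reported, never raised; ``fraction_complete`` is the
    share of subjects with no missing waves.
    """
    violations = []
    mask = data.mask
    obs = data.scores[mask]
    if obs.size and ((obs < 0) | (obs > 100)).any():
        rows, cols = np.nonzero(mask & ((data.scores < 0) | (data.scores > 100)))
        for i, j in zip(rows, cols):
            violations.append(
                (data.subject_ids[i], "score",
                 f"wave {data.wave_labels[j]}: {data.scores[i, j]} outside [0, 100]")
            )
    for i in np.nonzero(~mask.any(axis=1))[0]:
        violations.append((data.subject_ids[i], "scores", "no observed waves"))
    frac = float(mask.all(axis=1).mean())
    return ValidationReport(
        n_subjects=data.n_subjects,
        n_waves=data.n_waves,
        fraction_complete=frac,
        violations=violations,
    )


def impute_missing(data: CohortDataset, m: int = 10, seed: int = 0) -> ImputedSet:
    """Multiply impute missing wave scores.

    Chained-equations regression imputation: each missing wave is predicted
    from the subject's other waves plus the covariate, with draws from the
    normal posterior predictive (Bayesian ridge working model), so the ``m``
    completed copies differ at imputed cells. Draws are clipped to the
    [0, 100] score scale; observed cells are bit-identical to the input;
    the result is deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    empty = np.nonzero(~data.mask.any(axis=1))[0]
    if empty.size:
        ids = [data.subject_ids[i] for i in empty]
        raise CohortValidationError(f"subject(s) with zero observed waves: {ids}")

    if data.is_complete():
        return ImputedSet(
            completed=[data.copy() for _ in range(m)], m=m, seed=seed,
            method_label="no missing data (identity)",
        )

    design = np.column_stack([data.scores, data.covariate])
    completed = []
    for j in range(m):
        imputer = IterativeImputer(
            sample_posterior=True,
            random_state=(seed + j) % (2**31 - 1),
            max_iter=10,
            keep_empty_features=True,
        )
        filled = imputer.fit_transform(design)[:, : data.n_waves]
        filled = np.clip(filled, 0.0, 100.0)
        filled[data.mask] = data.scores[data.mask]  # observed cells untouched
        out = data.copy()
        out.scores = filled
        completed.append(out)
    return ImputedSet(completed=completed, m=m, seed=seed)


def write_imputed_set(imputed: ImputedSet, out_dir) -> None:
    """Serialize an :class:`ImputedSet` as m CSVs plus an index JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for j, ds in enumerate(imputed.completed, start=1):
        write_cohort(ds, out_dir / f"imputed_{j:02d}.csv")
    index = {"m": imputed.m, "seed": imputed.seed, "method_label": imputed.method_label}
    (out_dir / "index.json").write_text(json.dumps(index, indent=2))
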