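"""End-to-end orchestration: read -> validate -> impute -> fit -> steady -> regress.

A single :class:`PipelineConfig` (loadable from YAML) drives the whole
analysis of one scenario — either the first k test waves (early-warning
scenario) or all waves — and a :func:`run_pipeline` call produces a
:class:`ReportBundle` of artifacts: the state-count selection table, the
fitted (or MI-pooled) model with its score bands, per-subject steady-state
probabilities with group labels, cohort-level summaries, outcome
regressions and group outcome summaries. Runs are deterministic given the
config seeds; rerunning an identical config writes byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    CohortDataset,
    impute_missing,
    read_cohort,
    validate_cohort,
)
from .latent_markov import (
    FitResult,
    LatentModel,
    ModelSelectionTable,
    _batch_forward_backward,
    derive_state_bands,
    em_fit,
    pool_models,
    select_states,
)
from .outcome_analysis import (
    estimates_to_frame,
    fit_state_outcome_regression,
    group_summaries_to_frame,
    pool_mi_estimates,
    summarize_outcome_by_group,
)
from .steady_states import (
    SubjectPosterior,
    assign_group,
    cohort_steady_summary,
    compute_subject_steady_states,
    state_names,
    stationary_distribution,
    steady_states_to_frame,
    transition_edges_json,
)

logger = logging.getLogger("lmtraject")

__all__ = ["PipelineConfig", "ReportBundle", "scenario_split", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One serializable source of truth for a pipeline run."""

    input_path: str | None = None
    output_dir: str | None = None
    schema: dict | None = None
    first_k_waves: int | None = None  # None = all waves
    imputation_enabled: bool = True
    m_imputations: int = 10
    imputation_seed: int = 0
    native_missing: bool = False  # skip MI; marginalize missing emissions
    r_min: int = 3
    r_max: int = 6
    criterion: str = "bic"
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_restarts: int = 5
    em_seed: int = 0
    shrinkage: float = 0.5
    risk_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReportBundle:
    config: PipelineConfig
    validation: object
    selection: ModelSelectionTable
    model: LatentModel
    fit: FitResult
    bands: object
    subjects: list
    summary: object
    population_stationary: np.ndarray
    regressions: list
    group_summaries: list
    combined_group_summaries: list
    artifact_paths: dict = field(default_factory=dict)


def scenario_split(data: CohortDataset, first_k_waves: int) -> CohortDataset:
    """Keep only the first k waves; covariate and outcome are unchanged."""
    if not (2 <= first_k_waves <= data.n_waves):
        raise ValueError(
            f"first_k_waves must be in [2, {data.n_waves}], got {first_k_waves}"
        )
    out = data.copy()
    out.scores = out.scores[:, :first_k_waves]
    out.wave_labels = out.wave_labels[:first_k_waves]
    return out


def _subject_posteriors(data: CohortDataset, model: LatentModel) -> list:
    ll, gamma, xi = _batch_forward_backward(data.scores, model)
    return [
        SubjectPosterior(loglik=float(ll[i]), gamma=gamma[i], xi=xi[i])
        for i in range(data.n_subjects)
    ]


def run_pipeline(config: PipelineConfig, data: CohortDataset | None = None) -> ReportBundle:
    """Execute every stage of the scenario described by ``config``.

    ``data`` may be passed directly (e.g. a freshly generated synthetic
    cohort); otherwise ``config.input_path`` is read. Artifacts are written
    under ``config.output_dir`` when set.
    """
    t0 = time.perf_counter()
    if data is None:
        if config.input_path is None:
            raise ValueError("config.input_path required when no dataset is passed")
        data = read_cohort(config.input_path, schema=config.schema)

    report = validate_cohort(data)
    if any(v[1] == "score" for v in report.violations):
        raise ValueError(f"stage=validate: invalid scores: {report.violations}")
    logger.info("validate: N=%d T=%d complete=%.3f", report.n_subjects,
                report.n_waves, report.fraction_complete)

    if config.first_k_waves is not None:
        data = scenario_split(data, config.first_k_waves)

    em_opts = dict(tol=config.em_tol, max_iter=config.em_max_iter,
                   n_restarts=config.em_restarts, seed=config.em_seed)

    if data.is_complete() or config.native_missing or not config.imputation_enabled:
        datasets = [data]
        mi = False
    else:
        imputed = impute_missing(data, m=config.m_imputations,
                                 seed=config.imputation_seed)
        datasets = imputed.completed
        mi = True
    logger.info("imputation: %s (%d dataset(s))", "on" if mi else "off", len(datasets))

    selection = select_states(datasets[0], r_min=config.r_min, r_max=config.r_max,
                              criterion=config.criterion, **em_opts)
    r = selection.selected_r
    fit = selection.selected_fit
    if mi:
        models = [fit.model] + [
            em_fit(ds, r, **em_opts).model for ds in datasets[1:]
        ]
        model = pool_models(models)
    else:
        model = fit.model
    bands = derive_state_bands(model)
    logger.info("selected r=%d bands=%s", r, bands.render())

    # per-subject steady states, averaged over imputed datasets
    per_ds_subjects = []
    for ds in datasets:
        posts = _subject_posteriors(ds, model)
        per_ds_subjects.append(
            compute_subject_steady_states(
                ds.subject_ids, posts, model,
                shrinkage=config.shrinkage, risk_threshold=config.risk_threshold,
            )
        )
    subjects = per_ds_subjects[0]
    if mi:
        for i, subj in enumerate(subjects):
            pi = np.mean([dss[i].stationary for dss in per_ds_subjects], axis=0)
            pi /= pi.sum()
            group, combined, risk = assign_group(pi, config.risk_threshold)
            subj.stationary = pi
            subj.group, subj.combined_group, subj.flag_at_risk = group, combined, risk
    summary = cohort_steady_summary(subjects)
    pop_pi = stationary_distribution(model.transition)

    # per-state regressions; Rubin pooling across imputed datasets
    names = state_names(r)
    regressions = []
    for k in range(r):
        per_ds = []
        for dss in per_ds_subjects:
            probs = np.stack([s.stationary for s in dss])
            per_ds.append(
                fit_state_outcome_regression(
                    data.outcome, probs, data.covariate, k, state_label=names[k]
                )
            )
        regressions.append(pool_mi_estimates(per_ds))

    groups = np.array([s.group for s in subjects])
    combined = np.array([s.combined_group for s in subjects])
    group_summaries = summarize_outcome_by_group(
        data.outcome, data.outcome_pass_threshold, groups
    )
    combined_summaries = summarize_outcome_by_group(
        data.outcome, data.outcome_pass_threshold, combined
    )

    bundle = ReportBundle(
        config=config, validation=report, selection=selection, model=model,
        fit=fit, bands=bands, subjects=subjects, summary=summary,
        population_stationary=pop_pi, regressions=regressions,
        group_summaries=group_summaries, combined_group_summaries=combined_summaries,
    )
    if config.output_dir is not None:
        _write_bundle(bundle, data)
    logger.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return bundle


def _write_bundle(bundle: ReportBundle, data: CohortDataset) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save_csv(name, frame):
        p = out / name
        frame.to_csv(p, index=False, float_format="%.10g")
        paths[name] = str(p)

    bundle.selection.to_csv(out / "selection_table.csv")
    paths["selection_table.csv"] = str(out / "selection_table.csv")
    bundle.model.to_json(out / "model.json")
    paths["model.json"] = str(out / "model.json")

    with open(out / "state_bands.json", "w") as fh:
        json.dump(
            {"boundaries": bundle.bands.boundaries.tolist(),
             "rounded": bundle.bands.rounded, "text": bundle.bands.render()},
            fh, indent=2,
        )
    paths["state_bands.json"] = str(out / "state_bands.json")

    save_csv("subject_steady.csv", steady_states_to_frame(bundle.subjects))
    save_csv("regression.csv", estimates_to_frame(bundle.regressions))
    save_csv("group_summaries.csv", group_summaries_to_frame(bundle.group_summaries))
    save_csv("combined_group_summaries.csv",
             group_summaries_to_frame(bundle.combined_group_summaries))

    names = state_names(bundle.model.r)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(
            {
                "n_subjects": bundle.summary.n_subjects,
                "mean_subject_stationary": {
                    names[k]: bundle.summary.mean_stationary[k]
                    for k in range(bundle.model.r)
                },
                "population_matrix_stationary": {
                    names[k]: bundle.population_stationary[k]
                    for k in range(bundle.model.r)
                },
                "group_counts": bundle.summary.group_counts,
                "combined_group_counts": bundle.summary.combined_group_counts,
            },
            fh, indent=2,
        )
    paths["cohort_summary.json"] = str(out / "cohort_summary.json")

    transition_edges_json(bundle.model.transition, bundle.model.r,
                          out / "transition_edges.json")
    paths["transition_edges.json"] = str(out / "transition_edges.json")

    # tidy long trajectories with group labels, for external plotting
    rows = []
    group_of = {s.subject_id: (s.group, s.combined_group) for s in bundle.subjects}
    for i, sid in enumerate(data.subject_ids):
        for j, w in enumerate(data.wave_labels):
            rows.append(
                {"subject_id": sid, "wave": w, "score": data.scores[i, j],
                 "group": group_of[sid][0], "combined_group": group_of[sid][1]}
            )
    save_csv("trajectories_long.csv", pd.DataFrame(rows))

    with open(out / "run.json", "w") as fh:
        json.dump(
            {
                "package_version": __version__,
                "config": bundle.config.to_dict(),
                "seeds": {"em_seed": bundle.config.em_seed,
                          "imputation_seed": bundle.config.imputation_seed},
                "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            },
            fh, indent=2,
        )
    paths["run.json"] = str(out / "run.json")
    bundle.artifact_paths = paths
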