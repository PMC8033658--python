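"""Gaussian-emission latent Markov (hidden Markov) model estimation.

The observation model: each subject occupies one of ``r`` unobserved
knowledge states per wave; states evolve as a first-order, time-homogeneous
Markov chain with initial distribution ``initial`` and row-stochastic
``transition`` matrix; an occupied state ``k`` emits a test score drawn from
``Normal(emission_means[k], emission_sds[k])``. Missing waves contribute
likelihood one (marginalized emission). Maximum-likelihood estimation is by
Baum-Welch EM with a scaled forward-backward E-step; the number of states is
chosen by an AIC/BIC grid search; per-state score bands come from the
equal-density boundaries of adjacent emission Gaussians.

Label switching is resolved everywhere by ordering states by ascending
emission mean, so state 0 is always the lowest-scoring ("Novice") state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortDataset

_LOG_2PI = math.log(2.0 * math.pi)
SD_FLOOR = 0.5  # points; prevents degenerate zero-variance spikes

__all__ = [
    "LatentModel",
    "SubjectPosterior",
    "FitResult",
    "ModelSelectionTable",
    "StateBands",
    "state_log_density",
    "forward_backward",
    "em_fit",
    "count_free_parameters",
    "information_criteria",
    "select_states",
    "derive_state_bands",
    "pool_models",
]


class DegenerateDataError(ValueError):
    """The data cannot support the requested number of states."""


class SelectionError(RuntimeError):
    """No converged fit available to select a state count from."""


@dataclass
class LatentModel:
    """Parameters of an r-state Gaussian-emission latent Markov model."""

    r: int
    initial: np.ndarray
    transition: np.ndarray
    emission_means: np.ndarray
    emission_sds: np.ndarray

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.emission_sds = np.asarray(self.emission_sds, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-10) -> None:
        r = self.r
        if self.initial.shape != (r,) or self.transition.shape != (r, r):
            raise ValueError("initial/transition shapes inconsistent with r")
        if self.emission_means.shape != (r,) or self.emission_sds.shape != (r,):
            raise ValueError("emission parameter shapes inconsistent with r")
        if abs(self.initial.sum() - 1.0) > atol or (self.initial < -atol).any():
            raise ValueError("initial must be a probability simplex")
        if (np.abs(self.transition.sum(axis=1) - 1.0) > atol).any() or (
            self.transition < -atol
        ).any():
            raise ValueError("transition must be row-stochastic")
        if (self.emission_sds <= 0).any():
            raise ValueError("emission SDs must be positive")

    def sorted_by_mean(self) -> "LatentModel":
        """Return the mean-ascending relabeling of this model."""
        order = np.argsort(self.emission_means, kind="stable")
        return LatentModel(
            r=self.r,
            initial=self.initial[order],
            transition=self.transition[np.ix_(order, order)],
            emission_means=self.emission_means[order],
            emission_sds=self.emission_sds[order],
        )

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "emission_means": self.emission_means.tolist(),
            "emission_sds": self.emission_sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentModel":
        return cls(
            r=int(d["r"]),
            initial=d["initial"],
            transition=d["transition"],
            emission_means=d["emission_means"],
            emission_sds=d["emission_sds"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LatentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SubjectPosterior:
    """Forward-backward output for one subject's sequence."""

    loglik: float
    gamma: np.ndarray  # (T, r) posterior state probabilities
    xi: np.ndarray  # (T-1, r, r) posterior transition probabilities


@dataclass
class FitResult:
    model: LatentModel
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    n_restarts_used: int
    loglik_path: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_restarts_used": self.n_restarts_used,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class StateBands:
    """Half-open score intervals induced by adjacent-density boundaries.

    ``boundaries`` holds the exact (unrounded) equal-density crossing points;
    rounding to integer cutoffs happens only at rendering time.
    """

    boundaries: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if (np.diff(self.boundaries) <= 0).any():
            raise ValueError("band boundaries must be strictly increasing")

    @property
    def rounded(self) -> list:
        return [int(round(b)) for b in self.boundaries]

    @property
    def bands(self) -> list:
        """List of (low, high, closed_low) interval tuples partitioning [0, 100]."""
        edges = [0] + self.rounded + [100]
        out = []
        for k in range(len(edges) - 1):
            out.append((edges[k], edges[k + 1], k == 0))
        return out

    def render(self) -> str:
        """Interval text like ``[0, 44], (44, 56], (56, 69], (69, 100]``."""
        parts = []
        for low, high, closed_low in self.bands:
            bracket = "[" if closed_low else "("
            parts.append(f"{bracket}{low}, {high}]")
        return ", ".join(parts)


@dataclass
class ModelSelectionTable:
    rows: list  # dicts with r, bands, aic, bic, converged
    selected_r: int
    criterion: str
    fits: dict = field(default_factory=dict, repr=False)  # r -> FitResult

    @property
    def selected_fit(self) -> FitResult:
        return self.fits[self.selected_r]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# densities and forward-backward

def state_log_density(score: float, model: LatentModel) -> np.ndarray:
    """Per-state Gaussian log density of one score; zeros if score missing."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return np.zeros(model.r)
    z = (score - model.emission_means) / model.emission_sds
    return -0.5 * z * z - np.log(model.emission_sds) - 0.5 * _LOG_2PI


def _log_emission_matrix(scores: np.ndarray, model: LatentModel) -> np.ndarray:
    """(N, T, r) log emission matrix; missing cells get log 1 = 0."""
    obs = ~np.isnan(scores)
    logb = np.zeros(scores.shape + (model.r,))
    y = scores[obs][:, None]
    z = (y - model.emission_means[None, :]) / model.emission_sds[None, :]
    logb[obs] = -0.5 * z * z - np.log(model.emission_sds)[None, :] - 0.5 * _LOG_2PI
    return logb


def _batch_forward_backward(scores: np.ndarray, model: LatentModel):
    """Scaled forward-backward over an (N, T) score matrix (NaN = missing).

    Returns (logliks (N,), gamma (N,T,r), xi (N,T-1,r,r)). Per-step scaling
    plus a per-cell max-shift of the emission matrix keeps everything finite
    for sequences up to at least T = 1e4.
    """
    n, t = scores.shape
    r = model.r
    logb = _log_emission_matrix(scores, model)
    shift = logb.max(axis=2)
    b = np.exp(logb - shift[..., None])  # in (0, 1], max per cell = 1

    p = model.transition
    alpha = np.empty((n, t, r))
    c = np.empty((n, t))
    a0 = model.initial[None, :] * b[:, 0]
    c[:, 0] = a0.sum(axis=1)
    alpha[:, 0] = a0 / c[:, 0, None]
    for s in range(1, t):
        a = (alpha[:, s - 1] @ p) * b[:, s]
        c[:, s] = a.sum(axis=1)
        alpha[:, s] = a / c[:, s, None]
    logliks = np.log(c).sum(axis=1) + shift.sum(axis=1)

    beta = np.empty((n, t, r))
    beta[:, t - 1] = 1.0
    for s in range(t - 2, -1, -1):
        beta[:, s] = ((b[:, s + 1] * beta[:, s + 1]) @ p.T) / c[:, s + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    xi = np.empty((n, t - 1, r, r))
    for s in range(t - 1):
        sl = (
            alpha[:, s, :, None]
            * p[None, :, :]
            * (b[:, s + 1] * beta[:, s + 1])[:, None, :]
        )
        xi[:, s] = sl / sl.sum(axis=(1, 2))[:, None, None]
    return logliks, gamma, xi


def forward_backward(sequence, model: LatentModel, mask=None) -> SubjectPosterior:
    """Exact posteriors and log-likelihood for one score sequence.

    ``sequence`` may contain NaN for missing waves (or pass an explicit
    observed-``mask``). For T = 1 the chain degenerates to a mixture over
    the initial distribution.
    """
    y = np.asarray(sequence, dtype=float).copy()
    if mask is not None:
        y[~np.asarray(mask, dtype=bool)] = np.nan
    if np.isinf(y).any():
        raise ValueError("scores must be finite or missing (NaN)")
    if y.ndim != 1 or y.size < 1:
        raise ValueError("sequence must be a 1-D array with T >= 1")
    if y.size == 1:
        logb = state_log_density(float(y[0]), model)
        w = np.log(np.maximum(model.initial, 1e-300)) + logb
        m = w.max()
        lse = m + np.log(np.exp(w - m).sum())
        gamma = np.exp(w - lse)[None, :]
        return SubjectPosterior(
            loglik=float(lse), gamma=gamma, xi=np.empty((0, model.r, model.r))
        )
    ll, gamma, xi = _batch_forward_backward(y[None, :], model)
    return SubjectPosterior(loglik=float(ll[0]), gamma=gamma[0], xi=xi[0])


# ---------------------------------------------------------------------------
# EM fitting

def count_free_parameters(r: int) -> int:
    """Free parameters: (r-1) initial + r(r-1) transition + 2r emission."""
    if r < 1:
        raise ValueError("r must be >= 1")
    return r * r + 2 * r - 1


def information_criteria(loglik: float, n_params: int, n_obs: int):
    """AIC = -2*loglik + 2p; BIC = -2*loglik + ln(n)*p (natural log)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + math.log(n_obs) * n_params
    return aic, bic


def _initial_model(scores: np.ndarray, r: int, rng, jitter: float) -> LatentModel:
    """Quantile-block initialization with optional seeded mean jitter."""
    obs = scores[~np.isnan(scores)]
    obs_sorted = np.sort(obs)
    blocks = np.array_split(obs_sorted, r)
    means = np.array([b.mean() for b in blocks])
    sds = np.array([max(b.std(), SD_FLOOR) for b in blocks])
    if jitter > 0:
        means = means + rng.normal(0.0, jitter, size=r)
        means.sort()
    transition = np.full((r, r), 0.2 / max(r - 1, 1))
    np.fill_diagonal(transition, 0.8)
    if r == 1:
        transition = np.ones((1, 1))
    return LatentModel(
        r=r,
        initial=np.full(r, 1.0 / r),
        transition=transition,
        emission_means=means,
        emission_sds=sds,
    )


def _em_once(scores, r, start, tol, max_iter):
    model = start
    prev = -np.inf
    path = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll_n, gamma, xi = _batch_forward_backward(scores, model)
        ll = float(ll_n.sum())
        path.append(ll)
        if np.isfinite(prev) and abs(ll - prev) < tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll

        initial = gamma[:, 0].mean(axis=0)
        initial /= initial.sum()
        counts = xi.sum(axis=(0, 1))
        row = counts.sum(axis=1, keepdims=True)
        transition = np.where(row > 0, counts / np.maximum(row, 1e-300), 1.0 / r)
        transition /= transition.sum(axis=1, keepdims=True)

        obs = ~np.isnan(scores)
        y = np.where(obs, scores, 0.0)
        w = gamma * obs[..., None]
        wsum = w.sum(axis=(0, 1))
        wsum = np.maximum(wsum, 1e-300)
        means = (w * y[..., None]).sum(axis=(0, 1)) / wsum
        var = (w * (y[..., None] - means) ** 2).sum(axis=(0, 1)) / wsum
        sds = np.maximum(np.sqrt(var), SD_FLOOR)
        model = LatentModel(
            r=r, initial=initial, transition=transition,
            emission_means=means, emission_sds=sds,
        )
    final_ll, _, _ = _batch_forward_backward(scores, model)
    return model, float(final_ll.sum()), converged, n_iter, path


def em_fit(
    data,
    r: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit an r-state model by Baum-Welch EM, best of ``n_restarts``.

    ``data`` is a :class:`~lmtraject.cohort_io.CohortDataset` or an (N, T)
    score matrix; NaN cells are marginalized. Convergence is a relative
    log-likelihood change below ``tol``. Restarts jitter the quantile-based
    initial means with seeded noise; the best final log-likelihood wins.
    States are relabeled ascending by emission mean. Deterministic given
    ``seed``.
    """
    scores = data.scores if isinstance(data, CohortDataset) else np.asarray(data, float)
    if scores.ndim != 2:
        raise ValueError("scores must be an (N, T) matrix")
    obs = scores[~np.isnan(scores)]
    n_distinct = np.unique(obs).size
    if r > n_distinct:
        raise DegenerateDataError(
            f"r={r} exceeds the {n_distinct} distinct observed score(s)"
        )
    rng = np.random.default_rng(seed)
    pooled_sd = max(float(obs.std()), SD_FLOOR)

    best = None
    for restart in range(max(n_restarts, 1)):
        jitter = 0.0 if restart == 0 else pooled_sd / 2.0
        start = _initial_model(scores, r, rng, jitter)
        model, ll, converged, n_iter, path = _em_once(scores, r, start, tol, max_iter)
        if best is None or ll > best[1]:
            best = (model, ll, converged, n_iter, path, restart + 1)

    model, ll, converged, n_iter, path, used = best
    model = model.sorted_by_mean()
    n_obs = int((~np.isnan(scores)).sum())
    n_params = count_free_parameters(r)
    aic, bic = information_criteria(ll, n_params, n_obs)
    return FitResult(
        model=model, loglik=ll, n_params=n_params, n_obs=n_obs,
        aic=aic, bic=bic, converged=converged, n_iter=n_iter,
        n_restarts_used=used, loglik_path=path,
    )


def select_states(
    data,
    r_min: int = 3,
    r_max: int = 6,
    criterion: str = "bic",
    **em_options,
) -> ModelSelectionTable:
    """Grid-search the state count and select by minimum AIC or BIC.

    Defaults fit r in {3, 4, 5, 6} and select by BIC. Only converged fits
    compete; the table rows mirror the fitted score bands alongside the
    criteria values.
    """
    if r_min > r_max:
        raise ValueError("r_min must be <= r_max")
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    rows, fits = [], {}
    for r in range(r_min, r_max + 1):
        fit = em_fit(data, r, **em_options)
        fits[r] = fit
        bands = derive_state_bands(fit.model).render() if r > 1 else "[0, 100]"
        rows.append(
            {"r": r, "bands": bands, "aic": fit.aic, "bic": fit.bic,
             "converged": fit.converged}
        )
    candidates = [row for row in rows if row["converged"]]
    if not candidates:
        raise SelectionError("no converged fits in the grid")
    selected = min(candidates, key=lambda row: row[criterion])["r"]
    return ModelSelectionTable(rows=rows, selected_r=selected,
                               criterion=criterion, fits=fits)


# ---------------------------------------------------------------------------
# score bands

def _density_crossing(m1, s1, m2, s2):
    """Equal-density point of two Gaussians lying between their means."""
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * math.log(s2 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = np.array([(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        return 0.5 * (m1 + m2)
    return float(inside[0])


def derive_state_bands(model: LatentModel) -> StateBands:
    """Score cutoffs between adjacent states from their emission Gaussians.

    The boundary between states k and k+1 is the score where the two
    emission densities are equal (between the two means); with equal SDs
    this is the midpoint of the means. Requires mean-ordered states.
    """
    means, sds = model.emission_means, model.emission_sds
    if (np.diff(means) <= 0).any():
        raise ValueError("emission means must be strictly increasing")
    bounds = [
        _density_crossing(means[k], sds[k], means[k + 1], sds[k + 1])
        for k in range(model.r - 1)
    ]
    return StateBands(boundaries=np.array(bounds))


# ---------------------------------------------------------------------------
# multiple-imputation pooling of fitted models

def pool_models(models: Sequence[LatentModel]) -> LatentModel:
    """Average model parameters across imputations after mean-ordering.

    Each model is relabeled ascending by emission mean, parameters are
    averaged elementwise, and the simplex/stochastic constraints restored by
    renormalization.
    """
    models = [m.sorted_by_mean() for m in models]
    r = models[0].r
    if any(m.r != r for m in models):
        raise ValueError("all models must share the same state count")
    initial = np.mean([m.initial for m in models], axis=0)
    transition = np.mean([m.transition for m in models], axis=0)
    initial /= initial.sum()
    transition /= transition.sum(axis=1, keepdims=True)
    return LatentModel(
        r=r,
        initial=initial,
        transition=transition,
        emission_means=np.mean([m.emission_means for m in models], axis=0),
        emission_sds=np.mean([m.emission_sds for m in models], axis=0),
    )
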