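import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from lmtraject.latent_markov import LatentModel, em_fit
from lmtraject.synthetic_cohort import default_truth, generate_cohort


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def complete_cohort(truth):
    """Complete (no missing) default synthetic cohort with its truth record."""
    return generate_cohort(truth, n_subjects=358, n_waves=10, missing_rate=0.0,
                           seed=11)


@pytest.fixture(scope="session")
def fitted4(complete_cohort):
    """A 4-state model fitted once to the shared complete cohort."""
    return em_fit(complete_cohort[0], r=4, seed=5)


def random_model(rng, r: int, mean_span=(10.0, 90.0)) -> LatentModel:
    """A random valid mean-ordered model for oracle comparisons."""
    means = np.sort(rng.uniform(*mean_span, size=r))
    while (np.diff(means) < 1e-3).any():
        means = np.sort(rng.uniform(*mean_span, size=r))
    return LatentModel(
        r=r,
        initial=rng.dirichlet(np.ones(r)),
        transition=rng.dirichlet(np.ones(r), size=r),
        emission_means=means,
        emission_sds=rng.uniform(1.0, 10.0, size=r),
    )


def brute_force_loglik(y, model: LatentModel) -> float:
    """Likelihood by explicit enumeration of all r^T state paths (log domain)."""
    r, t = model.r, len(y)
    path_logs = []
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
        log_trans = np.log(model.transition)
    for path in itertools.product(range(r), repeat=t):
        lp = log_init[path[0]]
        for s in range(1, t):
            lp += log_trans[path[s - 1], path[s]]
        for s in range(t):
            if not np.isnan(y[s]):
                lp += norm.logpdf(y[s], model.emission_means[path[s]],
                                  model.emission_sds[path[s]])
        path_logs.append(lp)
    return float(logsumexp(path_logs))
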