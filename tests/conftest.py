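"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from sleeptrends.cohort_data import Observation
from sleeptrends.interval_mapping import default_schemes
from sleeptrends.synthetic_cohort import SyntheticConfig, default_truth, generate


@pytest.fixture(scope="session")
def schemes():
    return default_schemes()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-pair synthetic cohort reused by read/write and descriptive tests."""
    obs, truth = generate(SyntheticConfig(n_pairs=30, seed=11))
    return obs, truth


@pytest.fixture(scope="session")
def truth_params():
    return default_truth()


def mc_marginal_loglik(observations, params, n_draws: int, seed: int):
    """Monte Carlo estimate of the marginal log-likelihood and its SE.

    Independent of the package's quadrature path: frailties are simulated,
    interval probabilities are computed from the Weibull survival function
    directly, and the nested integral is the sample mean of the per-draw
    conditional likelihood of each pair.
    """
    rng = np.random.default_rng(seed)
    k = params.shape
    beta = np.asarray(params.beta)
    pairs: dict[str, list[Observation]] = {}
    for o in observations:
        pairs.setdefault(o.pair_id, []).append(o)

    def lin(o: Observation) -> float:
        x = np.zeros(6)
        names = [("birth_cohort", "1900-1919"), ("birth_cohort", "1920-1939"),
                 ("birth_cohort", "1940-1957"), ("age_group", "35-54"),
                 ("age_group", "55+"), ("gender", "male")]
        for j, (f, lv) in enumerate(names):
            x[j] = getattr(o, f) == lv
        return params.beta0 + float(x @ beta)

    total_ll = 0.0
    total_var = 0.0
    for members in pairs.values():
        u_p = rng.normal(0.0, params.sigma_pair, n_draws)
        subjects = sorted({o.subject_id for o in members})
        u_i = {s: rng.normal(0.0, params.sigma_ind, n_draws) for s in subjects}
        logL = np.zeros(n_draws)
        for o in members:
            eta = lin(o) + u_p + u_i[o.subject_id]
            sL = np.exp(-o.interval.left ** k * np.exp(eta)) if o.interval.left > 0 else np.ones(n_draws)
            sR = (np.exp(-o.interval.right ** k * np.exp(eta))
                  if math.isfinite(o.interval.right) else np.zeros(n_draws))
            logL += np.log(np.maximum(sL - sR, 1e-300))
        m = logL.max()
        w = np.exp(logL - m)
        z = float(np.mean(w))
        total_ll += m + math.log(z)
        total_var += float(np.var(w)) / n_draws / z**2  # delta method on log
    return total_ll, math.sqrt(total_var)
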