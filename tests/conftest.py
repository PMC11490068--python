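"""Shared fixtures and independent oracles.

The Gauss-Hermite oracle evaluates the logistic-normal integrals by
200-node quadrature, written directly against numpy primitives so it stays
independent of the package's Monte-Carlo path.
"""

from __future__ import annotations

import numpy as np
import pytest

import duoread as dr


# ---------------------------------------------------------------------------
# Independent quadrature oracles
# ---------------------------------------------------------------------------

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(200)


def gh_marginal_rate(r: float, sigma: float) -> float:
    """E[1/(1+exp(-(r + sigma Z)))], Z ~ N(0,1), by 200-node Gauss-Hermite."""
    q = r + sigma * np.sqrt(2.0) * _GH_X
    vals = 1.0 / (1.0 + np.exp(-q))
    return float(_GH_W @ vals / np.sqrt(np.pi))


def gh_marginal_disagreement(r1: float, r2: float, sigma: float) -> float:
    q1 = r1 + sigma * np.sqrt(2.0) * _GH_X
    q2 = r2 + sigma * np.sqrt(2.0) * _GH_X
    a1 = 1.0 / (1.0 + np.exp(-q1))
    a2 = 1.0 / (1.0 + np.exp(-q2))
    vals = a1 * (1.0 - a2) + a2 * (1.0 - a1)
    return float(_GH_W @ vals / np.sqrt(np.pi))


def mc_standard_error(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / np.sqrt(len(values)))


@pytest.fixture(scope="session")
def gh_oracle():
    return gh_marginal_rate, gh_marginal_disagreement


# ---------------------------------------------------------------------------
# Parameter-recovery harness: generate from known truth, aggregate, fit once
# ---------------------------------------------------------------------------

RECOVERY_SEED = 42


@pytest.fixture(scope="session")
def recovery_harness():
    """10 readers chained into overlapping pairs, ~20,000 negative and ~200
    positive reads each, fitted with a reduced Monte-Carlo sample."""
    pop_cfg = dr.PopulationConfig(
        n_readers=10,
        mean_r_neg=-3.3,
        sd_r_neg=0.3,
        mean_r_pos=1.0,
        sd_r_pos=0.5,
        correlation=0.0,
        sigma_neg=1.0,
        sigma_pos=1.5,
        seed=RECOVERY_SEED,
    )
    truth, rates = dr.generate_reader_population(pop_cfg)
    records = dr.generate_reading_records(
        truth, dr.DatasetConfig(n_exams=101_000, prevalence=0.01, seed=RECOVERY_SEED)
    )
    counts = dr.apply_exclusion_criteria(dr.aggregate_reading_records(records), 17)
    fitted = dr.fit_model(
        counts, dr.FitConfig(mc=dr.MonteCarloConfig(20_000, 7))
    )
    return {
        "truth": truth,
        "rates": rates,
        "records": records,
        "counts": counts,
        "fitted": fitted,
    }


@pytest.fixture(scope="session")
def small_population():
    """A 24-reader population at default (screening-realistic) settings."""
    params, rates = dr.generate_reader_population(
        dr.PopulationConfig(n_readers=24, seed=5)
    )
    return params, rates
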