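"""Shared fixtures: synthetic datasets and the heavy model fits.

The evoked-model fits are session-scoped so that recovery, model-comparison
and timing tests share one MCMC run per variant.
"""

import warnings

import numpy as np
import pytest

from mtspike import PiecewiseModelSpec, fit_piecewise_model
from mtspike.synthdata import (
    ON_POPULATION_PARAMS, OFF_POPULATION_PARAMS, gen_evoked_counts,
)

warnings.filterwarnings("ignore", message="The chain is shorter")


@pytest.fixture(scope="session")
def on_counts():
    """Pooled ON-cell counts generated at the reported posterior means."""
    return gen_evoked_counts("on_double_exp", ON_POPULATION_PARAMS, seed=20260927)


@pytest.fixture(scope="session")
def off_counts():
    """Pooled OFF-cell counts generated at the reported posterior means."""
    return gen_evoked_counts("off_linear_exp", OFF_POPULATION_PARAMS, seed=20260928)


@pytest.fixture(scope="session")
def on_fit(on_counts):
    fit = fit_piecewise_model(on_counts, PiecewiseModelSpec("on_double_exp", seed=11))
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def off_fit(off_counts):
    fit = fit_piecewise_model(off_counts, PiecewiseModelSpec("off_linear_exp", seed=12))
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def on_single_fit(on_counts):
    return fit_piecewise_model(on_counts, PiecewiseModelSpec("on_single_exp", seed=13))


@pytest.fixture(scope="session")
def on_null_fit(on_counts):
    return fit_piecewise_model(
        on_counts,
        PiecewiseModelSpec("null_constant", seed=14, n_steps=1200, n_burn=400,
                           n_walkers=16),
    )
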