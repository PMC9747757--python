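"""Shared fixtures.

The expensive CBM ensembles are session-scoped so the table-reproduction
and ordering checks share the same simulations.
"""

import numpy as np
import pytest

from quasicrit.cbm import CBMConfig, build_network
from quasicrit.cohort import CohortConfig, generate_cohort
from quasicrit.pipeline import run_cohort
from quasicrit.study import simulate_cell


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_network():
    cfg = CBMConfig(n_nodes=32, k_in=3, kappa=0.9, bias=0.5, seed=4)
    return cfg, build_network(cfg)


@pytest.fixture(scope="session")
def table_cells():
    """Ensemble statistics at the two reference parameter cells.

    Four independent runs per cell of up to 4e6 steps (5e4 avalanches).
    The duration exponent needs long runs — its scale-free stretch keeps
    growing well past 1e6 steps — so the cells run near full scale and the
    rest of the suite stays lean to compensate.
    """
    kwargs = dict(reps=4, seed=101, max_steps=4_000_000, target_avalanches=50_000)
    return {
        "high_bias": simulate_cell(bias=1.8, kappa=1.07, **kwargs),
        "low_bias": simulate_cell(bias=0.6, kappa=1.12, **kwargs),
    }


@pytest.fixture(scope="session")
def mini_cohort_results():
    """A small fully-analyzed synthetic cohort (8 subjects, 45 s)."""
    cfg = CohortConfig(n_subjects=8, duration_s=45.0, seed=21)
    subjects, metadata = generate_cohort(cfg)
    results = run_cohort(subjects)
    return subjects, metadata, results
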