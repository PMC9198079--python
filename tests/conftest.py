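"""Shared fixtures: synthetic cohorts are generated once per session.

The heavy fixtures (full model grids over multi-operation cohorts) are
session-scoped because several acceptance properties are read off the same
grids; everything is deterministic given the fixed seeds.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

from hammersound import SimConfig, generate_cohort, process_cohort, run_grid
from hammersound.synthetic_data import worked_example_fixture

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

logging.getLogger("hammersound").setLevel(logging.ERROR)

#: Cohort sizes used by the heavy end-to-end fixtures.
GRID_N_OPERATIONS = 20
SIGNAL_SEEDS = (1, 2, 3)
NULL_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def worked_example():
    """Single-operation worked-example cohort, processed end to end."""
    truths, pairs = worked_example_fixture(seed=0)
    cohort = process_cohort(pairs)
    return truths, pairs, cohort


def _run_full_grid(seed: int, beta: float):
    cfg = SimConfig(n_operations=GRID_N_OPERATIONS, seed=seed, seating_shift=beta)
    truths, pairs = generate_cohort(cfg)
    cohort = process_cohort(pairs)
    results, long_df, table = run_grid(cohort, seed=seed)
    return {
        "truths": truths,
        "pairs": pairs,
        "cohort": cohort,
        "results": results,
        "long": long_df,
        "table": table,
    }


@pytest.fixture(scope="session")
def signal_grids():
    """Full 6x3 LOOCV grids on three seating-effect cohorts (beta = 0.4)."""
    return {seed: _run_full_grid(seed, beta=0.4) for seed in SIGNAL_SEEDS}


@pytest.fixture(scope="session")
def null_grids():
    """Full 6x3 LOOCV grids on three null cohorts (beta = 0)."""
    return {seed: _run_full_grid(seed, beta=0.0) for seed in NULL_SEEDS}


@pytest.fixture(scope="session")
def small_cohort():
    """A light 6-operation cohort for unit-level pipeline tests."""
    cfg = SimConfig(n_operations=6, seed=99)
    truths, pairs = generate_cohort(cfg)
    cohort = process_cohort(pairs)
    return truths, pairs, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
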