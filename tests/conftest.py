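"""Shared fixtures. Expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from erlopbpk.physchem import load_drug
from erlopbpk.gi_absorption import build_physiology
from erlopbpk.pbpk_body import build_subject
from erlopbpk.engine import Regimen, simulate_single, simulate_population
from erlopbpk.covariates import run_all

POP_SEED = 20180216


@pytest.fixture(scope="session")
def drug():
    return load_drug()


@pytest.fixture(scope="session")
def predicted_drug():
    return load_drug("predicted")


@pytest.fixture(scope="session")
def standard_subject(drug):
    return build_subject(drug)


@pytest.fixture(scope="session")
def fasted_physiology():
    return build_physiology("fasted", False)


@pytest.fixture(scope="session")
def covariate_reports(drug):
    """Full co-variate scenario panel (shared by sign and magnitude checks)."""
    return run_all(drug)


@pytest.fixture(scope="session")
def population_day1(drug):
    """Virtual population of 25, day-1 single dose, fixed seed."""
    return simulate_population(drug, Regimen(dose=100.0, n_doses=1),
                               n=25, seed=POP_SEED, duration=24.0)


@pytest.fixture(scope="session")
def multidose_profile(drug, standard_subject, fasted_physiology):
    """100 mg q.d. for 8 days in the standard subject."""
    return simulate_single(drug, standard_subject, fasted_physiology,
                           Regimen(dose=100.0, interval=24.0, n_doses=8),
                           duration=8 * 24.0, rtol=1e-6, atol=1e-8)
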