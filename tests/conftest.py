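"""Shared synthetic fixtures.

Expensive objects (simulated cohorts, LTJMM fits) are session-scoped so the
whole suite pays for each fit once.
"""

import numpy as np
import pytest

from gaitprog import LTJMM, SimConfig, match_gait_to_clinical, simulate_full

ERL_SEED = 101


@pytest.fixture(scope="session")
def erl_small():
    """Erlangen-style cohort, reduced size for test runtime."""
    cfg = SimConfig.erl_like(n_patients=90, n_gait_patients=90)
    cohort, truth = simulate_full(cfg, ERL_SEED)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def erl_fit(erl_small):
    _, cohort, _ = erl_small
    model = LTJMM.from_cohort(cohort, ["updrs3", "axial"])
    return model.fit()


@pytest.fixture(scope="session")
def erl_matched(erl_small):
    _, cohort, _ = erl_small
    return match_gait_to_clinical(cohort)


@pytest.fixture(scope="session")
def lux_small():
    """LuxPARK-style cohort (single gait visit per patient), reduced size."""
    cfg = SimConfig.lux_like(n_patients=80, n_gait_patients=80)
    cohort, truth = simulate_full(cfg, 202)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
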