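import numpy as np
import pytest

import perlinspot as ps


@pytest.fixture(scope="session")
def stimulus_set():
    """Default-size screened stimulus set (30 pairs, 10 per strength)."""
    return ps.build_stimulus_set(n_pairs=30, seed=7)


@pytest.fixture(scope="session")
def small_set():
    """Three low-resolution pairs for fast structural tests."""
    return ps.build_stimulus_set(n_pairs=3, seed=3, scale_px_per_cm=10.0)


@pytest.fixture(scope="session")
def cohort(stimulus_set):
    """One simulated 30-participant cohort under default calibration."""
    params = ps.ObserverParams(seed=11)
    return ps.simulate_experiment(params, stimulus_set)


@pytest.fixture(scope="session")
def cohort_summaries(cohort):
    return ps.summarize_participant(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
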