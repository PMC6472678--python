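import numpy as np
import pytest
from hypothesis import settings

from eoa import EnsembleSample, Hypothesis, SyntheticRunSpec, build_grid

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def h0():
    """Hypothesis: value strictly greater than 0."""
    return Hypothesis(threshold=0.0, direction="greater")


@pytest.fixture
def two_level_7(h0):
    """7-member ensemble, 2 strong dissenters at -10, 5 consenters at +5 (ES = 5)."""
    return EnsembleSample.from_values([-10, -10, 5, 5, 5, 5, 5])


@pytest.fixture
def symmetric_4():
    """The balanced four-value ensemble straddling 0: no net evidence either way."""
    return EnsembleSample.from_values([-2, -1, 1, 2])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def small_run_spec(**overrides) -> SyntheticRunSpec:
    """A scaled-down synthetic run table spec for fast pipeline tests."""
    defaults = dict(
        n_models=5,
        grid=build_grid((0.0, 2.0, 1.0), (-10.0, 10.0, 10.0)),
        soils=("shallow",),
        co2_levels=(447,),
        sigma_model=0.0,
        sigma_resid=0.0,
        seed=7,
    )
    defaults.update(overrides)
    return SyntheticRunSpec(**defaults)


@pytest.fixture
def noiseless_runs():
    """Noiseless 5-member table over a 3x3 grid, +10% injected adaptation effect."""
    from eoa import simulate_model_runs

    return simulate_model_runs(small_run_spec())
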