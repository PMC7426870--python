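import pytest

from blifit import GlobalKineticsFit
from blifit.simulate import SimulationDesign, optonb_scenarios, simulate_dataset

REDUCED_CONCENTRATIONS = (2.0, 1.0, 0.5, 0.0)


@pytest.fixture(scope="session")
def scenarios():
    return optonb_scenarios()


@pytest.fixture(scope="session")
def lam8(scenarios):
    return scenarios["LaM8"].kinetics


def make_small_design(seed=11, noise_sigma=0.01, samples=40):
    """4-curve reduced design used to keep fits fast in unit tests."""
    return SimulationDesign(
        seed=seed,
        concentrations=REDUCED_CONCENTRATIONS,
        samples_per_phase=samples,
        noise_sigma=noise_sigma,
    )


@pytest.fixture(scope="session")
def small_dataset(lam8):
    return simulate_dataset(lam8, make_small_design())


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    return GlobalKineticsFit().fit(small_dataset)
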