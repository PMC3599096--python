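import numpy as np
import pytest

from riskkinetics import DegenerationSeries, RiskSeries
from riskkinetics.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (5 glaucoma + 3 control, noisy FA)."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_study():
    """Same design with fa_noise_sd = 0: observations equal the forward model."""
    return simulate_study(SimulationConfig(seed=7, fa_noise_sd=0.0))


@pytest.fixture
def simple_risk():
    return RiskSeries(
        subject_id="s1",
        group="glaucoma",
        eye="affected",
        days=np.array([0.0, 20.0, 50.0, 90.0, 140.0]),
        iop=np.array([23.0, 52.0, 60.0, 48.0, 55.0]),
    )


@pytest.fixture
def simple_degen():
    return DegenerationSeries(
        subject_id="s1",
        eye="affected",
        region="optic_nerve",
        days=np.array([50.0, 90.0, 140.0]),
        values=np.array([0.9, 0.7, 0.5]),
        kind="relative",
    )
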