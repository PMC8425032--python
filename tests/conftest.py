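import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from symportfit import SolutionCondition, StepProtocol, get_preset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# independent copies of the physical constants for oracle computations
FARADAY = 96485.332
GAS_CONSTANT = 8.3145


@pytest.fixture(scope="session")
def preset():
    """Packaged oocyte ground-truth preset."""
    return get_preset("trire2_104072")


@pytest.fixture(scope="session")
def buffer_ph55():
    return SolutionCondition(pH=5.5)


@pytest.fixture(scope="session")
def arabinose_5mm():
    return SolutionCondition(pH=5.5, sugar_name="l-arabinose", sugar_concentration=5.0)


@pytest.fixture(scope="session")
def default_protocol():
    return StepProtocol()


def oracle_boltzmann_fraction(v, v05, z, temperature):
    """Closed-form mobile-charge occupancy, written independently of the package."""
    return 1.0 / (1.0 + np.exp(z * FARADAY * (v - v05) * 1e-3 / (GAS_CONSTANT * temperature)))


def oracle_transport_current(preset, voltage, ph, sugar, conc):
    """Closed-form steady-state symport current from the preset parameters."""
    if sugar is None or conc == 0:
        return 0.0
    params = preset.sugars[sugar]
    table = np.asarray(preset.imax_voltage_table)
    scale = np.interp(voltage, table[:, 0], table[:, 1])
    mm = conc / (conc + params.Km)

    def hill(ph_value):
        h = 10.0 ** (9.0 - ph_value)
        hn = h**preset.hill_n_H
        return hn / (hn + preset.K05_H**preset.hill_n_H)

    return params.Imax_ref * scale * mm * hill(ph) / hill(preset.reference_pH)


def oracle_steady_state(preset, voltage, ph, sugar=None, conc=0.0):
    leak = preset.leak_conductance * (voltage - preset.leak_reversal)
    return leak + oracle_transport_current(preset, voltage, ph, sugar, conc)
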