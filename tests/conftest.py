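import numpy as np
import pytest
from hypothesis import settings

import soyemerge as se
from soyemerge.germination import ThermalTimeDistribution

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ecudor():
    return se.preset_cultivar_params("Ecudor")


@pytest.fixture()
def no_stress_weather():
    return se.generate_weather("no_stress", 45)


@pytest.fixture()
def benign_config():
    """A seedbed with no mortality pathway beyond non-germination."""
    return se.SeedbedConfig(
        n_seeds=500, aggregate_spec=[], soil_crusting_class="non_crusting"
    )


@pytest.fixture()
def point_mass_cultivar():
    """Deterministic cultivar: every seed needs exactly 18 deg C day."""
    return se.CultivarGerminationParams(
        name="point", Tb=4.0, Topt=30.0, psi_b_mean=-0.58,
        germinable_fraction=1.0,
        thermal_time_distribution=ThermalTimeDistribution.point_mass(18.0),
    )
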