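import numpy as np
import pytest

from pvsim import (
    EffortProfile,
    EffortTrain,
    RespiratoryMechanics,
    VentilatorSettings,
    simulate,
)
from pvsim.battery import build_default_battery, render_scenario


@pytest.fixture(scope="session")
def battery():
    return build_default_battery()


@pytest.fixture(scope="session")
def rendered_battery(battery):
    """Noiseless render of all 49 scenarios at seed 0, keyed by scenario_id."""
    return {sc.scenario_id: render_scenario(sc, seed=0) for sc in battery}


@pytest.fixture(scope="session")
def normal_mechanics():
    return RespiratoryMechanics(resistance=10.0, compliance=50.0, peep_total=5.0)


@pytest.fixture(scope="session")
def passive_vcv(normal_mechanics):
    """30-s passive volume-controlled record (R=10, C=50, PEEP 5)."""
    settings = VentilatorSettings(
        mode="VCV", insp_flow_lps=0.5, insp_time_s=1.0, set_rate_bpm=12.0,
        trigger_threshold=2.0,
    )
    return simulate(normal_mechanics, settings, EffortTrain.passive(), duration_s=30.0)


@pytest.fixture(scope="session")
def psv_with_efforts(normal_mechanics):
    """30-s pressure-support record with periodic half-sine efforts (amp 8)."""
    settings = VentilatorSettings(
        mode="PSV", trigger_threshold=2.0, pressure_above_peep=12.0,
        cycling_flow_fraction=0.3, max_insp_time_s=2.5,
    )
    efforts = EffortTrain.periodic(
        1.0, 4.0, 30.0, EffortProfile(shape="half_sine", amplitude=8.0, rise_s=0.5, release_s=0.5)
    )
    return simulate(normal_mechanics, settings, efforts, duration_s=30.0)
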