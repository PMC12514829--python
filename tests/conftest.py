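import numpy as np
import pytest

from oxyscope import ChamberSpec, CycleSchedule, FishMeta, OxygenTrace, WaterConditions


@pytest.fixture
def cond2c() -> WaterConditions:
    """Cold-treatment water: 2 °C, S 34, standard pressure."""
    return WaterConditions(temperature=2.0, salinity=34.0)


@pytest.fixture
def anchored_cond() -> WaterConditions:
    """Conditions pinned to the published conversion anchors."""
    return WaterConditions(
        temperature=2.0, salinity=34.0, sat_concentration=366.67, sat_po2=20.857
    )


@pytest.fixture
def fish40() -> FishMeta:
    return FishMeta(id="F1", body_weight=40.0, total_length=19.7)


@pytest.fixture
def chamber() -> ChamberSpec:
    return ChamberSpec(respirometer_volume=2.5, fish_volume_displacement=0.04)


@pytest.fixture
def tunnel() -> ChamberSpec:
    return ChamberSpec(respirometer_volume=5.0, kind="swim_tunnel")


def make_trace(
    o2,
    conditions,
    fish,
    chamber,
    schedule=CycleSchedule(flush_s=300, stabilization_s=200, measure_s=1630),
    unit="umol_per_L",
    dt=1.0,
):
    o2 = np.asarray(o2, float)
    return OxygenTrace(
        time=np.arange(o2.size) * dt,
        o2=o2,
        unit=unit,
        conditions=conditions,
        chamber=chamber,
        fish=fish,
        schedule=schedule,
    )
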