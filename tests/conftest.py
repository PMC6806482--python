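import numpy as np
import pytest

from protonval.beamline import Beam, BeamLineConfig, EnergyLayer, PBSPlan, Spot
from protonval.idd import IDDLibrary
from protonval.phantom import build_slab_phantom


@pytest.fixture(scope="session")
def idd_library():
    """One shared IDD library so curves are built once per session."""
    return IDDLibrary()


@pytest.fixture(scope="session")
def water_phantom():
    return build_slab_phantom([("water", 200.0)], lateral_size=100.0,
                              spacing=2.0)


@pytest.fixture(scope="session")
def simple_beamline():
    return BeamLineConfig(range_shifter_wet=0.0, air_gap=0.0)


def single_spot_plan(energy=150.0, weight=1.0, x=0.0, y=0.0, beamline=None):
    bl = beamline if beamline is not None else BeamLineConfig(
        range_shifter_wet=0.0, air_gap=0.0)
    layer = EnergyLayer(float(energy), [Spot(x, y, float(energy), weight)])
    return PBSPlan([Beam(np.array([0.0, 0.0, 1.0]), bl, [layer])], "single")


@pytest.fixture(scope="session")
def spot_plan_150(simple_beamline):
    return single_spot_plan(150.0, beamline=simple_beamline)
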