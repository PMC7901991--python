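import pytest

from pulmowk.synth import SubjectArchetype, make_waveform
from pulmowk.tree import VesselSegment, VesselTree
from pulmowk.windkessel import BloodProperties


@pytest.fixture
def blood():
    return BloodProperties()


def _segment(sid, name, parent, length, radius):
    return VesselSegment(id=sid, name=name, parent=parent, length=length, radius=radius)


@pytest.fixture
def tree5():
    """MPA -> LPA/RPA -> one outlet branch per side (5 segments)."""
    segs = [
        _segment("MPA", "MPA", None, 0.045, 0.0125),
        _segment("LPA", "LPA", "MPA", 0.035, 0.009),
        _segment("RPA", "RPA", "MPA", 0.035, 0.009),
        _segment("L1", "branch", "LPA", 0.025, 0.007),
        _segment("R1", "branch", "RPA", 0.025, 0.0065),
    ]
    t = VesselTree(segments=segs, outlet_sides={"L1": "left", "R1": "right"})
    t.fill_thickness()
    return t


@pytest.fixture
def tree3():
    """Depth-1 tree: MPA with LPA/RPA as the outlets."""
    segs = [
        _segment("MPA", "MPA", None, 0.045, 0.0125),
        _segment("LPA", "LPA", "MPA", 0.035, 0.009),
        _segment("RPA", "RPA", "MPA", 0.035, 0.009),
    ]
    t = VesselTree(segments=segs, outlet_sides={"LPA": "left", "RPA": "right"})
    t.fill_thickness()
    return t


@pytest.fixture
def control_archetype():
    return SubjectArchetype(
        group="control",
        period=0.74,
        stroke_volume=69e-6,
        systolic_fraction=0.35,
        f_reg=0.0,
        mpa_diameter=0.025,
        tree_depth=2,
        e_true=75e3,
        rt_true=3.99 * 7.99932e6,
        ct_true=0.85 * 7.5006e-9,
    )


@pytest.fixture
def control_inflow(control_archetype):
    return make_waveform(control_archetype, seed=0)
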