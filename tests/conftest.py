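import numpy as np
import pytest

from thermoembo import ParameterSet, VesselSpec, make_box_mesh, tag_vessel


@pytest.fixture
def params():
    """Reference parameter set (2 mol/L DCACl in oil, soft-tissue host)."""
    return ParameterSet()


@pytest.fixture
def mesh_1d():
    return make_box_mesh((0.01,), (10,))


@pytest.fixture
def mesh_2d():
    return make_box_mesh((0.02, 0.02), (8, 8))


def left_end_vessel(mesh):
    """Tag the boundary face(s) nearest the low-x corner/edge as vessel."""
    dim = mesh.dim
    mid = tuple(e / 2 for e in mesh.extents[1:])
    point = (0.0,) + mid
    spec = VesselSpec(segments=[(point, point)], radius=min(mesh.spacing))
    return tag_vessel(mesh, spec)
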