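import numpy as np
import pytest

from taphos3d import Box3Window, PhantomSpec, make_phantom

UNIT_CUBE_OBJ = """\
v 0 0 0
v 1 0 0
v 1 1 0
v 0 1 0
v 0 0 1
v 1 0 1
v 1 1 1
v 0 1 1
f 1 3 2
f 1 4 3
f 5 6 7
f 5 7 8
f 1 2 6
f 1 6 5
f 2 3 7
f 2 7 6
f 3 4 8
f 3 8 7
f 4 1 5
f 4 5 8
"""


@pytest.fixture
def unit_cube_path(tmp_path):
    path = tmp_path / "cube.obj"
    path.write_text(UNIT_CUBE_OBJ)
    return path


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(PhantomSpec(mesh_resolution=20))


@pytest.fixture
def box_window():
    return Box3Window(0, 100, 0, 30, 0, 30)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
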