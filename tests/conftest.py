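import numpy as np
import pytest

from prorad.calibration import default_curve
from prorad.phantom import CtVolume, PhantomSpec, generate_phantom, neck_region
from prorad.pr_sim import BeamConfig


@pytest.fixture(scope="session")
def curve():
    return default_curve()


@pytest.fixture(scope="session")
def desk_beam():
    return BeamConfig.desk()


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return generate_phantom(phantom_spec, seed=11)


@pytest.fixture(scope="session")
def region(phantom_spec):
    return neck_region(phantom_spec)


def make_slab_ct(
    layers: list[tuple[float, float]],
    ny: int = 32,
    nz: int = 32,
    spacing: float = 2.0,
) -> CtVolume:
    """Stack of homogeneous slabs along +x: [(thickness_mm, hu), ...]."""
    nx = int(round(sum(t for t, _ in layers) / spacing))
    hu = np.full((nx, ny, nz), -1000.0)
    x0 = 0.0
    for t, h in layers:
        i0, i1 = int(round(x0 / spacing)), int(round((x0 + t) / spacing))
        hu[i0:i1] = h
        x0 += t
    return CtVolume(hu, (spacing, spacing, spacing))
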