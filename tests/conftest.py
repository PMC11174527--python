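import numpy as np
import pytest

from holotomo import RITomogram, make_schedule
from holotomo.core import MEDIUM_RI


@pytest.fixture(scope="session")
def schedule21():
    """Light 21-angle scan over the full +-45 degree span."""
    return make_schedule(21)


def make_bead(radius_um: float, ri: float, n: int, pitch: float,
              medium_ri: float = MEDIUM_RI) -> RITomogram:
    x = (np.arange(n) - n // 2) * pitch
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    vals = np.where(X**2 + Y**2 + Z**2 <= radius_um**2, ri,
                    medium_ri).astype(np.float32)
    return RITomogram(vals, voxel_pitch_um=pitch, medium_ri=medium_ri)


def make_slab(delta_n: float, thickness_um: float, n: int, nz: int,
              pitch: float) -> RITomogram:
    vals = np.full((n, n, nz), MEDIUM_RI, dtype=np.float32)
    half = int(round(thickness_um / pitch / 2))
    z0 = nz // 2
    vals[:, :, z0 - half:z0 + half] = MEDIUM_RI + delta_n
    return RITomogram(vals, voxel_pitch_um=pitch)


@pytest.fixture(scope="session")
def bead4um():
    """4-um-diameter bead, n = 1.36, on a 96^3 grid at 0.1 um pitch."""
    return make_bead(2.0, 1.36, 96, 0.1)
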