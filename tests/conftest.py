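import numpy as np
import pytest

from lcrtrack.frames_io import Frame
from lcrtrack.segmentation import LCRImage, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(
    frame_index: int,
    image_id: int,
    voxels,
    signal_mass_nmol: float = 1e-15,
    n_peaks: int = 1,
    amplitude: float = 1.0,
) -> LCRImage:
    """Hand-built LCR image for tracker unit tests."""
    voxels = frozenset((int(r), int(c)) for r, c in voxels)
    anchor = sorted(voxels)[:n_peaks]
    peaks = tuple(Peak(voxel=v, amplitude=amplitude) for v in anchor)
    return LCRImage(
        frame_index=frame_index,
        image_id=image_id,
        voxels=voxels,
        peaks=peaks,
        signal_mass_nmol=signal_mass_nmol,
    )


def random_frame(rng, height, width, scale=1.0) -> Frame:
    return Frame(rng.random((height, width)) * scale)
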