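import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mbkit.io import ImageStack, RoiSpec, place_rois_inner50
from mbkit.synthetic import ContractionGroundTruth, gen_contraction_movie
from mbkit.tracking import TrackingParams, track_roi

#: scaled-down acquisition used throughout the tests: 0.5 um/px keeps full
#: 50 fps sampling while fitting many movies in one test session
PIXEL_SIZE = 0.5
FPS = 50.0


@pytest.fixture(scope="session")
def texture():
    """Band-limited random texture, contrast 30 on background 100."""
    rng = np.random.default_rng(0)
    base = gaussian_filter(rng.standard_normal((96, 96)), 2.0)
    return 100.0 + 30.0 * base / base.std()


@pytest.fixture(scope="session")
def beat_movie():
    """Short contracting-bundle movie (FS 5%, 0.4 Hz, 6 s) with ground truth."""
    truth = ContractionGroundTruth(fs_max=0.05, frequency_hz=0.4)
    stack, record = gen_contraction_movie(
        truth, pixel_size=PIXEL_SIZE, fps=FPS, duration_s=6.0, seed=1
    )
    return stack, record


@pytest.fixture(scope="session")
def tracked_pair(beat_movie):
    stack, record = beat_movie
    geo = record["geometry"]
    prox, dist = place_rois_inner50(geo, PIXEL_SIZE, 10, stack.frame_shape)
    params = TrackingParams(search_radius=12)
    return track_roi(stack, prox, params), track_roi(stack, dist, params), record


def make_stack(frames, pixel_size=PIXEL_SIZE, frame_interval=1.0 / FPS):
    return ImageStack(np.asarray(frames), pixel_size, frame_interval)


def center_roi(shape, half=10, label="proximal"):
    return RoiSpec((shape[1] // 2, shape[0] // 2), (half, half), label)
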