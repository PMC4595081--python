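import numpy as np
import pytest

from nemapose.config import RunConfig
from nemapose.edges import build_masks, detect_edges
from nemapose.synth import SceneSpec, render_scene, sample_posture

# study-scale geometry used throughout the suite: an L4-like animal of
# width 12 px and length 144 px in a 320 x 320 frame, coarse unit 3 px
WIDTH = 12.0
LENGTH = 144.0
FRAME = (320, 320)
UNIT = 3


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_masks():
    return build_masks(WIDTH)


def make_scene(family: str, seed: int = 0, *, contrast: float = 1.0,
               blur: float = 0.0, noise: float = 0.0, heading=None):
    post = sample_posture(family, length=LENGTH, width=WIDTH, seed=seed)
    post.position = (FRAME[0] / 2, FRAME[1] / 2)
    if heading is not None:
        post.heading = heading
    return render_scene(SceneSpec(posture=post, frame_shape=FRAME,
                                  contrast_scale=contrast, blur_sigma=blur,
                                  noise_sd=noise, seed=seed + 77))


@pytest.fixture(scope="session")
def straight_scene():
    """Clean vertical straight worm with ground truth."""
    return make_scene("straight", seed=1, heading=np.pi / 2)


@pytest.fixture(scope="session")
def straight_edges(straight_scene):
    img, _ = straight_scene
    return detect_edges(img, 5.0)


def stripe_image(width: int = 8, level_bg: float = 200.0,
                 level_fg: float = 60.0, size: int = 64) -> np.ndarray:
    """Vertical dark stripe of the given width on a bright background."""
    img = np.full((size, size), level_bg)
    a = size // 2 - width // 2
    img[:, a:a + width] = level_fg
    return img
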