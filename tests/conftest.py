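import numpy as np
import pytest

from dermseg import FixtureSpec, generate_fixture

#: Problem size used throughout the suite; large enough for a realistic
#: lesion-to-frame ratio, small enough to keep GrabCut runs in seconds.
FIXTURE_SIZE = (192, 192)


@pytest.fixture(scope="session")
def clean_fixture():
    """One artifact-free synthetic dermoscopy frame."""
    return generate_fixture(FixtureSpec(seed=0, size=FIXTURE_SIZE))


@pytest.fixture(scope="session")
def artifact_fixture():
    """One frame with corner borders and hairs."""
    return generate_fixture(FixtureSpec(seed=0, size=FIXTURE_SIZE, borders=True, hairs=True))


def frame_with_border(h: int, w: int, thickness: int, *, border_val: int = 0, body_val: int = 200) -> np.ndarray:
    """Uniform dark frame of the given thickness around a bright body."""
    img = np.full((h, w), body_val, dtype=np.uint8)
    t = thickness
    img[:t, :] = border_val
    img[-t:, :] = border_val
    img[:, :t] = border_val
    img[:, -t:] = border_val
    return img


def jaccard_of_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    p = pred == 255
    t = truth == 255
    union = (p | t).sum()
    return float((p & t).sum() / union) if union else 1.0
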