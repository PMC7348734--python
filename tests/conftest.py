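import numpy as np
import pytest

from lacpi.imaging import FrameStack, LayoutEntry, SurfaceLayout


@pytest.fixture
def small_layout() -> SurfaceLayout:
    """Two 9×9 ROIs inside a 64×64 frame."""
    return SurfaceLayout(
        [
            LayoutEntry("sample", "sample", 32, 16, 9),
            LayoutEntry("reference", "reference", 32, 48, 9),
        ]
    )


@pytest.fixture
def constant_stack() -> FrameStack:
    """Three 64×64 frames, every pixel 1000."""
    return FrameStack(
        frames=np.full((3, 64, 64), 1000, dtype=np.uint16),
        bit_depth=12,
        session_id="const",
    )


def make_stack(values: np.ndarray, bit_depth: int = 12, **kw) -> FrameStack:
    return FrameStack(frames=np.asarray(values), bit_depth=bit_depth, **kw)
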