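import numpy as np
import pytest

from splitpin import PinholeStack, SceneSpec, generate_stack


def random_stack(
    rng: np.random.Generator,
    n_frames: int | None = None,
    size: int | None = None,
    max_size: int = 64,
) -> PinholeStack:
    """A random nonnegative stack with strictly decreasing pinhole sizes."""
    n = n_frames or int(rng.integers(2, 5))
    h = size or int(rng.integers(8, max_size + 1))
    w = size or int(rng.integers(8, max_size + 1))
    frames = rng.uniform(0.0, 100.0, size=(n, h, w))
    sizes = tuple(np.sort(rng.uniform(0.2, 5.0, size=n))[::-1])
    return PinholeStack(frames=frames, pinhole_sizes=sizes)


@pytest.fixture(scope="session")
def default_scene():
    """Reference synthetic acquisition (seed 1) shared across tests."""
    return generate_stack(SceneSpec(), seed=1)


@pytest.fixture(scope="session")
def noiseless_scene():
    return generate_stack(SceneSpec(poisson=False), seed=1)
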