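import numpy as np
import pytest

from dentamorph import (BinaryMask, ProbabilityMap, ScalarVolume, SimShapeSpec,
                        simulate_dentated_cuboid)


@pytest.fixture(scope="session")
def dentated_spec():
    """A mid-grid dentated cuboid: A = 0.3 mm, F = 0.2 bumps/mm."""
    return SimShapeSpec(amplitude_mm=0.3, frequency_bpm=0.2, phase_rad=0.7)


@pytest.fixture(scope="session")
def dentated_mask(dentated_spec):
    return simulate_dentated_cuboid(dentated_spec)


@pytest.fixture(scope="session")
def coarse_spec():
    """A strongly dentated, low-frequency shape used for pipeline tests."""
    return SimShapeSpec(amplitude_mm=0.4, frequency_bpm=0.1, phase_rad=1.3)


@pytest.fixture(scope="session")
def coarse_mask(coarse_spec):
    return simulate_dentated_cuboid(coarse_spec)


def make_ball(radius_vox: float, n: int, spacing: float = 1.0,
              smooth: bool = False):
    """Digital ball mask (or partial-volume probability ball)."""
    c = (n - 1) / 2
    idx = np.arange(n)
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
    if smooth:
        data = np.clip(radius_vox + 0.5 - r, 0.0, 1.0)
        return ProbabilityMap(data=data, spacing_mm=spacing)
    return BinaryMask(data=(r <= radius_vox).astype(np.uint8),
                      spacing_mm=spacing)


@pytest.fixture
def zero_image():
    def _make(shape, spacing=1.0):
        return ScalarVolume(data=np.zeros(shape), spacing_mm=spacing)
    return _make
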