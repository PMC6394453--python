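import numpy as np
import pytest

from petstrat.volume_io import PetVolume, Units, VoiMask


def make_volume(values, spacing=(1.0, 1.0, 1.0), units=Units.SUV) -> PetVolume:
    return PetVolume(values=np.asarray(values, dtype=float), spacing=spacing, units=units)


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), label="lesion") -> VoiMask:
    return VoiMask(voxels=np.asarray(voxels, dtype=bool), spacing=spacing, label=label)


def random_masked_volume(seed: int, shape=(8, 8, 8), mask_p=0.6):
    """A random SUV volume and random mask, reproducible per seed."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 12.0, size=shape)
    mask = rng.random(shape) < mask_p
    if mask.sum() < 8:  # guarantee a usable VOI
        mask[:2, :2, :2] = True
    return make_volume(values), make_mask(mask)


@pytest.fixture
def line_voi():
    """1×1×4 line whose SUVs quantize to levels [1, 1, 2, 2] at G = 2."""
    vol = make_volume(np.array([[[0.0, 0.0, 10.0, 10.0]]]))
    mask = make_mask(np.ones((1, 1, 4), dtype=bool))
    return vol, mask


@pytest.fixture
def uniform_voi():
    vol = make_volume(np.full((6, 6, 6), 4.2))
    mask = make_mask(np.ones((6, 6, 6), dtype=bool))
    return vol, mask
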