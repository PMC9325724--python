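import numpy as np
import pytest

from fetalrad.imaging import QuantizedPatch


def make_patch(levels: np.ndarray, n_levels: int | None = None,
               mask: np.ndarray | None = None) -> QuantizedPatch:
    """Quantized patch straight from a level array (levels already 1..Ng)."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    return QuantizedPatch(
        levels=np.where(mask, levels, 0),
        mask=np.asarray(mask, bool),
        n_levels=n_levels or int(levels.max()),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_patches(rng):
    """Random 6x6 patches with 4 grey levels and occasional masked pixels."""
    patches = []
    for k in range(30):
        levels = rng.integers(1, 5, size=(6, 6))
        mask = np.ones((6, 6), bool)
        if k % 3 == 0:  # some patches get an irregular mask
            mask[rng.random((6, 6)) < 0.2] = False
            if mask.sum() < 4:
                mask[:] = True
        patches.append(make_patch(levels, n_levels=4, mask=mask))
    return patches
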