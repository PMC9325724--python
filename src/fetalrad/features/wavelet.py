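"""Single-level 2-D discrete wavelet decomposition of the ROI crop.

The mask bounding-box crop is decomposed with an orthonormal Haar transform
(zero-padded borders) into approximation (LL), horizontal (LH), vertical
(HL) and diagonal (HH) sub-bands; the mask is downsampled to sub-band
resolution (a coefficient is in-mask when any pixel of its 2x2 support is).
Out-of-mask pixels inside the bounding box are filled with the in-mask mean
before the transform so background intensity does not leak into the
coefficients. For an even-sized crop the transform is orthonormal, so total
sub-band energy equals crop energy.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..errors import DegenerateROIError
from ..imaging import GreyImage, ROIMask

SUB_BANDS = ("approximation", "horizontal", "vertical", "diagonal")

MIN_BBOX = 8


def wavelet_subbands(
    image: GreyImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    wavelet: str = "haar",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sub-band coefficient rasters with their downsampled masks.

    Returns ``{band: (coefficients, mask)}`` for the four level-1 bands.
    Raises :class:`DegenerateROIError` if the mask bounding box is smaller
    than 8x8.
    """
    px = image.pixels if isinstance(image, GreyImage) else np.asarray(image, float)
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0 or rows.size < MIN_BBOX or cols.size < MIN_BBOX:
        raise DegenerateROIError(
            f"mask bounding box {rows.size}x{cols.size} smaller than {MIN_BBOX}x{MIN_BBOX}"
        )
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = px[r0:r1, c0:c1].astype(np.float64)
    crop_mask = m[r0:r1, c0:c1]
    fill = crop[crop_mask].mean()
    crop = np.where(crop_mask, crop, fill)

    ll, (lh, hl, hh) = pywt.dwt2(crop, wavelet, mode="zero")
    # 2x-downsampled mask: in-mask if any source pixel of the 2x2 block is
    hpad = (-crop_mask.shape[0]) % 2
    wpad = (-crop_mask.shape[1]) % 2
    mp = np.pad(crop_mask, ((0, hpad), (0, wpad)))
    sub_mask = mp.reshape(mp.shape[0] // 2, 2, mp.shape[1] // 2, 2).any(axis=(1, 3))
    sub_mask = sub_mask[: ll.shape[0], : ll.shape[1]]
    # pywt names: LH = horizontal detail, HL = vertical detail
    return {
        "approximation": (ll, sub_mask),
        "horizontal": (lh, sub_mask),
        "vertical": (hl, sub_mask),
        "diagonal": (hh, sub_mask),
    }
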