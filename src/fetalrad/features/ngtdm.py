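"""Neighbourhood grey-tone difference matrix (NGTDM) features.

For every in-mask pixel with at least one in-mask 8-neighbour, the absolute
difference between its level and the mean level of those neighbours is
accumulated per grey level: ``s(i) = sum |i - nbr_mean|`` over pixels of
level ``i``. Coarseness, contrast, busyness, complexity and strength follow
the canonical Amadasun-King definitions, with 0/0 guarded to 0.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate

from ..errors import DegenerateROIError
from ..imaging import QuantizedPatch

_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)
_EPS = np.finfo(float).tiny


def ngtdm_table(patch: QuantizedPatch) -> tuple[np.ndarray, np.ndarray]:
    """Per-level tone-difference sums ``s(i)`` and pixel counts ``n(i)``."""
    lev = patch.levels.astype(np.float64)
    mask = patch.mask.astype(np.float64)
    nbr_sum = correlate(lev * mask, _KERNEL, mode="constant", cval=0.0)
    nbr_cnt = correlate(mask, _KERNEL, mode="constant", cval=0.0)
    valid = patch.mask & (nbr_cnt > 0)
    if not valid.any():
        raise DegenerateROIError("no in-mask pixel has an in-mask neighbour")
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr_mean = np.where(nbr_cnt > 0, nbr_sum / nbr_cnt, 0.0)
    diff = np.abs(lev - nbr_mean)
    ng = patch.n_levels
    s = np.zeros(ng)
    n = np.zeros(ng)
    idx = patch.levels[valid] - 1
    np.add.at(s, idx, diff[valid])
    np.add.at(n, idx, 1.0)
    return s, n


def ngtdm_features(patch: QuantizedPatch) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength of a patch."""
    s, n = ngtdm_table(patch)
    total = n.sum()
    p = n / total
    present = p > 0
    ngp = int(present.sum())  # number of occupied grey levels
    i = np.arange(1, patch.n_levels + 1, dtype=np.float64)

    coarse_denom = float((p * s).sum())
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 0.0

    if ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        di = i[:, None] - i[None, :]
        contrast = float(
            (pi * pj * di**2).sum() / (ngp * (ngp - 1)) * s.sum() / total
        )
        busy_denom = float(
            np.abs(i[present][:, None] * p[present][:, None]
                   - i[present][None, :] * p[present][None, :]).sum()
        )
        busyness = coarse_denom / busy_denom if busy_denom > 0 else 0.0
        ip = i[present]
        pp = p[present]
        num = np.abs(ip[:, None] - ip[None, :]) * (
            pp[:, None] * s[present][:, None] + pp[None, :] * s[present][None, :]
        ) / (pp[:, None] + pp[None, :])
        complexity = float(num.sum() / total)
        strength_num = float(
            ((pp[:, None] + pp[None, :]) * (ip[:, None] - ip[None, :]) ** 2).sum()
        )
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


NGTDM_FEATURE_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
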