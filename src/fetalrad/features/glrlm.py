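"""Grey-level run-length matrix (GLRLM) and scalar features.

A run is a maximal sequence of pixels of equal quantized level along one of
the four standard directions; runs are truncated at the mask boundary.
Scalar features are computed per direction and averaged, matching the
direction-averaged construction used for the co-occurrence features.
"""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateROIError
from ..imaging import QuantizedPatch

#: (row step, col step) for 0, 45, 90, 135 degrees.
RUN_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _lines(shape: tuple[int, int], direction: tuple[int, int]):
    """Index arrays of every scan line of ``shape`` along ``direction``."""
    h, w = shape
    dr, dc = direction
    rows, cols = np.mgrid[0:h, 0:w]
    if (dr, dc) == (0, 1):
        key = rows
        order = cols
    elif (dr, dc) == (-1, 0):
        key = cols
        order = -rows
    elif (dr, dc) == (-1, 1):
        key = rows + cols  # anti-diagonals, traversed up-right
        order = cols
    else:  # (-1, -1): main diagonals, traversed up-left
        key = rows - cols
        order = -cols
    flat = np.lexsort((order.ravel(), key.ravel()))
    starts = np.flatnonzero(np.diff(key.ravel()[flat], prepend=key.ravel()[flat][0] - 1))
    return flat, np.append(starts, flat.size)


def glrlm_matrix(
    patch: QuantizedPatch,
    directions: tuple[tuple[int, int], ...] = RUN_DIRECTIONS,
) -> list[np.ndarray]:
    """Per-direction run-length count matrices, shape ``(Ng, Nr)``.

    ``Nr`` is the longest possible run (max patch dimension). Out-of-mask
    pixels break runs exactly like a level change.
    """
    lev, mask = patch.levels, patch.mask
    if not mask.any():
        raise DegenerateROIError("empty mask")
    ng = patch.n_levels
    nr = max(lev.shape)
    values = np.where(mask, lev, 0).ravel()
    out = []
    for d in directions:
        flat, bounds = _lines(lev.shape, d)
        counts = np.zeros((ng, nr), dtype=np.float64)
        for s, e in zip(bounds[:-1], bounds[1:]):
            line = values[flat[s:e]]
            # maximal equal-value segments of the line
            change = np.flatnonzero(np.diff(line)) + 1
            seg_starts = np.concatenate(([0], change))
            seg_ends = np.concatenate((change, [line.size]))
            for a, b in zip(seg_starts, seg_ends):
                v = line[a]
                if v > 0:
                    counts[v - 1, b - a - 1] += 1
        out.append(counts)
    return out


def glrlm_features_single(counts: np.ndarray) -> dict[str, float]:
    """Run-length features of one direction's count matrix."""
    total = counts.sum()
    if total == 0:
        raise DegenerateROIError("run-length matrix has no runs")
    p = counts / total
    ng, nr = p.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nr + 1, dtype=np.float64)[None, :]
    p_i = p.sum(axis=1, keepdims=True)
    p_j = p.sum(axis=0, keepdims=True)
    mu_i = float((i * p_i).sum())
    mu_j = float((j * p_j).sum())
    n_pixels = float((counts * j).sum())
    nz = p[p > 0]
    return {
        "Short-run emphasis": float((p / j**2).sum()),
        "Long-run emphasis": float((p * j**2).sum()),
        "Grey-level non-uniformity": float((counts.sum(axis=1) ** 2).sum() / total),
        "Grey-level non-uniformity normalized": float((p.sum(axis=1) ** 2).sum()),
        "Run-length non-uniformity": float((counts.sum(axis=0) ** 2).sum() / total),
        "Run-length non-uniformity normalized": float((p.sum(axis=0) ** 2).sum()),
        "Run percentage": float(total / n_pixels),
        "Grey-level variance": float((p * (i - mu_i) ** 2).sum()),
        "Run-length variance": float((p * (j - mu_j) ** 2).sum()),
        "Run entropy": float(-(nz * np.log2(nz)).sum()),
        "Low grey-level run emphasis": float((p / i**2).sum()),
        "High grey-level run emphasis": float((p * i**2).sum()),
        "Short-run low grey-level emphasis": float((p / (i**2 * j**2)).sum()),
        "Short-run high grey-level emphasis": float((p * i**2 / j**2).sum()),
        "Long-run low grey-level emphasis": float((p * j**2 / i**2).sum()),
        "Long-run high grey-level emphasis": float((p * i**2 * j**2).sum()),
    }


def glrlm_features(matrices: list[np.ndarray]) -> dict[str, float]:
    """Direction-averaged run-length features."""
    per_dir = [glrlm_features_single(m) for m in matrices]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


GLRLM_FEATURE_NAMES = tuple(
    glrlm_features_single(np.array([[1.0, 1.0], [1.0, 1.0]])).keys()
)
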