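"""Grey-level co-occurrence matrix (GLCM) and its scalar features.

The GLCM is the joint distribution of quantized grey-level pairs at a fixed
pixel offset. Here it is built per offset on the in-mask pixels only (pairs
with either endpoint outside the mask are excluded), symmetrised by counting
both directions, normalized to sum to one, and averaged over the four
standard 2-D directions 0/45/90/135 degrees. Scalar features follow the
canonical co-occurrence definitions; direction-averaged contrast and
covariance are exposed under the "Mean of ..." names used in the catalog.
"""

from __future__ import annotations

import numpy as np

from ..errors import ContractViolation, DegenerateROIError
from ..imaging import QuantizedPatch

#: (row step, col step) for 0, 45, 90, 135 degrees in image coordinates.
ANGLE_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EPS = np.finfo(float).tiny


def glcm_matrix(
    patch: QuantizedPatch,
    distance: int = 1,
    angles: tuple[tuple[int, int], ...] = ANGLE_OFFSETS,
) -> np.ndarray:
    """Symmetric normalized GLCM averaged over ``angles`` at ``distance``.

    Returns an ``(Ng, Ng)`` matrix summing to 1. Raises
    :class:`DegenerateROIError` when no offset yields a valid in-mask pair.
    """
    if distance < 1:
        raise ContractViolation(f"distance must be >= 1, got {distance}")
    ng = patch.n_levels
    lev, mask = patch.levels, patch.mask
    h, w = lev.shape
    per_angle = []
    for dr, dc in angles:
        dr, dc = dr * distance, dc * distance
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        if r0s >= r0e or c0s >= c0e:
            continue
        a = lev[r0s:r0e, c0s:c0e]
        b = lev[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        if not valid.any():
            continue
        i, j = a[valid] - 1, b[valid] - 1
        counts = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(counts, (i, j), 1.0)
        counts += counts.T  # count both directions -> symmetric
        per_angle.append(counts / counts.sum())
    if not per_angle:
        raise DegenerateROIError("mask too thin: no valid co-occurrence pairs")
    return np.mean(per_angle, axis=0)


def _check_normalized(p: np.ndarray) -> None:
    if p.ndim != 2 or p.shape[0] != p.shape[1] or not np.isclose(p.sum(), 1.0):
        raise ContractViolation("glcm must be square and normalized to sum 1")


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """Scalar co-occurrence features of a normalized GLCM.

    All guards map degenerate cases (single occupied level, zero marginal
    entropy) to 0 so that downstream vectors stay finite.
    """
    _check_normalized(p)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    sd_i = float(np.sqrt(((ii - mu_i) ** 2 * p).sum()))
    sd_j = float(np.sqrt(((jj - mu_j) ** 2 * p).sum()))

    # diagonal-sum distribution p_{x+y}(k), k = 2..2Ng
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    # anti-diagonal difference distribution p_{x-y}(k), k = 0..Ng-1
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    idx_sum = (ii + jj - 2).astype(int)
    idx_diff = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, idx_sum.ravel(), p.ravel())
    np.add.at(p_diff, idx_diff.ravel(), p.ravel())

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.nansum(np.where(p > 0, p * np.log2(px[:, None] * py[None, :] + _EPS), 0.0)))
        outer = px[:, None] * py[None, :]
        hxy2 = float(-np.nansum(np.where(outer > 0, outer * np.log2(outer), 0.0)))

    diff = ii - jj
    contrast = float(((diff**2) * p).sum())
    covariance = float(((ii - mu_i) * (jj - mu_j) * p).sum())
    correlation = covariance / (sd_i * sd_j) if sd_i > 0 and sd_j > 0 else 0.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))
    sum_avg = float((k_sum * p_sum).sum())
    diff_avg = float((k_diff * p_diff).sum())
    inv_var_mask = idx_diff > 0
    inv_var = float((p[inv_var_mask] / (idx_diff[inv_var_mask] ** 2)).sum()) if inv_var_mask.any() else 0.0

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "Joint average": mu_i,
        "Cluster prominence": float(((ii + jj - mu_i - mu_j) ** 4 * p).sum()),
        "Cluster shade": float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()),
        "Cluster tendency": float(((ii + jj - mu_i - mu_j) ** 2 * p).sum()),
        "Mean of contrast": contrast,
        "Correlation": correlation,
        "Mean of covariance": covariance,
        "Difference average": diff_avg,
        "Difference entropy": ent(p_diff),
        "Difference variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Joint energy": float((p**2).sum()),
        "Joint entropy": hxy,
        "Information measure of correlation 1": imc1,
        "Information measure of correlation 2": imc2,
        "Inverse difference moment": float((p / (1.0 + diff**2)).sum()),
        "Inverse difference moment normalized": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "Inverse difference": float((p / (1.0 + np.abs(diff))).sum()),
        "Inverse difference normalized": float((p / (1.0 + np.abs(diff) / ng)).sum()),
        "Inverse variance": inv_var,
        "Maximum probability": float(p.max()),
        "Sum average": sum_avg,
        "Sum entropy": ent(p_sum),
        "Sum variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "Sum of squares": float(((ii - mu_i) ** 2 * p).sum()),
        "Dissimilarity": float((np.abs(diff) * p).sum()),
    }


#: Names emitted by :func:`glcm_features`, in catalog order.
GLCM_FEATURE_NAMES = tuple(glcm_features(np.full((2, 2), 0.25)).keys())
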