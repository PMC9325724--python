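"""Whole-catalog feature extraction for one image + ROI."""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateROIError, FetalRadError
from ..imaging import DEFAULT_LEVELS, GreyImage, QuantizedPatch, ROIMask, quantize
from .catalog import (
    GLCM_D2_TEXTURE,
    GLCM_D2_WAVELET,
    CatalogEntry,
    default_catalog,
)
from .firstorder import firstorder_features
from .glcm import glcm_features, glcm_matrix
from .glrlm import glrlm_features, glrlm_matrix
from .morphology import morphological_features
from .ngtdm import ngtdm_features
from .wavelet import SUB_BANDS, wavelet_subbands

#: Relaxed foreground floor for half-resolution sub-band masks.
SUBBAND_MIN_PIXELS = 16


def _matrix_family(patch: QuantizedPatch, d2_subset: tuple[str, ...]) -> dict[str, float]:
    """Co-occurrence (d=1, d=2), run-length and grey-tone features."""
    out: dict[str, float] = {}
    out.update(glcm_features(glcm_matrix(patch, distance=1)))
    d2 = glcm_features(glcm_matrix(patch, distance=2))
    out.update({f"{k} (distance 2)": d2[k] for k in d2_subset})
    out.update(glrlm_features(glrlm_matrix(patch)))
    out.update(ngtdm_features(patch))
    return out


def extract_all(
    image: GreyImage,
    mask: ROIMask,
    catalog: list[CatalogEntry] | None = None,
    n_levels: int = DEFAULT_LEVELS,
    wavelet: str = "haar",
) -> dict[str, float]:
    """Compute every catalog feature for one image + ROI.

    Returns an ordered ``{name: value}`` mapping matching the catalog.
    Deterministic given the inputs; values are always finite (formula-level
    guards map degenerate cases to 0). A family whose ROI is unusable
    raises :class:`DegenerateROIError` naming the family.
    """
    catalog = catalog or default_catalog()
    values: dict[str, float] = {}

    try:
        values.update(morphological_features(mask))
    except FetalRadError as exc:
        raise DegenerateROIError(f"morphological features: {exc}") from exc

    try:
        raw = image.pixels[mask.mask].astype(np.float64)
        values.update(firstorder_features(raw))
        patch = quantize(image, mask, n_levels=n_levels)
        values.update(_matrix_family(patch, GLCM_D2_TEXTURE))
    except FetalRadError as exc:
        raise DegenerateROIError(f"texture features: {exc}") from exc

    try:
        bands = wavelet_subbands(image, mask, wavelet=wavelet)
        energies = {}
        for band in SUB_BANDS:
            coeffs, sub_mask = bands[band]
            vals = coeffs[sub_mask]
            energies[band] = float((vals**2).sum())
            fo = firstorder_features(vals)
            values.update({f"{k} of {band}": v for k, v in fo.items()})
            sub_patch = quantize(
                coeffs, sub_mask, n_levels=n_levels, min_pixels=SUBBAND_MIN_PIXELS
            )
            fam = _matrix_family(sub_patch, GLCM_D2_WAVELET)
            values.update({f"{k} of {band}": v for k, v in fam.items()})
        total_e = sum(energies.values())
        detail_e = total_e - energies["approximation"]
        values["Detail energy fraction"] = detail_e / total_e if total_e > 0 else 0.0
        q = np.array([energies[b] for b in SUB_BANDS]) / total_e if total_e > 0 else np.zeros(4)
        qnz = q[q > 0]
        values["Sub-band energy entropy"] = float(-(qnz * np.log2(qnz)).sum()) if qnz.size else 0.0
    except FetalRadError as exc:
        raise DegenerateROIError(f"wavelet features: {exc}") from exc

    ordered = {e.name: float(values[e.name]) for e in catalog}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    assert not bad, f"non-finite feature values: {bad[:5]}"
    return ordered
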