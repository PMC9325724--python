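"""Morphological (shape) features of an ROI mask.

Built on ``skimage.measure.regionprops`` of the largest connected
component. 2-D analogues are used for the volume-based shape descriptors:
circularity = 4*pi*A/P^2, compactness = P^2/A, sphericity analogue =
2*sqrt(pi*A)/P (equals 1 for a perfect disk).
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label, regionprops

from ..errors import DegenerateROIError
from ..imaging import ROIMask


def morphological_features(mask: ROIMask | np.ndarray) -> dict[str, float]:
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise DegenerateROIError("empty mask")
    lab = label(m, connectivity=2)
    props = max(regionprops(lab), key=lambda r: r.area)
    area = float(props.area)
    perim = float(props.perimeter) if props.perimeter > 0 else 1.0
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    bb = props.bbox  # (r0, c0, r1, c1)
    bb_h, bb_w = bb[2] - bb[0], bb[3] - bb[1]
    return {
        "Area": area,
        "Perimeter": perim,
        "Equivalent diameter": float(props.equivalent_diameter_area),
        "Eccentricity": float(props.eccentricity),
        "Solidity": float(props.solidity),
        "Extent": float(props.extent),
        "Major axis length": major,
        "Minor axis length": minor,
        "Circularity": 4.0 * np.pi * area / perim**2,
        "Convex area": float(props.area_convex),
        "Bounding-box aspect ratio": max(bb_h, bb_w) / max(min(bb_h, bb_w), 1),
        "Compactness": perim**2 / area,
        "Elongation": minor / major if major > 0 else 1.0,
        "Sphericity analogue": 2.0 * np.sqrt(np.pi * area) / perim,
        "Perimeter-to-area ratio": perim / area,
    }


MORPHOLOGY_FEATURE_NAMES = tuple(
    morphological_features(np.pad(np.ones((10, 10), bool), 2)).keys()
)
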