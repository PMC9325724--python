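"""First-order (histogram) statistics of in-mask or sub-band values.

Population (not sample) moments throughout; skewness and kurtosis are
guarded to 0 when the standard deviation is 0; entropy and uniformity use a
16-bin min-max histogram of the values.
"""

from __future__ import annotations

import numpy as np

from ..errors import ContractViolation

ENTROPY_BINS = 16


def firstorder_features(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ContractViolation(f"need >= 2 values, got {values.size}")
    mean = float(values.mean())
    var = float(values.var())  # population variance
    sd = float(np.sqrt(var))
    centered = values - mean
    skew = float((centered**3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float((centered**4).mean() / sd**4) if sd > 0 else 0.0
    if values.max() > values.min():
        hist, _ = np.histogram(values, bins=ENTROPY_BINS)
        pk = hist[hist > 0] / values.size
        entropy = float(-(pk * np.log2(pk)).sum())
        uniformity = float((pk**2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    return {
        "Mean": mean,
        "Variance": var,
        "Standard deviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((values**2).sum()),
        "Entropy": entropy,
        "Range": float(values.max() - values.min()),
        "Mean absolute deviation": float(np.abs(centered).mean()),
        "Median": float(np.median(values)),
        "Minimum": float(values.min()),
        "Maximum": float(values.max()),
        "Root mean square": float(np.sqrt((values**2).mean())),
        "Uniformity": uniformity,
    }


FIRSTORDER_FEATURE_NAMES = tuple(firstorder_features(np.array([0.0, 1.0])).keys())
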