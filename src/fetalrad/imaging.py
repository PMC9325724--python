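"""Image and ROI handling: readers, grey-level quantization, square masks.

Conventions used throughout the package: rasters are row-major 2-D numpy
arrays indexed ``[row, col]``, 0-based; windows are half-open. A region of
interest (ROI) is a boolean raster congruent with its image. Quantized
patches carry integer grey levels ``1..n_levels`` inside the mask and the
sentinel 0 outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DegenerateROIError, GeometryError, ImageIOError

log = logging.getLogger(__name__)

#: Side length of the fixed square delineation, in pixels.
SQUARE_SIDE = 40

#: Minimum foreground pixel count for a usable ROI.
MIN_ROI_PIXELS = 64

#: Default grey-level count for matrix-based texture features.
DEFAULT_LEVELS = 16


@dataclass(frozen=True)
class GreyImage:
    """Single-channel non-negative intensity raster."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ConfigurationError(f"image must be 2-D, got shape {px.shape}")
        if px.shape[0] < SQUARE_SIDE or px.shape[1] < SQUARE_SIDE:
            raise ConfigurationError(
                f"image must be at least {SQUARE_SIDE}x{SQUARE_SIDE}, got {px.shape}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIMask:
    """Boolean raster marking the analysed lung patch.

    ``provenance`` records which delineation produced the mask:
    ``freehand_A`` / ``freehand_B`` (manual polygon) or ``square40``.
    """

    mask: np.ndarray
    provenance: str = "freehand_A"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ConfigurationError(f"mask must be 2-D, got shape {m.shape}")
        n_fg = int(m.sum())
        if n_fg < MIN_ROI_PIXELS:
            raise DegenerateROIError(
                f"ROI has {n_fg} foreground pixels, need >= {MIN_ROI_PIXELS}"
            )
        if self.provenance == "square40":
            rows = np.flatnonzero(m.any(axis=1))
            cols = np.flatnonzero(m.any(axis=0))
            ok = (
                n_fg == SQUARE_SIDE * SQUARE_SIDE
                and rows.size == SQUARE_SIDE
                and cols.size == SQUARE_SIDE
            )
            if not ok:
                raise GeometryError("square40 mask must be a contiguous 40x40 square")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass(frozen=True)
class QuantizedPatch:
    """Integer raster with grey levels ``1..n_levels`` in-mask, 0 outside."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def load_image(path: str | Path) -> GreyImage:
    """Read a DICOM (.dcm) or raster (PNG/TIFF/...) file as a grey image.

    Multi-channel rasters are collapsed to one channel by averaging the
    channels (logged). Raises :class:`ImageIOError` naming the path if the
    file is missing, unreadable or empty.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    if path.suffix.lower() == ".dcm":
        import pydicom

        try:
            ds = pydicom.dcmread(path)
            px = ds.pixel_array
        except Exception as exc:  # pragma: no cover - backend specific
            raise ImageIOError(f"cannot read DICOM file {path}: {exc}") from exc
        bit_depth = int(getattr(ds, "BitsStored", 8) or 8)
    else:
        from PIL import Image

        try:
            with Image.open(path) as im:
                px = np.asarray(im)
        except Exception as exc:
            raise ImageIOError(f"cannot read image file {path}: {exc}") from exc
        bit_depth = 16 if px.dtype == np.uint16 else 8
    if px.size == 0:
        raise ImageIOError(f"zero-size image: {path}")
    if px.ndim == 3:
        log.warning("multi-channel image %s collapsed by channel average", path)
        px = px.astype(np.float64).mean(axis=2)
    return GreyImage(pixels=np.asarray(px), bit_depth=bit_depth)


def load_mask(path: str | Path, provenance: str = "freehand_A") -> ROIMask:
    """Read a mask raster; any nonzero pixel is foreground."""
    img = load_image(path)
    return ROIMask(mask=img.pixels > 0, provenance=provenance)


def quantize(
    image: GreyImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    n_levels: int = DEFAULT_LEVELS,
    min_pixels: int = MIN_ROI_PIXELS,
) -> QuantizedPatch:
    """Uniform min-max binning of in-mask intensities into ``n_levels`` bins.

    Bins are right-open with the maximum intensity assigned to the top bin;
    a constant patch maps entirely to level 1. Accepts either the dataclass
    wrappers or bare arrays (used on wavelet sub-bands, where ``min_pixels``
    is relaxed because sub-band resolution is halved).
    """
    if n_levels < 2:
        raise ConfigurationError(f"n_levels must be >= 2, got {n_levels}")
    px = image.pixels if isinstance(image, GreyImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if px.shape != m.shape:
        raise ConfigurationError(f"image {px.shape} and mask {m.shape} differ in shape")
    n_fg = int(m.sum())
    if n_fg < min_pixels:
        raise DegenerateROIError(f"ROI has {n_fg} pixels, need >= {min_pixels}")
    vals = px[m].astype(np.float64)
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(px.shape, dtype=np.int64)
    if hi == lo:
        levels[m] = 1
    else:
        binned = np.floor((px[m] - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        levels[m] = np.clip(binned, 1, n_levels)
    return QuantizedPatch(levels=levels, mask=m, n_levels=n_levels)


def square_mask(center: tuple[int, int], image: GreyImage) -> ROIMask:
    """Axis-aligned 40x40 square ROI centered at ``center`` (row, col).

    The window spans ``center - 20 .. center + 20`` (half-open) on each
    axis; it must fit inside the image.
    """
    r, c = center
    half = SQUARE_SIDE // 2
    r0, r1 = r - half, r + half
    c0, c1 = c - half, c + half
    h, w = image.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise GeometryError(
            f"40x40 window at center ({r},{c}) exceeds image bounds {h}x{w}"
        )
    m = np.zeros((h, w), dtype=bool)
    m[r0:r1, c0:c1] = True
    return ROIMask(mask=m, provenance="square40")
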