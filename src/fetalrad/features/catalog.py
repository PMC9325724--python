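"""The default 430-feature catalog: 15 morphological, 73 texture, 342 wavelet.

Composition of the default catalog (configuration, documented in
``docs/methods.md``):

* morphological (15): shape descriptors of the ROI mask;
* texture (73), on the quantized ROI: 14 first-order statistics of raw
  in-mask intensities, 26 co-occurrence features at distance 1, a 12-feature
  co-occurrence subset at distance 2, 16 run-length features, 5
  neighbourhood grey-tone difference features;
* wavelet (342): per level-1 Haar sub-band (approximation / horizontal /
  vertical / diagonal) the 14 first-order, 26 + 24 co-occurrence
  (distances 1 and 2), 16 run-length and 5 grey-tone features (85 x 4 =
  340), plus 2 sub-band energy summaries (detail energy fraction and
  sub-band energy entropy).

Wavelet feature names follow the "<feature> of <sub-band>" convention;
direction-averaged co-occurrence contrast and covariance carry the
"Mean of" prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .firstorder import FIRSTORDER_FEATURE_NAMES
from .glcm import GLCM_FEATURE_NAMES
from .glrlm import GLRLM_FEATURE_NAMES
from .morphology import MORPHOLOGY_FEATURE_NAMES
from .ngtdm import NGTDM_FEATURE_NAMES
from .wavelet import SUB_BANDS

#: Distance-2 co-occurrence subset used in the texture family.
GLCM_D2_TEXTURE = (
    "Autocorrelation",
    "Mean of contrast",
    "Correlation",
    "Mean of covariance",
    "Difference entropy",
    "Joint energy",
    "Joint entropy",
    "Information measure of correlation 1",
    "Inverse difference moment normalized",
    "Maximum probability",
    "Sum entropy",
    "Sum variance",
)

#: Distance-2 co-occurrence subset used per wavelet sub-band.
GLCM_D2_WAVELET = tuple(
    n for n in GLCM_FEATURE_NAMES
    if n not in ("Information measure of correlation 2", "Inverse variance")
)

#: Catalog-level wavelet energy summaries.
WAVELET_GLOBAL = ("Detail energy fraction", "Sub-band energy entropy")


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    family: str  # morphological | texture | wavelet
    sub_band: str  # none | approximation | horizontal | vertical | diagonal
    formula_id: str


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_").replace("-", "_").replace("(", "").replace(")", "")


def default_catalog() -> list[CatalogEntry]:
    """The ordered default catalog; family counts (15, 73, 342)."""
    entries: list[CatalogEntry] = []
    for n in MORPHOLOGY_FEATURE_NAMES:
        entries.append(CatalogEntry(n, "morphological", "none", f"morph.{_slug(n)}"))

    for n in FIRSTORDER_FEATURE_NAMES:
        entries.append(CatalogEntry(n, "texture", "none", f"fo.{_slug(n)}"))
    for n in GLCM_FEATURE_NAMES:
        entries.append(CatalogEntry(n, "texture", "none", f"glcm.d1.{_slug(n)}"))
    for n in GLCM_D2_TEXTURE:
        entries.append(
            CatalogEntry(f"{n} (distance 2)", "texture", "none", f"glcm.d2.{_slug(n)}")
        )
    for n in GLRLM_FEATURE_NAMES:
        entries.append(CatalogEntry(n, "texture", "none", f"glrlm.{_slug(n)}"))
    for n in NGTDM_FEATURE_NAMES:
        entries.append(CatalogEntry(n, "texture", "none", f"ngtdm.{_slug(n)}"))

    for band in SUB_BANDS:
        for n in FIRSTORDER_FEATURE_NAMES:
            entries.append(
                CatalogEntry(f"{n} of {band}", "wavelet", band, f"fo.{_slug(n)}")
            )
        for n in GLCM_FEATURE_NAMES:
            entries.append(
                CatalogEntry(f"{n} of {band}", "wavelet", band, f"glcm.d1.{_slug(n)}")
            )
        for n in GLCM_D2_WAVELET:
            entries.append(
                CatalogEntry(
                    f"{n} (distance 2) of {band}", "wavelet", band, f"glcm.d2.{_slug(n)}"
                )
            )
        for n in GLRLM_FEATURE_NAMES:
            entries.append(
                CatalogEntry(f"{n} of {band}", "wavelet", band, f"glrlm.{_slug(n)}")
            )
        for n in NGTDM_FEATURE_NAMES:
            entries.append(
                CatalogEntry(f"{n} of {band}", "wavelet", band, f"ngtdm.{_slug(n)}")
            )
    for n in WAVELET_GLOBAL:
        entries.append(CatalogEntry(n, "wavelet", "none", f"wav.global.{_slug(n)}"))

    names = [e.name for e in entries]
    assert len(names) == len(set(names)), "catalog names must be unique"
    return entries


def catalog_names(entries: list[CatalogEntry] | None = None) -> list[str]:
    return [e.name for e in (entries or default_catalog())]


def family_counts(entries: list[CatalogEntry] | None = None) -> dict[str, int]:
    counts: dict[str, int] = {}
    for e in entries or default_catalog():
        counts[e.family] = counts.get(e.family, 0) + 1
    return counts


#: The 20 radiomics feature names reported as selected in the study,
#: all present verbatim in the default catalog.
TABLE4_RADIOMICS = (
    "Run-length variance",
    "Short-run high grey-level emphasis",
    "Skewness of diagonal",
    "Mean of contrast of approximation",
    "Energy of vertical",
    "Busyness of diagonal",
    "Complexity of vertical",
    "Grey-level variance of diagonal",
    "Grey-level variance of vertical",
    "Mean of contrast of diagonal",
    "Short-run high grey-level emphasis of diagonal",
    "Variance of vertical",
    "Variance of approximation",
    "Mean of covariance of diagonal",
    "Sum entropy of diagonal",
    "Information measure of correlation 1 of approximation",
    "Inverse difference moment normalized of approximation",
    "Standard deviation of approximation",
    "Mean of covariance of horizontal",
    "Mean of covariance of vertical",
)

#: The two clinical covariates appended after radiomics selection.
CLINICAL_FEATURES = ("GA", "GDM or PE")
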