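"""Radiomic feature-name catalog.

The pipelines operate on per-patient feature tables whose columns carry the
naming convention of a standard radiomics extractor run on T1-weighted and
T2-weighted MRI of a segmented lymph node:

    ``N_<image>_<filter>_<class>_<name>``

e.g. ``N_T1w_original_shape_Elongation`` or
``N_T2w_waveletLHL_glcm_SumEntropy``.

Per image type the catalog enumerates 536 features: 14 shape/size, 18
first-order statistics and 40 textural features (24 grey-level co-occurrence
matrix + 16 grey-level run-length matrix) on the original image, plus the 18
first-order and 40 textural features recomputed on each of the eight 3-D
wavelet decomposition sub-bands (8 x 58 = 464 wavelet features).  Shape
features describe ROI geometry and therefore exist only for the original
image.  Two image types give 1072 features.
"""

from __future__ import annotations

from dataclasses import dataclass

IMAGE_TYPES = ("T1w", "T2w")

WAVELET_SUBBANDS = ("LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH", "LLL")

SHAPE_FEATURES = (
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
)

FIRSTORDER_FEATURES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

_CLASS_FEATURES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
}


@dataclass(frozen=True)
class CatalogEntry:
    """One named radiomic feature."""

    image_type: str
    filter: str  # "original" or "wavelet<subband>"
    feature_class: str  # shape / firstorder / glcm / glrlm
    name: str

    @property
    def full_name(self) -> str:
        return f"N_{self.image_type}_{self.filter}_{self.feature_class}_{self.name}"


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered collection of radiomic feature names."""

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalog")
        for e in self.entries:
            if e.feature_class == "shape" and e.filter != "original":
                raise ValueError("shape features exist only on the original image")

    @property
    def names(self) -> list[str]:
        return [e.full_name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def build_feature_catalog(image_types: set[str] | tuple[str, ...]) -> FeatureCatalog:
    """Enumerate the radiomic feature names for the requested image types.

    Parameters
    ----------
    image_types
        Non-empty subset of ``{"T1w", "T2w"}``.

    Returns
    -------
    FeatureCatalog
        536 entries per image type: 72 on the original image (14 shape +
        18 first-order + 24 GLCM + 16 GLRLM) and 58 non-shape features on
        each of the 8 wavelet sub-bands.
    """
    types = list(image_types)
    if not types:
        raise ValueError("image_types must be non-empty")
    unknown = set(types) - set(IMAGE_TYPES)
    if unknown:
        raise ValueError(f"unknown image types: {sorted(unknown)}")
    # deterministic order: T1w before T2w
    types = [t for t in IMAGE_TYPES if t in types]

    entries: list[CatalogEntry] = []
    for img in types:
        for cls in ("shape", "firstorder", "glcm", "glrlm"):
            for name in _CLASS_FEATURES[cls]:
                entries.append(CatalogEntry(img, "original", cls, name))
        for band in WAVELET_SUBBANDS:
            for cls in ("firstorder", "glcm", "glrlm"):
                for name in _CLASS_FEATURES[cls]:
                    entries.append(CatalogEntry(img, f"wavelet{band}", cls, name))
    return FeatureCatalog(tuple(entries))
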