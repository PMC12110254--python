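"""Frozen manifest of the radiomic feature bank.

Each (sequence, region) pair yields exactly 144 features split over nine
families (intensity 20, histogram 61, volumetric 2, morphology 19, GLCM 8,
GLRLM 10, GLSZM 18, NGTDM 5, LBP 1).  With 11 sequences and 3 tumor
subregions the full per-subject vector has 144 x 11 x 3 = 4752 entries.

Feature names follow the dialect

    <SEQ>_<REGION>_<FAMILY>[_Bins.<B>[_Radius.<r>]]_<FeatureName>

e.g. ``DSC_PSR_ET_GLCM_Bins.16_Radius.1_Contrast``.  The name list is frozen
in ``gliorad/data/feature_manifest.json`` so that column identity and order
are part of the package contract; :func:`validate_manifest` cross-checks the
shipped JSON against these constants at test time.
"""

from __future__ import annotations

import json
from importlib import resources

# Canonical imaging sequences of a multiparametric glioma protocol:
# structural (T1, T1Gd, T2, FLAIR), DSC perfusion maps (rCBV, rCBF, PSR),
# DTI maps (FA, MD), diffusion ADC and susceptibility-weighted imaging.
SEQUENCES: tuple[str, ...] = (
    "T1",
    "T1Gd",
    "T2",
    "FLAIR",
    "DSC_rCBV",
    "DSC_rCBF",
    "DSC_PSR",
    "DTI_FA",
    "DTI_MD",
    "ADC",
    "SWI",
)

# Tumor subregions (BraTS-style integer codes, remappable via config):
# enhancing tumor, necrotic core, peritumoral edema.
REGIONS: tuple[str, ...] = ("ET", "NCR", "ED")
DEFAULT_REGION_CODES: dict[str, int] = {"NCR": 1, "ED": 2, "ET": 4}

FAMILIES: tuple[str, ...] = (
    "INTENSITY",
    "HISTOGRAM",
    "VOLUMETRIC",
    "MORPHOLOGY",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "NGTDM",
    "LBP",
)

FAMILY_CARDINALITY: dict[str, int] = {
    "INTENSITY": 20,
    "HISTOGRAM": 61,
    "VOLUMETRIC": 2,
    "MORPHOLOGY": 19,
    "GLCM": 8,
    "GLRLM": 10,
    "GLSZM": 18,
    "NGTDM": 5,
    "LBP": 1,
}

INTENSITY_FEATURES: tuple[str, ...] = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Energy",
    "TotalEnergy",
    "RootMeanSquared",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "MedianAbsoluteDeviation",
    "Percentile10",
    "Percentile90",
    "InterquartileRange",
    "CoefficientOfVariation",
    "QuartileCoefficientOfDispersion",
)

# Histogram family: 32 normalized bin frequencies over the ROI intensity
# range plus 29 distribution statistics of the quantized gray levels.
N_HISTOGRAM_BINS = 32

HISTOGRAM_FEATURES: tuple[str, ...] = tuple(
    f"Bin.{i:02d}Frequency" for i in range(1, N_HISTOGRAM_BINS + 1)
) + (
    "Entropy",
    "Uniformity",
    "GrayLevelEnergy",
    "GrayLevelMean",
    "GrayLevelVariance",
    "GrayLevelSkewness",
    "GrayLevelKurtosis",
    "GrayLevelMedian",
    "GrayLevelMode",
    "ModeProbability",
    "GrayLevelMinimum",
    "GrayLevelMaximum",
    "GrayLevelRange",
    "Decile.10",
    "Decile.20",
    "Decile.30",
    "Decile.40",
    "Decile.50",
    "Decile.60",
    "Decile.70",
    "Decile.80",
    "Decile.90",
    "Quartile.25",
    "Quartile.75",
    "GrayLevelInterquartileRange",
    "GrayLevelMeanAbsoluteDeviation",
    "GrayLevelMedianAbsoluteDeviation",
    "GrayLevelRobustMeanAbsoluteDeviation",
    "GrayLevelCoefficientOfVariation",
)

VOLUMETRIC_FEATURES: tuple[str, ...] = ("Volume", "SurfaceArea")

MORPHOLOGY_FEATURES: tuple[str, ...] = (
    "SurfaceVolumeRatio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "SphericalDisproportion",
    "EquivalentSphericalRadius",
    "EquivalentSphericalSurfaceArea",
    "Maximum3DDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
    "BoundingBoxVolume",
    "Extent",
    "ConvexHullVolume",
    "Solidity",
    "ConnectedComponentCount",
    "CentroidShift",
)

GLCM_FEATURES: tuple[str, ...] = (
    "Contrast",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "Correlation",
    "ClusterShade",
    "ClusterProminence",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "MeanZoneSize",
    "MaximumZoneSize",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

LBP_FEATURES: tuple[str, ...] = ("AboveCenterFraction",)

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "INTENSITY": INTENSITY_FEATURES,
    "HISTOGRAM": HISTOGRAM_FEATURES,
    "VOLUMETRIC": VOLUMETRIC_FEATURES,
    "MORPHOLOGY": MORPHOLOGY_FEATURES,
    "GLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
    "LBP": LBP_FEATURES,
}

# Families whose values depend on the gray-level quantization / offset radius
# carry the corresponding tags in the feature name.
_BINS_TAGGED = frozenset({"HISTOGRAM", "GLCM", "GLRLM", "GLSZM", "NGTDM", "LBP"})
_RADIUS_TAGGED = frozenset({"GLCM", "NGTDM", "LBP"})


def family_tag(family: str, bins: int = 16, radius: int = 1) -> str:
    """Parameter tag inserted between the family token and the feature name."""
    tag = ""
    if family in _BINS_TAGGED:
        tag += f"_Bins.{bins}"
    if family in _RADIUS_TAGGED:
        tag += f"_Radius.{radius}"
    return tag


def feature_name(
    sequence: str, region: str, family: str, feature: str, bins: int = 16, radius: int = 1
) -> str:
    return f"{sequence}_{region}_{family}{family_tag(family, bins, radius)}_{feature}"


def pair_feature_names(
    sequence: str, region: str, bins: int = 16, radius: int = 1
) -> list[str]:
    """The 144 feature names for one (sequence, region) pair, in family order."""
    names = []
    for family in FAMILIES:
        for feat in FAMILY_FEATURES[family]:
            names.append(feature_name(sequence, region, family, feat, bins, radius))
    return names


def full_feature_names(bins: int = 16, radius: int = 1) -> list[str]:
    """All 4752 feature names ordered by (sequence, region, family, feature)."""
    names = []
    for seq in SEQUENCES:
        for region in REGIONS:
            names.extend(pair_feature_names(seq, region, bins, radius))
    return names


def parse_feature_name(name: str) -> dict[str, str]:
    """Split a manifest-dialect feature name into its components.

    Sequence tokens may themselves contain underscores (``DSC_PSR``), so the
    name is anchored on the region token.
    """
    parts = name.split("_")
    region_idx = None
    for i, tok in enumerate(parts):
        if tok in REGIONS:
            region_idx = i
            break
    if region_idx is None or region_idx == 0 or region_idx + 1 >= len(parts):
        raise ValueError(f"unparseable feature name: {name!r}")
    family = parts[region_idx + 1]
    if family not in FAMILIES:
        raise ValueError(f"unknown feature family in name: {name!r}")
    rest = parts[region_idx + 2 :]
    # strip parameter tags
    while rest and (rest[0].startswith("Bins.") or rest[0].startswith("Radius.")):
        rest.pop(0)
    if not rest:
        raise ValueError(f"feature name missing terminal feature token: {name!r}")
    return {
        "sequence": "_".join(parts[:region_idx]),
        "region": parts[region_idx],
        "family": family,
        "feature": "_".join(rest),
    }


def manifest_dict() -> dict:
    """Manifest structure as written to gliorad/data/feature_manifest.json."""
    return {
        "sequences": list(SEQUENCES),
        "regions": list(REGIONS),
        "region_codes": dict(DEFAULT_REGION_CODES),
        "families": {fam: list(FAMILY_FEATURES[fam]) for fam in FAMILIES},
        "family_cardinality": dict(FAMILY_CARDINALITY),
        "features_per_pair": sum(FAMILY_CARDINALITY.values()),
        "total_features": sum(FAMILY_CARDINALITY.values())
        * len(SEQUENCES)
        * len(REGIONS),
    }


def load_shipped_manifest() -> dict:
    with resources.files("gliorad.data").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)


def validate_manifest() -> None:
    """Raise if the shipped JSON manifest disagrees with the code constants."""
    shipped = load_shipped_manifest()
    current = manifest_dict()
    if shipped != current:
        raise RuntimeError("feature_manifest.json is out of sync with manifest.py")


for _fam, _feats in FAMILY_FEATURES.items():
    if len(_feats) != FAMILY_CARDINALITY[_fam]:
        raise AssertionError(
            f"manifest family {_fam}: {len(_feats)} names != "
            f"declared cardinality {FAMILY_CARDINALITY[_fam]}"
        )
del _fam, _feats
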