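{
  "families": {
    "GLCM": [
      "Contrast",
      "Dissimilarity",
      "Energy",
      "Entropy",
      "Homogeneity",
      "Correlation",
      "ClusterShade",
      "ClusterProminence"
    ],
    "GLRLM": [
      "ShortRunEmphasis",
      "LongRunEmphasis",
      "GrayLevelNonUniformityNormalized",
      "RunLengthNonUniformityNormalized",
      "RunPercentage",
      "LowGrayLevelRunEmphasis",
      "HighGrayLevelRunEmphasis",
      "ShortRunLowGrayLevelEmphasis",
      "ShortRunHighGrayLevelEmphasis",
      "LongRunLowGrayLevelEmphasis"
    ],
    "GLSZM": [
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
      "MaximumZoneSize"
    ],
    "HISTOGRAM": [
      "Bin.01Frequency",
      "Bin.02Frequency",
      "Bin.03Frequency",
      "Bin.04Frequency",
      "Bin.05Frequency",
      "Bin.06Frequency",
      "Bin.07Frequency",
      "Bin.08Frequency",
      "Bin.09Frequency",
      "Bin.10Frequency",
      "Bin.11Frequency",
      "Bin.12Frequency",
      "Bin.13Frequency",
      "Bin.14Frequency",
      "Bin.15Frequency",
      "Bin.16Frequency",
      "Bin.17Frequency",
      "Bin.18Frequency",
      "Bin.19Frequency",
      "Bin.20Frequency",
      "Bin.21Frequency",
      "Bin.22Frequency",
      "Bin.23Frequency",
      "Bin.24Frequency",
      "Bin.25Frequency",
      "Bin.26Frequency",
      "Bin.27Frequency",
      "Bin.28Frequency",
      "Bin.29Frequency",
      "Bin.30Frequency",
      "Bin.31Frequency",
      "Bin.32Frequency",
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
      "GrayLevelCoefficientOfVariation"
    ],
    "INTENSITY": [
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
      "QuartileCoefficientOfDispersion"
    ],
    "LBP": [
      "AboveCenterFraction"
    ],
    "MORPHOLOGY": [
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
      "CentroidShift"
    ],
    "NGTDM": [
      "Coarseness",
      "Contrast",
      "Busyness",
      "Complexity",
      "Strength"
    ],
    "VOLUMETRIC": [
      "Volume",
      "SurfaceArea"
    ]
  },
  "family_cardinality": {
    "GLCM": 8,
    "GLRLM": 10,
    "GLSZM": 18,
    "HISTOGRAM": 61,
    "INTENSITY": 20,
    "LBP": 1,
    "MORPHOLOGY": 19,
    "NGTDM": 5,
    "VOLUMETRIC": 2
  },
  "features_per_pair": 144,
  "region_codes": {
    "ED": 2,
    "ET": 4,
    "NCR": 1
  },
  "regions": [
    "ET",
    "NCR",
    "ED"
  ],
  "sequences": [
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
    "SWI"
  ],
  "total_features": 4752
}
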