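{
  "version": "1.0",
  "families": {
    "shape": [
      "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
      "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
      "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
      "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness"
    ],
    "firstorder": [
      "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
      "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
      "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
      "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
      "Variance", "Uniformity"
    ],
    "glcm": [
      "Autocorrelation", "ClusterProminence", "ClusterShade",
      "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
      "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
      "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
      "JointEntropy", "MCC", "MaximumProbability", "SumAverage",
      "SumEntropy", "SumSquares"
    ],
    "glrlm": [
      "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
      "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
      "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
      "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
      "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
      "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
      "ShortRunLowGrayLevelEmphasis"
    ],
    "glszm": [
      "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
      "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
      "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
      "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
      "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
      "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
      "ZoneEntropy", "ZonePercentage", "ZoneVariance"
    ],
    "gldm": [
      "DependenceEntropy", "DependenceNonUniformity",
      "DependenceNonUniformityNormalized", "DependenceVariance",
      "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
      "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
      "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
      "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
      "SmallDependenceLowGrayLevelEmphasis"
    ],
    "ngtdm": [
      "Busyness", "Coarseness", "Complexity", "Contrast", "Strength"
    ]
  }
}
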