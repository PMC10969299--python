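"""The pinned, ordered manifest of the 107 radiomic feature names.

The ordering is a repository contract: feature vectors are always emitted in
this order, prefixed by the source map identifier.
"""

SHAPE_FEATURES = (
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness",
)

FIRSTORDER_FEATURES = (
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Variance",
    "firstorder_Uniformity",
)

GLCM_FEATURES = (
    "glcm_Autocorrelation",
    "glcm_JointAverage",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MCC",
    "glcm_MaximumProbability",
    "glcm_SumAverage",
    "glcm_SumEntropy",
    "glcm_SumSquares",
)

GLRLM_FEATURES = (
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_GrayLevelVariance",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_RunEntropy",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_RunVariance",
    "glrlm_ShortRunEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_GrayLevelVariance",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_SmallAreaEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_ZoneEntropy",
    "glszm_ZonePercentage",
    "glszm_ZoneVariance",
)

GLDM_FEATURES = (
    "gldm_DependenceEntropy",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_DependenceVariance",
    "gldm_GrayLevelNonUniformity",
    "gldm_GrayLevelVariance",
    "gldm_HighGrayLevelEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LowGrayLevelEmphasis",
    "gldm_SmallDependenceEmphasis",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_FEATURES = (
    "ngtdm_Busyness",
    "ngtdm_Coarseness",
    "ngtdm_Complexity",
    "ngtdm_Contrast",
    "ngtdm_Strength",
)

FEATURE_NAMES = (SHAPE_FEATURES + FIRSTORDER_FEATURES + GLCM_FEATURES
                 + GLRLM_FEATURES + GLSZM_FEATURES + GLDM_FEATURES + NGTDM_FEATURES)

FEATURE_CLASS_COUNTS = {
    "shape": len(SHAPE_FEATURES),
    "firstorder": len(FIRSTORDER_FEATURES),
    "glcm": len(GLCM_FEATURES),
    "glrlm": len(GLRLM_FEATURES),
    "glszm": len(GLSZM_FEATURES),
    "gldm": len(GLDM_FEATURES),
    "ngtdm": len(NGTDM_FEATURES),
}

assert len(FEATURE_NAMES) == 107
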