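"""The fixed 58-feature radiomic catalogue.

Feature names follow the conventional ``Texture_*`` / ``Shape_*`` radiomics
naming. The catalogue order is the canonical column order for every feature
table the package reads or writes.
"""

from __future__ import annotations

HISTOGRAM_FEATURES = (
    "Texture_Histo_Mean",
    "Texture_Histo_SD",
    "Texture_Histo_Skewness",
    "Texture_Histo_ExcessKurtosis",
    "Texture_Histo_Energy",
    "Texture_Histo_Entropy",
    "Texture_Histo_Min",
    "Texture_Histo_Max",
    "Texture_Histo_VoxelCount",
    "Texture_Percentile_10",
    "Texture_Percentile_25",
    "Texture_Percentile_50",
    "Texture_Percentile_75",
    "Texture_Percentile_90",
    "Texture_Percentile_95",
)

GRADIENT_FEATURES = (
    "Texture_Grad_Mean",
    "Texture_Grad_SD",
)

GLCM_FEATURES = (
    "Texture_GLCM_ASM",
    "Texture_GLCM_IDM",
    "Texture_GLCM_Homogeneity",
    "Texture_GLCM_Contrast",
    "Texture_GLCM_Correlation",
    "Texture_GLCM_Autocor",
    "Texture_GLCM_Entropy",
    "Texture_GLCM_CP",
    "Texture_GLCM_CS",
    "Texture_GLCM_CT",
    "Texture_GLCM_SumEntropy",
    "Texture_GLCM_DiffAverage",
    "Texture_GLCM_DiffEntropy",
)

GLRLM_FEATURES = (
    "Texture_GLRLM_SRE",
    "Texture_GLRLM_LRE",
    "Texture_GLRLM_LGRE",
    "Texture_GLRLM_HGRE",
    "Texture_GLRLM_SRLGE",
    "Texture_GLRLM_SRHGE",
    "Texture_GLRLM_LRLGE",
    "Texture_GLRLM_LRHGE",
    "Texture_GLRLM_GNUN",
    "Texture_GLRLM_RLNUN",
    "Texture_GLRLM_RP",
    "Texture_GLRLM_RV",
    "Texture_GLRLM_RE",
)

MOMENT_FEATURES = (
    "Texture_Moment_J1",
    "Texture_Moment_J2",
    "Texture_Moment_J3",
)

SHAPE_FEATURES = (
    "Shape_Volume",
    "Shape_SurfaceArea",
    "Shape_Sphericity",
    "Shape_Compactness",
    "Shape_Roundness",
    "Shape_Circularity",
    "Shape_Longest1stAxis",
    "Shape_Longest2ndAxis",
    "Shape_PCA1stMajorSD",
    "Shape_PCA2ndMajorSD",
    "Shape_PCA3rdMajorSD",
)

FRACTAL_FEATURES = ("Fractal_Dimension",)

#: category name -> tuple of feature names, in canonical order
CATEGORIES = {
    "histogram": HISTOGRAM_FEATURES,
    "gradient": GRADIENT_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "moment": MOMENT_FEATURES,
    "shape": SHAPE_FEATURES,
    "fractal": FRACTAL_FEATURES,
}

#: all 58 feature names in canonical (catalogue) order
ALL_FEATURES = tuple(name for names in CATEGORIES.values() for name in names)

#: per-category counts (15 histogram, 2 gradient, 13 GLCM, 13 GLRLM,
#: 3 moment, 11 shape, 1 fractal)
CATEGORY_COUNTS = {cat: len(names) for cat, names in CATEGORIES.items()}

assert len(ALL_FEATURES) == 58


def category_of(name: str) -> str:
    """Return the category a catalogue feature belongs to."""
    for cat, names in CATEGORIES.items():
        if name in names:
            return cat
    raise KeyError(f"not a catalogue feature: {name!r}")
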