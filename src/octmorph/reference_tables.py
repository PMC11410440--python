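"""Published group-level summaries of the reference NDR/DR cohort.

The clinical study this pipeline reimplements reports only group-level
summaries (means ± SD, counts, correlations and reduced regression
equations), not patient-level data. Those printed summaries serve two roles
here: as inputs for recomputing the reported test statistics
(:mod:`octmorph.reproduce`), and as calibration for the synthetic cohort
presets (:mod:`octmorph.synthetic`).

Groups: ``NDR`` — type-2 diabetes without diabetic retinopathy (n = 75);
``DR`` — with diabetic retinopathy (n = 65). Morphometry keys: ``ld`` lumen
diameter (µm), ``od`` outer diameter (µm), ``wt`` wall thickness (µm),
``wlr`` wall-to-lumen ratio, ``wcsa`` wall cross-sectional area (µm²).
"""

from __future__ import annotations

GROUP_SIZES = {"NDR": 75, "DR": 65}

#: male / female counts per group
SEX_COUNTS = {"NDR": (39, 36), "DR": (43, 22)}

#: (mean, SD) per group
AGE_YEARS = {"NDR": (62.40, 10.05), "DR": (65.50, 8.41)}
BMI = {"NDR": (25.26, 3.32), "DR": (24.30, 3.32)}

#: arteriolar morphometry, (mean, SD) per group
ARTERY = {
    "NDR": {
        "ld": (104.88, 15.68),
        "od": (135.60, 17.22),
        "wlr": (0.29, 0.06),
        "wt": (15.26, 2.56),
        "wcsa": (5824.64, 1330.07),
    },
    "DR": {
        "ld": (128.80, 36.00),
        "od": (147.01, 17.55),
        "wlr": (0.28, 0.05),
        "wt": (18.29, 5.97),
        "wcsa": (6647.51, 1590.52),
    },
}

#: venular morphometry, (mean, SD) per group
VEIN = {
    "NDR": {
        "ld": (133.66, 21.07),
        "od": (156.43, 23.36),
        "wlr": (0.17, 0.03),
        "wt": (11.38, 2.33),
        "wcsa": (5321.03, 1695.19),
    },
    "DR": {
        "ld": (146.17, 34.42),
        "od": (180.20, 38.70),
        "wlr": (0.23, 0.05),
        "wt": (17.01, 4.23),
        "wcsa": (8962.13, 3897.34),
    },
}

#: reported two-sample t statistics (NDR vs DR) and the t-test variant each
#: one is numerically consistent with (arteriolar rows: pooled Student's t;
#: venular rows: Welch). WLR rows cannot be recomputed from the printed
#: summaries because the means are rounded to two decimals.
REPORTED_T = {
    ("artery", "ld"): (-5.214, "pooled"),
    ("artery", "od"): (-3.872, "pooled"),
    ("artery", "wlr"): (1.756, "pooled"),
    ("artery", "wt"): (-3.998, "pooled"),
    ("artery", "wcsa"): (-3.333, "pooled"),
    ("vein", "ld"): (-2.545, "welch"),
    ("vein", "od"): (-4.313, "welch"),
    ("vein", "wlr"): (-7.827, "welch"),
    ("vein", "wt"): (-9.529, "welch"),
    ("vein", "wcsa"): (-6.982, "welch"),
}

REPORTED_SEX_CHI2 = 2.875
REPORTED_AGE_T = -1.965
REPORTED_BMI_T = 1.699

#: DR stage counts over stages I..VI in the DR group (sum = 65)
STAGE_COUNTS = (37, 11, 11, 4, 2, 0)

#: within-DR Pearson correlations (r, p) that the source reports significant
REPORTED_CORRELATIONS = {
    ("artery", "ld", "stage"): (0.480, None),  # p < 0.001
    ("artery", "wt", "stage"): (0.524, None),
    ("artery", "wlr", "age"): (0.271, 0.029),
    ("vein", "ld", "stage"): (0.588, None),
    ("vein", "od", "stage"): (0.603, None),
    ("vein", "wt", "stage"): (0.369, 0.003),
    ("vein", "wlr", "duration"): (0.280, 0.024),
    ("vein", "wcsa", "stage"): (0.567, None),
}

#: reduced single-predictor regression equations within the DR group:
#: (vessel, parameter) -> (predictor, intercept, slope, R^2, F)
REPORTED_REGRESSIONS = {
    ("artery", "ld"): ("stage", 82.963, 17.633, 0.231, 18.908),
    ("artery", "wt"): ("stage", 9.997, 3.193, 0.274, 23.817),
    ("artery", "wlr"): ("age", 0.162, 0.002, 0.074, 5.006),
    ("vein", "ld"): ("stage", 92.532, 20.632, 0.346, 18.908),
    ("vein", "od"): ("stage", 118.273, 23.819, 0.364, 36.012),
    ("vein", "wt"): ("stage", 12.871, 1.593, 0.136, 9.916),
    ("vein", "wlr"): ("duration", 0.208, 0.004, 0.078, 5.344),
    ("vein", "wcsa"): ("stage", 3108.217, 2251.506, 0.321, 29.814),
}
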