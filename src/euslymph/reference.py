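"""Published summary statistics of the 68-lesion development cohort.

These are the printed class-conditional summaries of the retrospective
EUS-FNA cohort (30 malignant / 38 benign lymph nodes) on which the
agreement-based criteria were developed.  They parameterize the simulator
defaults, anchor the marginal-based validation experiments, and feed the
audit that reconstructs the published accuracy table from its printed
sensitivity/specificity columns.
"""

from __future__ import annotations

N_MALIGNANT = 30
N_BENIGN = 38
N_LESIONS = N_MALIGNANT + N_BENIGN

#: class-conditional mean +/- SD of node measurements (mm / ratio)
SIZE_SUMMARY = {
    "long_axis_mm": {"malignant": (25.3, 11.3), "benign": (16.8, 8.1)},
    "short_axis_mm": {"malignant": (16.3, 9.6), "benign": (9.8, 5.2)},
    "ratio": {"malignant": (0.66, 0.21), "benign": (0.59, 0.17)},
}

#: printed per-indicator counts (malignant, benign) out of 30 / 38
FEATURE_COUNTS = {
    "ratio>0.5": (22, 22),
    "long_axis>10mm": (27, 32),
    "long_axis>20mm": (19, 9),
    "short_axis>10mm": (24, 12),
    "shape=round": (8, 4),
    "shape=oval": (14, 18),
    "shape=triangle": (0, 5),
    "shape=polygonal": (8, 11),
    "round_or_oval&ratio>0.5": (18, 13),
    "location_mediastinal": (3, 5),
}

#: published per-feature multi-rater kappas and their verbal assessment
REPORTED_KAPPA = {
    "shape": 0.44,
    "border": 0.22,
    "margin": -0.02,
    "echogenicity": 0.33,
    "homogeneity": 0.34,
    "hilum": 0.22,
}
REPORTED_ASSESSMENT = {
    "shape": "moderate",
    "border": "fair",
    "margin": "less than chance",
    "echogenicity": "fair",
    "homogeneity": "fair",
    "hilum": "fair",
}

#: ROC-derived axis cutoffs (mm) before clinical rounding
REPORTED_CUTOFFS_MM = {"long": 19.7, "short": 10.7}

#: published accuracy-table rows: sensitivity/specificity as proportions
CRITERIA_PERFORMANCE = {
    "old_ge2": {"sensitivity": 0.833, "specificity": 0.158},
    "old_ge3": {"sensitivity": 0.467, "specificity": 0.526},
    "new_ge2": {"sensitivity": 0.767, "specificity": 0.711},
    "new_all3": {"sensitivity": 0.267, "specificity": 0.974},
}

#: published whole-score AUCs of the two criteria sets
REPORTED_AUC = {"new": 0.82, "old": 0.52}

#: per-item class-conditional positivity rates implied by FEATURE_COUNTS;
#: the two historical descriptor items without printed marginals are
#: class-equal (the historical criteria performed at chance in this cohort)
NEW_ITEM_MARGINALS = (
    (19 / 30, 9 / 38),   # long axis > 20 mm
    (24 / 30, 12 / 38),  # short axis > 10 mm
    (18 / 30, 13 / 38),  # round-or-oval with ratio > 0.5
)
OLD_ITEM_MARGINALS = (
    (27 / 30, 32 / 38),  # long axis > 10 mm
    (8 / 30, 4 / 38),    # round shape
    (0.5, 0.5),          # clear border (no printed class marginal)
    (0.5, 0.5),          # dark echogenicity (no printed class marginal)
)
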