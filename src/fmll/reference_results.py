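"""Published evaluation numbers for FMLL and its baselines.

Per-label metric rows reported for FMLL on the three public datasets
(Amphibians, Anuran-Calls-(MFCCs), HackerEarth-Adopt-A-Buddy), the
accuracy of the baseline methods on Amphibians, and the per-taxonomic-level
precision/recall/F-score baselines on Anuran calls.  These printed values
are inputs to the comparison arithmetic (macro averages and
improvement-over-baseline differences); nothing here is computed.
"""

from __future__ import annotations

from .evaluation import DatasetReport, LabelMetrics

__all__ = [
    "AMPHIBIANS_REPORT",
    "ANURAN_REPORT",
    "ADOPT_A_BUDDY_REPORT",
    "AMPHIBIANS_BASELINE_ACCURACY",
    "ANURAN_BASELINES",
    "ANURAN_FMLL",
]

# Columns: label, accuracy (%), precision, TNR, ROC, PRC, recall, F-score.
AMPHIBIANS_REPORT = DatasetReport(
    "Amphibians",
    [
        LabelMetrics("Green frogs", 68.78, 0.694, 0.688, 0.715, 0.682, 0.688, 0.689),
        LabelMetrics("Brown frogs", 78.31, 0.613, 0.783, 0.503, 0.665, 0.783, 0.688),
        LabelMetrics("Common toad", 71.43, 0.712, 0.714, 0.621, 0.653, 0.714, 0.674),
        LabelMetrics("Fire-bellied toad", 70.37, 0.669, 0.704, 0.576, 0.612, 0.704, 0.650),
        LabelMetrics("Tree frog", 65.61, 0.639, 0.655, 0.638, 0.627, 0.656, 0.631),
        LabelMetrics("Common newt", 69.84, 0.658, 0.698, 0.528, 0.603, 0.698, 0.619),
        LabelMetrics("Great crested newt", 88.36, 0.790, 0.884, 0.539, 0.818, 0.884, 0.834),
    ],
)

ANURAN_REPORT = DatasetReport(
    "Anuran-Calls-(MFCCs)",
    [
        LabelMetrics("Family", 95.75, 0.957, 0.980, 0.978, 0.964, 0.957, 0.957),
        LabelMetrics("Genus", 94.19, 0.941, 0.991, 0.979, 0.943, 0.942, 0.941),
        LabelMetrics("Species", 93.55, 0.935, 0.992, 0.983, 0.935, 0.936, 0.935),
    ],
)

ADOPT_A_BUDDY_REPORT = DatasetReport(
    "HackerEarth-Adopt-A-Buddy",
    [
        LabelMetrics("Breed_category", 85.43, 0.856, 0.927, 0.965, 0.938, 0.854, 0.850),
        LabelMetrics("Pet_category", 86.80, 0.869, 0.928, 0.946, 0.928, 0.868, 0.865),
    ],
)

# Accuracy (%) of prior methods on the Amphibians dataset.
AMPHIBIANS_BASELINE_ACCURACY = {
    "GBT": 64.18,
    "RF": 57.54,
    "ADA": 60.01,
    "DT": 58.37,
    "PMDT": 71.50,
}
AMPHIBIANS_FMLL_ACCURACY = 73.24

# (precision, recall, f_score) per method and taxonomic level on Anuran calls.
ANURAN_BASELINES = {
    "species": {
        "KNN-Flat": (0.690, 0.720, 0.700),
        "RBF-SVM-Flat": (0.850, 0.540, 0.660),
        "Polynomial-SVM-Flat": (0.710, 0.760, 0.740),
        "Tree-Flat": (0.490, 0.500, 0.500),
        "KNN-LCPL": (0.691, 0.719, 0.705),
        "KNN-Hierarchical-LCPN": (0.690, 0.720, 0.700),
        "RBF-SVM-Hierarchical-LCPN": (0.840, 0.540, 0.650),
        "Polynomial-SVM-Hierarchical-LCPN": (0.680, 0.710, 0.700),
        "Tree-Hierarchical-LCPN": (0.570, 0.560, 0.560),
        "KNN-Hierarchical-LCPL": (0.690, 0.720, 0.700),
        "RBF-SVM-Hierarchical-LCPL": (0.830, 0.520, 0.640),
        "Polynomial-SVM-Hierarchical-LCPL": (0.690, 0.740, 0.720),
        "Tree-Hierarchical-LCPL": (0.470, 0.500, 0.490),
    },
    "family": {"KNN-LCPL": (0.713, 0.820, 0.763)},
    "genus": {"KNN-LCPL": (0.663, 0.731, 0.695)},
    "combined": {"KNN-LCPL": (0.689, 0.757, 0.721)},
}

ANURAN_FMLL = {
    "species": (0.935, 0.936, 0.935),
    "family": (0.957, 0.957, 0.957),
    "genus": (0.941, 0.942, 0.941),
    "combined": (0.944, 0.945, 0.944),
}
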