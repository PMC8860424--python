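"""Published reference values for the 13 SPCH vs 49 LPA study cohort.

The original CT images of the cohort are not publicly deposited; what is
reproducible from the publication are the per-group feature summaries
(mean +/- SD per histology group), the printed univariate p-values, the
headline classification metrics of both models, and the leaf-node feature
selection tallies.  They are kept here as plain constants so that
summary-statistics reproductions (t-tests from n/mean/SD) and consistency
checks can run without the raw images.
"""

from __future__ import annotations

from .cohort_stats import GroupSummary

N_SPCH = 13
N_LPA = 49

#: feature -> (SPCH summary, LPA summary, printed two-sided p as a string)
COHORT_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary, str]] = {
    "skewness": (
        GroupSummary(13, 1.413, 0.773),
        GroupSummary(49, 1.227, 0.511),
        "0.302",
    ),
    "kurtosis": (
        GroupSummary(13, 4.888, 3.70),
        GroupSummary(49, 3.406, 1.415),
        "0.026",
    ),
    "p75": (
        GroupSummary(13, 87.75, 33.976),
        GroupSummary(49, 80.505, 30.563),
        "0.461",
    ),
    "p975": (
        GroupSummary(13, 128.55, 54.810),
        GroupSummary(49, 100.971, 35.913),
        "0.106",
    ),
    "uniformity": (
        GroupSummary(13, 0.0173, 0.005),
        GroupSummary(49, 0.029, 0.011),
        "<0.001",
    ),
    "autocorrelation": (
        GroupSummary(13, 54.450, 43.098),
        GroupSummary(49, 215.698, 186.057),
        "<0.001",
    ),
    "contrast": (
        GroupSummary(13, 5.179, 4.420),
        GroupSummary(49, 3.667, 3.529),
        "0.198",
    ),
    "correlation": (
        GroupSummary(13, 0.501, 0.091),
        GroupSummary(49, 0.636, 0.121),
        "<0.001",
    ),
    "cluster_prominence": (
        GroupSummary(13, 973.146, 982.489),
        GroupSummary(49, 2051.079, 5967.805),
        "0.521",
    ),
    "cluster_shade": (
        GroupSummary(13, -8.520, 60.754),
        GroupSummary(49, 62.069, 168.781),
        "0.145",
    ),
    "dissimilarity": (
        GroupSummary(13, 1.546, 0.742),
        GroupSummary(49, 1.255, 0.719),
        "0.202",
    ),
    "energy": (
        GroupSummary(13, 0.049, 0.026),
        GroupSummary(49, 0.066, 0.062),
        "0.141",
    ),
    "entropy": (
        GroupSummary(13, 3.512, 0.579),
        GroupSummary(49, 3.470, 0.955),
        "0.844",
    ),
    "inverse_difference": (
        GroupSummary(13, 0.554, 0.099),
        GroupSummary(49, 0.603, 0.136),
        "0.230",
    ),
    "inverse_difference_moment": (
        GroupSummary(13, 0.505, 0.121),
        GroupSummary(49, 0.563, 0.165),
        "0.242",
    ),
    "maximum_probability": (
        GroupSummary(13, 0.114, 0.044),
        GroupSummary(49, 0.127, 0.109),
        "0.518",
    ),
    "sum_of_squares_variance": (
        GroupSummary(13, 57.70, 45.249),
        GroupSummary(49, 216.875, 186.892),
        "<0.001",
    ),
    "sum_average": (
        GroupSummary(13, 13.245, 5.961),
        GroupSummary(49, 25.005, 15.119),
        "<0.001",
    ),
    "sum_variance": (
        GroupSummary(13, 160.969, 142.297),
        GroupSummary(49, 735.150, 651.642),
        "<0.001",
    ),
    "sum_entropy": (
        GroupSummary(13, 2.481, 0.347),
        GroupSummary(49, 2.492, 0.526),
        "0.930",
    ),
    "difference_variance": (
        GroupSummary(13, 5.179, 4.420),
        GroupSummary(49, 3.667, 3.529),
        "0.198",
    ),
    "difference_entropy": (
        GroupSummary(13, 1.487, 0.341),
        GroupSummary(49, 1.306, 0.415),
        "0.153",
    ),
    "imc1": (
        GroupSummary(13, -0.170, 0.052),
        GroupSummary(49, -0.197, 0.075),
        "0.234",
    ),
    "imc2": (
        GroupSummary(13, 0.663, 0.099),
        GroupSummary(49, 0.685, 0.106),
        "0.507",
    ),
    "inverse_difference_normalized": (
        GroupSummary(13, 0.994, 0.003),
        GroupSummary(49, 0.995, 0.003),
        "0.202",
    ),
    "inverse_difference_moment_normalized": (
        GroupSummary(13, 0.999, 0.00007),
        GroupSummary(49, 0.999, 0.00005),
        "0.202",
    ),
}

#: Headline LOOCV metrics of the two models on the study cohort.
REPORTED_METRICS = {
    "cascade": {
        "auc": 0.954,
        "accuracy_pct": 91.9,
        "sensitivity_pct": 92.3,
        "specificity_pct": 91.8,
    },
    "baseline": {
        "auc": 0.805,
        "accuracy_pct": 85.5,
        "sensitivity_pct": 61.5,
        "specificity_pct": 91.8,
    },
}

#: Reported p-value of the correlated-AUC comparison between the models.
REPORTED_AUC_COMPARISON_P = 0.025

#: Leaf-node feature selection tallies over the 62 LOOCV folds
#: (2 selections per fold, 124 in total).
LEAF_SELECTION_COUNTS = {
    "correlation": 61,
    "inverse_difference": 37,
    "uniformity": 14,
    "imc2": 12,
}
LEAF_SELECTION_TOTAL = 124

#: The six most frequently selected baseline features over the 62 folds
#: (285 selections in total).
BASELINE_SELECTION_COUNTS = {
    "uniformity": 62,
    "correlation": 62,
    "dissimilarity": 35,
    "autocorrelation": 20,
    "energy": 18,
    "inverse_difference": 17,
}
BASELINE_SELECTION_TOTAL = 285
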