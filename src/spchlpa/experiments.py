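"""Replication experiments over seeded synthetic cohorts.

Helpers that run the full pipeline - generate a cohort, extract the 26
features, fit and cross-validate both classifiers - so that multi-seed
replications (divide-and-conquer benefit, constraint checks, null
calibrations) are written once and shared by the test suite, the
acceptance script and ad-hoc analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cascade import ModelConfig, fit_cascade
from .cohort_stats import feature_table_report
from .evaluation import compare_auc, loocv_scores, roc_auc
from .synthetic import CohortSpec, generate_cohort
from .texture import FEATURE_NAMES, ExtractionConfig, extract_features


def cohort_features(
    spec: CohortSpec, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Generate a cohort and return its feature table (case_id, label, 26)."""
    config = config or ExtractionConfig()
    rows = []
    for item in generate_cohort(spec):
        feats = extract_features(item.volume, item.mask, config)
        rows.append({"case_id": item.case_id, "label": item.label, **feats})
    return pd.DataFrame(rows)


def evaluate_cohort(
    features: pd.DataFrame, model_config: ModelConfig | None = None
) -> dict:
    """LOOCV both models on a feature table; also audit the root constraint.

    Returns a dict with the two out-of-fold AUCs, the per-case score
    frames, and the number of *training* SPCH cases picked out by the root
    of a full-cohort fit (the 100%-sensitivity constraint audit; 0 when the
    constraint holds).
    """
    model_config = model_config or ModelConfig()
    X = features[list(FEATURE_NAMES)].to_numpy()
    y = (features["label"] == "SPCH").astype(int).to_numpy()
    cascade_scores = loocv_scores(
        X, y, "cascade", model_config, case_ids=features["case_id"].tolist()
    )
    baseline_scores = loocv_scores(
        X, y, "baseline", model_config, case_ids=features["case_id"].tolist()
    )
    full = fit_cascade(X, y, model_config)
    _, p1, _ = full.predict(X)
    return {
        "auc_cascade": roc_auc(cascade_scores["P"], y),
        "auc_baseline": roc_auc(baseline_scores["P"], y),
        "cascade_scores": cascade_scores,
        "baseline_scores": baseline_scores,
        "training_spch_picked_out": int((p1[y == 1] == 0).sum()),
    }


def replicate_aucs(
    spec_fn, n_seeds: int, model_config: ModelConfig | None = None
) -> pd.DataFrame:
    """Run evaluate_cohort on spec_fn(seed) for seeds 0..n_seeds-1."""
    records = []
    frames = []
    for seed in range(n_seeds):
        features = cohort_features(spec_fn(seed))
        res = evaluate_cohort(features, model_config)
        records.append(
            {
                "seed": seed,
                "auc_cascade": res["auc_cascade"],
                "auc_baseline": res["auc_baseline"],
                "training_spch_picked_out": res["training_spch_picked_out"],
            }
        )
        frames.append(features)
    out = pd.DataFrame(records)
    out.attrs["feature_frames"] = frames
    return out


def null_score_rejection_rate(
    n_replicates: int = 500,
    n_pos: int = 13,
    n_neg: int = 49,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of pure-noise score-set pairs the correlated-AUC test rejects."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * n_neg)
    hits = 0
    for _ in range(n_replicates):
        s1 = rng.random(n_pos + n_neg)
        s2 = rng.random(n_pos + n_neg)
        if compare_auc(s1, s2, y).p < alpha:
            hits += 1
    return hits / n_replicates


def permutation_flag_rate(
    feature_frames: list[pd.DataFrame],
    n_replicates: int = 200,
    seed: int = 0,
) -> float:
    """Mean fraction of features flagged at 0.05 under label permutation.

    Labels of no-signal cohorts are exchangeable, so permuting them yields
    null replicates of the per-feature Levene-gated t-test report.
    """
    rng = np.random.default_rng(seed)
    rates = []
    k = 0
    while len(rates) < n_replicates:
        frame = feature_frames[k % len(feature_frames)]
        labels = rng.permutation(frame["label"].to_numpy())
        report = feature_table_report(frame, labels)
        rates.append(report["significant"].mean())
        k += 1
    return float(np.mean(rates))
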