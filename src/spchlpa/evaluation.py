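"""Leave-one-out cross-validation, ROC metrics and correlated-AUC testing.

The AUC comparison follows Hanley and McNeil's z-test for two ROC areas
measured on the same cases: each AUC's standard error is computed from the
area and the class counts, and the correlation between the two area
estimates is looked up from a pre-tabulated function of the average
within-class rank correlation of the score sets and the average area
(bilinear interpolation, edges clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._hm_rtable import RANK_CORR_GRID, AUC_GRID, R_TABLE
from .cascade import ModelConfig, fit_baseline, fit_cascade
from .synthetic import SPCH


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return (arr == SPCH).astype(int)
    return (arr > 0).astype(int)


def loocv_scores(
    features,
    labels,
    trainer: str = "cascade",
    config: ModelConfig | None = None,
    case_ids=None,
) -> pd.DataFrame:
    """Out-of-fold SPCH scores under leave-one-out cross-validation.

    The entire pipeline (PCA, root threshold, feature selection,
    calibration) is refitted on the n-1 retained cases of every fold.

    trainer : "cascade" or "baseline" (or a callable fit(X, y, config) ->
        model exposing predict()).
    Returns a DataFrame with columns case_id, label, P1, P2, P (P1/P2 are
    NaN for the baseline).
    """
    config = config or ModelConfig()
    X = np.asarray(
        features.loc[:, :].to_numpy(dtype=float)
        if hasattr(features, "to_numpy")
        else features,
        dtype=float,
    )
    y = _as_binary(labels)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 cases for LOOCV")
    if case_ids is None:
        case_ids = [f"case{i:03d}" for i in range(n)]
    records = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if y[keep].min() == y[keep].max():
            raise ValueError(f"fold {i} loses one class entirely")
        if trainer == "cascade":
            model = fit_cascade(X[keep], y[keep], config)
            p, p1, p2 = model.predict(X[i : i + 1])
            records.append((case_ids[i], y[i], float(p1[0]), float(p2[0]), float(p[0])))
        elif trainer == "baseline":
            model = fit_baseline(X[keep], y[keep], config)
            p = model.predict(X[i : i + 1])
            records.append((case_ids[i], y[i], np.nan, np.nan, float(p[0])))
        else:
            model = trainer(X[keep], y[keep], config)
            p = np.asarray(model.predict(X[i : i + 1]), dtype=float).ravel()
            records.append((case_ids[i], y[i], np.nan, np.nan, float(p[0])))
    return pd.DataFrame(records, columns=["case_id", "label", "P1", "P2", "P"])


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2; SPCH positive."""
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("both classes are required for an ROC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve points including the (0,0) and (1,1) endpoints."""
    y = _as_binary(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def confusion_metrics(
    scores, labels, threshold: float = 0.5
) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and PPV at `threshold`.

    A case is called SPCH iff its score is strictly greater than the
    threshold, so root-rejected cases (P = 0) are always LPA at 0.5.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s > threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    acc = (tp + tn) / len(y)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "ppv": ppv,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
    }


def accuracy_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> float:
    """Overall accuracy implied by per-class rates on known class counts.

    The reported rates are first resolved to integer confusion counts
    (rounding sensitivity*n_pos and specificity*n_neg), mirroring how the
    rates themselves arise from counts.
    """
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    return (tp + tn) / (n_pos + n_neg)


def hanley_mcneil_se(A: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an AUC from the area and the class counts."""
    if not 0.0 <= A <= 1.0:
        raise ValueError("A must be in [0, 1]")
    q1 = A / (2.0 - A)
    q2 = 2.0 * A**2 / (1.0 + A)
    num = (
        A * (1.0 - A)
        + (n_pos - 1) * (q1 - A**2)
        + (n_neg - 1) * (q2 - A**2)
    )
    return float(np.sqrt(max(num, 0.0) / (n_pos * n_neg)))


def lookup_r(rank_corr: float, mean_auc: float) -> float:
    """Bilinear interpolation of the AUC-correlation table, edge-clamped."""
    x = float(np.clip(rank_corr, RANK_CORR_GRID[0], RANK_CORR_GRID[-1]))
    a = float(np.clip(mean_auc, AUC_GRID[0], AUC_GRID[-1]))
    # interpolate along the rank-correlation axis for each bracketing column
    j = int(np.clip(np.searchsorted(AUC_GRID, a) - 1, 0, len(AUC_GRID) - 2))
    w = (a - AUC_GRID[j]) / (AUC_GRID[j + 1] - AUC_GRID[j])
    r_lo = np.interp(x, RANK_CORR_GRID, R_TABLE[:, j])
    r_hi = np.interp(x, RANK_CORR_GRID, R_TABLE[:, j + 1])
    return float((1.0 - w) * r_lo + w * r_hi)


@dataclass
class AUCComparison:
    """Correlated-AUC z-test summary for two score sets on the same cases."""

    auc1: float
    auc2: float
    se1: float
    se2: float
    r: float
    z: float
    p: float

    def report(self) -> str:
        return (
            f"AUC1 = {self.auc1:.4f} (SE {self.se1:.4f})\n"
            f"AUC2 = {self.auc2:.4f} (SE {self.se2:.4f})\n"
            f"r = {self.r:.4f}\n"
            f"z = {self.z:.4f}\n"
            f"two-sided p = {self.p:.4f}\n"
        )


def compare_auc(scores1, scores2, labels) -> AUCComparison:
    """Test the difference of two AUCs measured on the same cases.

    z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2) with a two-sided
    normal p; identical scores (or a degenerate 0/0) are reported as
    z = 0, p = 1.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = _as_binary(labels)
    if s1.shape != s2.shape or s1.shape[0] != y.shape[0]:
        raise ValueError("score sets must cover the same cases")
    a1 = roc_auc(s1, y)
    a2 = roc_auc(s2, y)
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    se1 = hanley_mcneil_se(a1, n_pos, n_neg)
    se2 = hanley_mcneil_se(a2, n_pos, n_neg)

    def _rank_corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0
        rho = stats.spearmanr(a, b).statistic
        return 0.0 if np.isnan(rho) else float(rho)

    rank_corr = 0.5 * (
        _rank_corr(s1[y == 1], s2[y == 1]) + _rank_corr(s1[y == 0], s2[y == 0])
    )
    r = lookup_r(rank_corr, 0.5 * (a1 + a2))
    var = se1**2 + se2**2 - 2.0 * r * se1 * se2
    diff = a1 - a2
    if var <= 0 or (diff == 0 and var == 0) or np.array_equal(s1, s2):
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AUCComparison(auc1=a1, auc2=a2, se1=se1, se2=se2, r=r, z=float(z), p=p)
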