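"""Fast linear soft-margin classifier used in every tree node.

The cascade and the wrapper feature selection together require hundreds of
thousands of small SVM fits per cohort (leave-one-out inside sequential
forward selection, inside an outer leave-one-out loop).  General-purpose SVM
bindings carry per-call overhead that makes that loop impractically slow on a
single CPU, so the hinge-loss linear SVM is solved here directly by dual
coordinate descent (the liblinear algorithm) compiled with numba.  The bias
term is handled through an appended constant feature, i.e. it is (weakly)
regularized; with standardized inputs this is numerically irrelevant.

Class weighting follows the "balanced" convention: the per-sample box
constraint is ``C * n / (2 * n_class)``, compensating the 13:49 SPCH:LPA
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

# Sweep budgets: FULL_* for a from-scratch fit, LOO_* for the warm-started
# refit after removing one sample's dual contribution.  Node-model fits use
# the tighter FIT_* budget (few fits, and fold-to-fold stability of the
# decision values matters for the root threshold).
FULL_MAX_SWEEPS = 400
LOO_MAX_SWEEPS = 8
DUAL_TOL = 1e-4
FIT_MAX_SWEEPS = 4000
FIT_TOL = 1e-8


@njit(cache=True)
def _dcd_sweeps(X, y, C_i, alpha, w, skip, max_sweeps, tol):
    """In-place dual coordinate descent sweeps; row `skip` is excluded.

    Dot products are written as explicit loops: the rows arrive as views
    whose contiguity numba cannot prove, and np.dot would take a slow
    generic path in this innermost loop.
    """
    n, d = X.shape
    for _ in range(max_sweeps):
        max_pg = 0.0
        for i in range(n):
            if i == skip:
                continue
            acc = 0.0
            for k in range(d):
                acc += w[k] * X[i, k]
            g = y[i] * acc - 1.0
            pg = g
            if alpha[i] == 0.0 and g > 0.0:
                pg = 0.0
            elif alpha[i] == C_i[i] and g < 0.0:
                pg = 0.0
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if pg != 0.0:
                qii = 0.0
                for k in range(d):
                    qii += X[i, k] * X[i, k]
                if qii > 0.0:
                    a_old = alpha[i]
                    a_new = min(max(a_old - g / qii, 0.0), C_i[i])
                    alpha[i] = a_new
                    da = a_new - a_old
                    if da != 0.0:
                        for k in range(d):
                            w[k] += da * y[i] * X[i, k]
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def _fit_weights(X, y, C_i, max_sweeps, tol):
    n, d = X.shape
    alpha = np.zeros(n)
    w = np.zeros(d)
    _dcd_sweeps(X, y, C_i, alpha, w, -1, max_sweeps, tol)
    return alpha, w


@njit(cache=True)
def _loo_balanced_accuracy(X, y, c_pos, c_neg, full_sweeps, loo_sweeps, tol):
    """Leave-one-out balanced accuracy of the linear SVM on (X, y).

    X must already be standardized and carry the trailing constant-1 column;
    y is +/-1.  Each fold is warm-started from the full-data dual solution
    with the held-out sample's contribution removed, then corrected with a
    few sweeps - a close, deterministic approximation of the exact LOO that
    is an order of magnitude cheaper.
    """
    n, d = X.shape
    C_i = np.empty(n)
    for i in range(n):
        C_i[i] = c_pos if y[i] > 0 else c_neg
    alpha0, w0 = _fit_weights(X, y, C_i, full_sweeps, tol)
    tp = 0
    fn = 0
    tn = 0
    fp = 0
    for o in range(n):
        alpha = alpha0.copy()
        w = w0.copy()
        if alpha[o] != 0.0:
            for k in range(d):
                w[k] -= alpha[o] * y[o] * X[o, k]
            alpha[o] = 0.0
        _dcd_sweeps(X, y, C_i, alpha, w, o, loo_sweeps, tol)
        acc = 0.0
        for k in range(d):
            acc += w[k] * X[o, k]
        pred = 1.0 if acc > 0.0 else -1.0
        if y[o] > 0:
            if pred > 0:
                tp += 1
            else:
                fn += 1
        else:
            if pred < 0:
                tn += 1
            else:
                fp += 1
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    return 0.5 * (sens + spec)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale <= 0.0] = 1.0
    return mean, scale


def _augment(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, np.ones(X.shape[0])])


def loo_balanced_accuracy(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    """Leave-one-out balanced accuracy of the class-weighted linear SVM.

    Parameters
    ----------
    X : (n, d) feature matrix (raw scale; standardized internally).
    y : binary labels, positives > 0.
    """
    X = np.asarray(X, dtype=np.float64)
    ypm = np.where(np.asarray(y) > 0, 1.0, -1.0)
    n_pos = int((ypm > 0).sum())
    n_neg = int((ypm < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required")
    n = len(ypm)
    mean, scale = _standardize_fit(X)
    Xs = _augment((X - mean) / scale)
    c_pos = C * n / (2.0 * n_pos)
    c_neg = C * n / (2.0 * n_neg)
    return float(
        _loo_balanced_accuracy(
            Xs, ypm, c_pos, c_neg, FULL_MAX_SWEEPS, LOO_MAX_SWEEPS, DUAL_TOL
        )
    )


@dataclass
class LinearSVM:
    """Class-weighted linear SVM with standardized inputs.

    Equivalent in formulation to an L1-loss linear SVC with
    ``class_weight="balanced"``; solved by deterministic dual coordinate
    descent so that repeated fits are bit-identical.
    """

    C: float = 1.0
    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)
    coef_: np.ndarray = field(default=None, repr=False)
    intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVM":
        X = np.asarray(X, dtype=np.float64)
        ypm = np.where(np.asarray(y) > 0, 1.0, -1.0)
        n_pos = int((ypm > 0).sum())
        n_neg = int((ypm < 0).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("both classes are required")
        n = len(ypm)
        self.mean_, self.scale_ = _standardize_fit(X)
        Xs = _augment((X - self.mean_) / self.scale_)
        C_i = np.where(ypm > 0, self.C * n / (2.0 * n_pos), self.C * n / (2.0 * n_neg))
        _, w = _fit_weights(Xs, ypm, C_i, FIT_MAX_SWEEPS, FIT_TOL)
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        Z = (X - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0.0).astype(int)

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSVM":
        m = cls(C=d["C"])
        m.mean_ = np.asarray(d["mean"], dtype=float)
        m.scale_ = np.asarray(d["scale"], dtype=float)
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.intercept_ = float(d["intercept"])
        return m
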