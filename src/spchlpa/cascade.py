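"""Two-level divide-and-conquer SPCH-LPA classifier and single-SVM baseline.

The cascade untangles the imbalanced, intertwined SPCH/LPA feature
distribution in two stages:

* **Root gate** - a linear SVM on the first two principal components of the
  (unstandardized) 26-feature training matrix.  Its decision threshold is
  swept to pick out as many LPA cases as possible subject to the hard
  constraint that *every* training SPCH case is forwarded (100% training
  sensitivity; equivalently, maximal positive predictive value of the
  forwarded set).  Picked-out cases receive P1 = 0, forwarded cases P1 = 1.
* **Leaf node** - a linear SVM on exactly two features chosen by sequential
  forward selection among the cases the root forwards, with a Platt-type
  sigmoid calibration mapping its decision value to P2 in [0, 1].

The final SPCH probability is P = P1 * P2.  The baseline model is a single
class-weighted linear SVM on 3-6 forward-selected features, calibrated the
same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from ._svm import LinearSVM, loo_balanced_accuracy
from .texture import FEATURE_NAMES
from .synthetic import SPCH, LPA


@dataclass
class ModelConfig:
    """Shared classifier settings (root, leaf and baseline).

    C : SVM cost parameter.
    pca_standardize : run the root PCA on z-scored features instead of raw
        covariance (off by default: with raw radiomic features the two
        leading components of the unstandardized covariance carry almost
        all variance, which is what the root gate exploits).
    leaf_on_forwarded_only : train the leaf on root-forwarded cases only.
    soft_gate : replace the hard P1 in {0, 1} with a calibrated root
        probability.
    seed : echoed into serialized models; all fits are deterministic.
    """

    C: float = 1.0
    pca_standardize: bool = False
    leaf_on_forwarded_only: bool = True
    soft_gate: bool = False
    seed: int = 0


def _as_matrix(features) -> np.ndarray:
    """Accept an (n, 26) array or a DataFrame with the canonical columns."""
    if hasattr(features, "loc") and hasattr(features, "columns"):
        return features.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2D")
    return X


def _as_binary(labels) -> np.ndarray:
    """SPCH (positive) -> 1, LPA -> 0."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return (arr == SPCH).astype(int)
    return (arr > 0).astype(int)


def fit_pca2(features) -> tuple[np.ndarray, np.ndarray, float]:
    """First two principal components of the feature matrix.

    Returns (mean, loadings (2, d), explained_fraction).  Components come
    from the covariance of the unstandardized matrix; loadings are
    orthonormal with a deterministic sign convention (largest-magnitude
    coefficient positive).
    """
    X = _as_matrix(features)
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 cases for a 2-component PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("rank-0 feature matrix")
    loadings = vt[:2].copy()
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
    explained = float(var[: loadings.shape[0]].sum() / total)
    if loadings.shape[0] < 2:
        raise ValueError("fewer than 2 non-degenerate components")
    return mean, loadings, explained


@dataclass
class RootModel:
    """PCA-2 + constrained-threshold SVM gate emitting P1 in {0, 1}."""

    pca_mean: np.ndarray
    pca_loadings: np.ndarray
    explained_fraction: float
    svm: LinearSVM
    tau: float
    platt_a: float = 1.0
    platt_b: float = 0.0

    def scores(self, features) -> np.ndarray:
        X = _as_matrix(features)
        return (X - self.pca_mean) @ self.pca_loadings.T

    def decision_values(self, features) -> np.ndarray:
        return self.svm.decision_function(self.scores(features))

    def predict_p1(self, features) -> np.ndarray:
        """1 = forwarded to the leaf, 0 = picked out as confident LPA.

        A case whose decision value ties the threshold is forwarded: the
        threshold sits at the lowest training-SPCH decision value, so ties
        must never cost sensitivity.
        """
        return (self.decision_values(features) >= self.tau).astype(float)


def fit_root(pc_scores, labels, config: ModelConfig | None = None) -> RootModel:
    """Train the gate SVM on PC scores and sweep its decision threshold.

    Among all thresholds keeping every training SPCH strictly on the
    forward side, the one picking out the most LPA is chosen - i.e. the
    forwarded-set PPV is maximized subject to 100% training sensitivity.
    All thresholds between the highest picked-out LPA and the lowest SPCH
    decision value are equivalent under that objective; the midpoint is
    taken, maximizing the margin on both sides (an SPCH-like new case must
    cross half the gap before it is wrongly picked out).
    """
    config = config or ModelConfig()
    S = np.asarray(pc_scores, dtype=float)
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("both classes are required at the root")
    svm = LinearSVM(C=config.C).fit(S, y)
    d = svm.decision_function(S)
    d_spch_min = float(d[y == 1].min())
    below = d[(y == 0) & (d < d_spch_min)]
    if below.size:
        tau = 0.5 * (float(below.max()) + d_spch_min)
    else:
        tau = d_spch_min - 1.0  # gate inactive: nobody picked out
    # placeholder PCA fields; fit_cascade fills them in
    return RootModel(
        pca_mean=np.zeros(S.shape[1]),
        pca_loadings=np.eye(2, S.shape[1]),
        explained_fraction=1.0,
        svm=svm,
        tau=tau,
    )


def sfs_select(
    features,
    labels,
    k_min: int,
    k_max: int,
    config: ModelConfig | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> list[str]:
    """Greedy sequential forward feature selection.

    The criterion is the leave-one-out balanced accuracy of the
    class-weighted linear SVM within the provided training set.  Growth is
    unconditional up to k_min, then continues while some candidate strictly
    improves the criterion, up to k_max.  Ties keep the earliest candidate
    in canonical feature order.
    """
    config = config or ModelConfig()
    if k_min < 1 or k_max > len(feature_names) or k_min > k_max:
        raise ValueError(f"invalid selection range [{k_min}, {k_max}]")
    X = _as_matrix(features) if feature_names == FEATURE_NAMES else np.asarray(
        features, dtype=float
    )
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("both classes are required for feature selection")
    selected: list[int] = []
    current_score = -np.inf
    while len(selected) < k_max:
        best_j = -1
        best_score = -np.inf
        for j in range(X.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            score = loo_balanced_accuracy(X[:, cols], y, C=config.C)
            if score > best_score:
                best_score = score
                best_j = j
        if best_j < 0:
            break
        if len(selected) >= k_min and best_score <= current_score:
            break
        selected.append(best_j)
        current_score = best_score
    return [feature_names[j] for j in selected]


def _fit_platt(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt-type sigmoid P = 1/(1+exp(-(a*d+b))) with a >= 0.

    Fitted as a 1-D logistic regression on the training decision values;
    a non-positive slope (possible only on degenerate data) is replaced by
    a flat map at the positive-class prior to keep the calibration monotone
    non-decreasing.
    """
    d = np.asarray(decision_values, dtype=float).reshape(-1, 1)
    lr = LogisticRegression(C=1e6, max_iter=1000).fit(d, y)
    a = float(lr.coef_[0, 0])
    b = float(lr.intercept_[0])
    if a < 0.0:
        prior = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        return 0.0, float(np.log(prior / (1 - prior)))
    return a, b


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class LeafModel:
    """Two-feature SVM with monotone probability calibration (P2)."""

    selected_features: list[str]
    svm: LinearSVM
    platt_a: float
    platt_b: float

    def _columns(self, features) -> np.ndarray:
        X = _as_matrix(features)
        idx = [FEATURE_NAMES.index(f) for f in self.selected_features]
        return X[:, idx]

    def decision_values(self, features) -> np.ndarray:
        return self.svm.decision_function(self._columns(features))

    def predict_p2(self, features) -> np.ndarray:
        return _sigmoid(self.platt_a * self.decision_values(features) + self.platt_b)


def _fit_leaf_like(X, y, names: list[str], config: ModelConfig) -> LeafModel:
    idx = [FEATURE_NAMES.index(f) for f in names]
    svm = LinearSVM(C=config.C).fit(X[:, idx], y)
    d = svm.decision_function(X[:, idx])
    a, b = _fit_platt(d, y)
    return LeafModel(selected_features=list(names), svm=svm, platt_a=a, platt_b=b)


@dataclass
class CascadeModel:
    """Fitted two-level decision tree; SPCH is the positive class."""

    root: RootModel
    leaf: LeafModel
    config: ModelConfig = field(default_factory=ModelConfig)

    def predict(self, features) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (P, P1, P2) for each case; P = P1 * P2."""
        X = _as_matrix(features)
        if self.config.soft_gate:
            d = self.root.decision_values(X)
            p1 = _sigmoid(self.root.platt_a * d + self.root.platt_b)
        else:
            p1 = self.root.predict_p1(X)
        p2 = self.leaf.predict_p2(X)
        return p1 * p2, p1, p2


def fit_cascade(features, labels, config: ModelConfig | None = None) -> CascadeModel:
    """Fit the full cascade on a training cohort.

    Root: PCA-2 + constrained-threshold SVM on all cases.  Leaf: 2-feature
    forward selection + SVM + Platt calibration on the forwarded cases
    (or all cases when `leaf_on_forwarded_only` is off).
    """
    config = config or ModelConfig()
    X = _as_matrix(features)
    y = _as_binary(labels)
    if len(y) < 6:
        raise ValueError("need at least 6 training cases")
    if y.min() == y.max():
        raise ValueError("both classes are required")
    Xp = X
    if config.pca_standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd <= 0] = 1.0
        Xp = X / sd
    mean, loadings, explained = fit_pca2(Xp)
    scores = (Xp - mean) @ loadings.T
    root = fit_root(scores, y, config)
    root.pca_mean = mean
    root.pca_loadings = loadings
    root.explained_fraction = explained
    if config.soft_gate:
        root.platt_a, root.platt_b = _fit_platt(
            root.svm.decision_function(scores), y
        )
    if config.pca_standardize:
        # fold the scaling into the loadings so predict works on raw features
        root.pca_loadings = loadings / sd
        root.pca_mean = mean * sd

    p1 = root.predict_p1(X)
    if config.leaf_on_forwarded_only:
        fwd = p1 > 0
        if y[fwd].min() == y[fwd].max():
            raise ValueError(
                "all training LPA picked out at the root: leaf has one class"
            )
        leaf = _fit_leaf_like(
            X[fwd],
            y[fwd],
            sfs_select(X[fwd], y[fwd], 2, 2, config),
            config,
        )
    else:
        leaf = _fit_leaf_like(X, y, sfs_select(X, y, 2, 2, config), config)
    return CascadeModel(root=root, leaf=leaf, config=config)


def predict_cascade(model: CascadeModel, x) -> tuple[float, float, float]:
    """Score a single feature vector; returns (P, P1, P2)."""
    if isinstance(x, dict):
        x = np.array([[x[name] for name in FEATURE_NAMES]])
    else:
        x = np.atleast_2d(np.asarray(x, dtype=float))
    p, p1, p2 = model.predict(x)
    return float(p[0]), float(p1[0]), float(p2[0])


@dataclass
class BaselineModel:
    """Single-stage SVM on 3-6 forward-selected features."""

    selected_features: list[str]
    svm: LinearSVM
    platt_a: float
    platt_b: float
    config: ModelConfig = field(default_factory=ModelConfig)

    def decision_values(self, features) -> np.ndarray:
        X = _as_matrix(features)
        idx = [FEATURE_NAMES.index(f) for f in self.selected_features]
        return self.svm.decision_function(X[:, idx])

    def predict(self, features) -> np.ndarray:
        """Probability of SPCH for each case."""
        return _sigmoid(self.platt_a * self.decision_values(features) + self.platt_b)


def fit_baseline(features, labels, config: ModelConfig | None = None) -> BaselineModel:
    config = config or ModelConfig()
    X = _as_matrix(features)
    y = _as_binary(labels)
    if len(y) < 6:
        raise ValueError("need at least 6 training cases")
    if y.min() == y.max():
        raise ValueError("both classes are required")
    names = sfs_select(X, y, 3, 6, config)
    leaf = _fit_leaf_like(X, y, names, config)
    return BaselineModel(
        selected_features=leaf.selected_features,
        svm=leaf.svm,
        platt_a=leaf.platt_a,
        platt_b=leaf.platt_b,
        config=config,
    )


# ---------------------------------------------------------------------------
# plain-text (JSON) serialization


def save_model(model: CascadeModel | BaselineModel, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(model, CascadeModel):
        payload = {
            "kind": "cascade",
            "config": asdict(model.config),
            "root": {
                "pca_mean": model.root.pca_mean.tolist(),
                "pca_loadings": model.root.pca_loadings.tolist(),
                "explained_fraction": model.root.explained_fraction,
                "svm": model.root.svm.to_dict(),
                "tau": model.root.tau,
                "platt": [model.root.platt_a, model.root.platt_b],
            },
            "leaf": {
                "selected_features": model.leaf.selected_features,
                "svm": model.leaf.svm.to_dict(),
                "platt": [model.leaf.platt_a, model.leaf.platt_b],
            },
        }
    else:
        payload = {
            "kind": "baseline",
            "config": asdict(model.config),
            "selected_features": model.selected_features,
            "svm": model.svm.to_dict(),
            "platt": [model.platt_a, model.platt_b],
        }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_model(path: str | Path) -> CascadeModel | BaselineModel:
    payload = json.loads(Path(path).read_text())
    config = ModelConfig(**payload["config"])
    if payload["kind"] == "cascade":
        r = payload["root"]
        root = RootModel(
            pca_mean=np.asarray(r["pca_mean"], float),
            pca_loadings=np.asarray(r["pca_loadings"], float),
            explained_fraction=float(r["explained_fraction"]),
            svm=LinearSVM.from_dict(r["svm"]),
            tau=float(r["tau"]),
            platt_a=float(r.get("platt", [1.0, 0.0])[0]),
            platt_b=float(r.get("platt", [1.0, 0.0])[1]),
        )
        lf = payload["leaf"]
        leaf = LeafModel(
            selected_features=list(lf["selected_features"]),
            svm=LinearSVM.from_dict(lf["svm"]),
            platt_a=float(lf["platt"][0]),
            platt_b=float(lf["platt"][1]),
        )
        return CascadeModel(root=root, leaf=leaf, config=config)
    if payload["kind"] == "baseline":
        return BaselineModel(
            selected_features=list(payload["selected_features"]),
            svm=LinearSVM.from_dict(payload["svm"]),
            platt_a=float(payload["platt"][0]),
            platt_b=float(payload["platt"][1]),
            config=config,
        )
    raise ValueError(f"unknown model kind: {payload['kind']}")
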