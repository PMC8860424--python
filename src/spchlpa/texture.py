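"""Radiomic texture features of a masked lesion.

Twenty-six features are computed per lesion: 5 first-order histogram
features (skewness, kurtosis, 75th and 97.5th percentiles, uniformity) and
21 Haralick-family features of the grey-level co-occurrence matrix (GLCM)
accumulated over all *horizontally adjacent* voxel pairs, i.e. pairs at unit
offset along the in-plane column axis, with both voxels inside the lesion
mask.

Grey levels are obtained by clipping Hounsfield units to a fixed window and
mapping linearly onto ``1..n_levels`` (round half up).  The two feature
families use independent quantization channels: 256 levels for the
histogram features and 32 for the GLCM, both over the same window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .volume_io import CTVolume, LesionMask

HISTOGRAM_FEATURES = (
    "skewness",
    "kurtosis",
    "p75",
    "p975",
    "uniformity",
)

GLCM_FEATURES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "inverse_difference",
    "inverse_difference_moment",
    "maximum_probability",
    "sum_of_squares_variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

#: Canonical feature order: the row order of the cohort feature table.
FEATURE_NAMES = HISTOGRAM_FEATURES + GLCM_FEATURES


@dataclass
class ExtractionConfig:
    """Settings of :func:`extract_features`.

    window
        HU clipping window applied before quantization, default
        [-1000, 400] (air to soft tissue, covering ground-glass lesions).
    hist_levels / glcm_levels
        Grey-level counts of the two independent quantization channels.
    log_base
        Base of the logarithm in all entropy-type features ("e" or a
        number such as 2).
    percentile_method
        numpy percentile interpolation method (default "linear", i.e.
        linear interpolation between order statistics).
    degenerate_glcm_fallback
        When True, a lesion with no co-occurring in-mask pair (e.g. a
        single voxel) yields a single-cell diagonal GLCM instead of an
        error.
    """

    window: tuple[float, float] = (-1000.0, 400.0)
    hist_levels: int = 256
    glcm_levels: int = 32
    log_base: str | float = "e"
    percentile_method: str = "linear"
    degenerate_glcm_fallback: bool = False

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"degenerate window: [{lo}, {hi}]")
        if self.hist_levels < 2 or self.glcm_levels < 2:
            raise ValueError("quantization needs at least 2 levels")

    def _log(self, x: np.ndarray) -> np.ndarray:
        if self.log_base == "e":
            return np.log(x)
        return np.log(x) / np.log(float(self.log_base))


@dataclass
class QuantizedLesion:
    """Integer grey levels ``1..n_levels`` defined at in-mask voxels."""

    levels: np.ndarray
    n_levels: int
    mask: LesionMask

    @property
    def values(self) -> np.ndarray:
        """In-mask grey levels as a flat array."""
        return self.levels[self.mask.flags]


def rescale_to_levels(
    volume: CTVolume,
    mask: LesionMask,
    window: tuple[float, float] = (-1000.0, 400.0),
    n_levels: int = 32,
) -> QuantizedLesion:
    """Clip HU to `window` and map linearly onto integer levels 1..n_levels.

    Values are rounded half-up so the mapping is deterministic across
    platforms: level = 1 + floor((x-lo)/(hi-lo)*(n-1) + 0.5).
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate window: [{lo}, {hi}]")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = np.clip(volume.voxels.astype(np.float64), lo, hi)
    scaled = (x - lo) / (hi - lo) * (n_levels - 1)
    levels = 1 + np.floor(scaled + 0.5).astype(np.int64)
    np.clip(levels, 1, n_levels, out=levels)
    return QuantizedLesion(levels=levels, n_levels=n_levels, mask=mask)


def histogram_features(
    quantized: QuantizedLesion, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """First-order features of the in-mask grey-level sample.

    Skewness and kurtosis use population central moments (divide by n) in
    the non-excess Pearson convention, kurtosis(N(0,1)) = 3.  A constant
    sample returns 0 for both by convention.  Uniformity is the sum of
    squared bin probabilities over the n_levels-bin histogram.
    """
    config = config or ExtractionConfig()
    v = quantized.values.astype(np.float64)
    if v.size == 0:
        raise ValueError("empty sample: mask contains no voxels")
    m = v.mean()
    c = v - m
    m2 = np.mean(c**2)
    if m2 > 0:
        skewness = np.mean(c**3) / m2**1.5
        kurtosis = np.mean(c**4) / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0
    p75, p975 = np.percentile(v, [75.0, 97.5], method=config.percentile_method)
    counts = np.bincount(
        quantized.values.astype(np.int64), minlength=quantized.n_levels + 1
    )[1:]
    p = counts / counts.sum()
    uniformity = float(np.sum(p**2))
    return {
        "skewness": float(skewness),
        "kurtosis": float(kurtosis),
        "p75": float(p75),
        "p975": float(p975),
        "uniformity": uniformity,
    }


@dataclass
class GLCM:
    """Symmetric normalized grey-level co-occurrence matrix.

    ``p[i-1, j-1]`` is the joint probability of the (unordered) level pair
    (i, j); levels run 1..n_levels.  Marginals and the sum/difference
    distributions p_{x+y} and p_{x-y} are derived on construction.
    """

    p: np.ndarray
    n_levels: int = field(init=False)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("GLCM must be square")
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"GLCM not normalized (sum={total})")
        self.n_levels = self.p.shape[0]

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.n_levels + 1, dtype=np.float64)

    @property
    def px(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def mu_x(self) -> float:
        return float(np.sum(self.levels * self.px))

    @property
    def mu_y(self) -> float:
        return float(np.sum(self.levels * self.py))

    @property
    def sigma_x(self) -> float:
        return float(np.sqrt(np.sum((self.levels - self.mu_x) ** 2 * self.px)))

    @property
    def sigma_y(self) -> float:
        return float(np.sqrt(np.sum((self.levels - self.mu_y) ** 2 * self.py)))

    def p_xplusy(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, p_{x+y}(k)) for k = 2..2*n_levels."""
        ks = np.arange(2, 2 * self.n_levels + 1)
        out = np.zeros(ks.size)
        i = np.arange(1, self.n_levels + 1)
        s = i[:, None] + i[None, :]
        for idx, k in enumerate(ks):
            out[idx] = self.p[s == k].sum()
        return ks.astype(np.float64), out

    def p_xminusy(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, p_{x-y}(k)) for k = 0..n_levels-1."""
        ks = np.arange(0, self.n_levels)
        out = np.zeros(ks.size)
        i = np.arange(1, self.n_levels + 1)
        d = np.abs(i[:, None] - i[None, :])
        for idx, k in enumerate(ks):
            out[idx] = self.p[d == k].sum()
        return ks.astype(np.float64), out


def build_glcm(
    quantized: QuantizedLesion,
    offset: tuple[int, int, int] = (0, 0, 1),
) -> GLCM:
    """Accumulate the symmetric GLCM over in-mask voxel pairs at `offset`.

    The default offset (0, 0, 1) is the unit displacement along the column
    axis - "horizontal" adjacency on an axial slice.  Only pairs with both
    voxels inside the mask are counted; each ordered pair contributes to
    both (i, j) and (j, i).
    """
    levels = quantized.levels
    flags = quantized.mask.flags
    ds, dr, dc = offset
    if sorted(map(abs, offset)) != [0, 0, 1]:
        raise ValueError("offset must be a unit axis displacement")
    sl_a = tuple(
        slice(max(d, 0), n + min(d, 0)) for d, n in zip((ds, dr, dc), levels.shape)
    )
    sl_b = tuple(
        slice(max(-d, 0), n + min(-d, 0)) for d, n in zip((ds, dr, dc), levels.shape)
    )
    a = levels[sl_b]
    b = levels[sl_a]
    valid = flags[sl_b] & flags[sl_a]
    i = a[valid] - 1
    j = b[valid] - 1
    if i.size == 0:
        raise ValueError("no co-occurring pairs: lesion too small for the offset")
    ng = quantized.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)
    return GLCM(p=counts / counts.sum())


def glcm_features(
    glcm: GLCM, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """The 21 Haralick-family features of a normalized GLCM.

    Conventions: correlation and the information measures are 0 for a
    zero-variance (single-level) matrix; entropies use 0*log(0)=0;
    difference variance is the contrast variant (second moment of |i-j|);
    sum variance is centred on sum average; imc2 is clipped into [0, 1].
    """
    config = config or ExtractionConfig()
    p = glcm.p
    ng = glcm.n_levels
    i = glcm.levels[:, None]
    j = glcm.levels[None, :]
    log = config._log

    def _entropy(q: np.ndarray) -> float:
        nz = q[q > 0]
        return float(-np.sum(nz * log(nz)))

    mu_x, mu_y = glcm.mu_x, glcm.mu_y
    sig_x, sig_y = glcm.sigma_x, glcm.sigma_y
    px, py = glcm.px, glcm.py

    autocorrelation = float(np.sum(i * j * p))
    contrast = float(np.sum((i - j) ** 2 * p))
    if sig_x * sig_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 0.0
    cluster_shade = float(np.sum((i + j - mu_x - mu_y) ** 3 * p))
    cluster_prominence = float(np.sum((i + j - mu_x - mu_y) ** 4 * p))
    dissimilarity = float(np.sum(np.abs(i - j) * p))
    energy = float(np.sum(p**2))
    entropy = _entropy(p)
    inverse_difference = float(np.sum(p / (1.0 + np.abs(i - j))))
    inverse_difference_moment = float(np.sum(p / (1.0 + (i - j) ** 2)))
    maximum_probability = float(p.max())
    sum_of_squares_variance = float(np.sum((i - mu_x) ** 2 * p))

    ks, psum = glcm.p_xplusy()
    sum_average = float(np.sum(ks * psum))
    sum_variance = float(np.sum((ks - sum_average) ** 2 * psum))
    sum_entropy = _entropy(psum)

    kd, pdiff = glcm.p_xminusy()
    difference_variance = contrast
    difference_entropy = _entropy(pdiff)

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = entropy
    outer = px[:, None] * py[None, :]
    joint_nz = p > 0
    hxy1 = float(-np.sum(p[joint_nz] * log(outer[joint_nz])))
    outer_nz = outer > 0
    hxy2 = float(-np.sum(outer[outer_nz] * log(outer[outer_nz])))
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, 1.0)))

    inverse_difference_normalized = float(np.sum(p / (1.0 + np.abs(i - j) / ng)))
    inverse_difference_moment_normalized = float(
        np.sum(p / (1.0 + ((i - j) / ng) ** 2))
    )

    return {
        "autocorrelation": autocorrelation,
        "contrast": contrast,
        "correlation": float(correlation),
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "entropy": entropy,
        "inverse_difference": inverse_difference,
        "inverse_difference_moment": inverse_difference_moment,
        "maximum_probability": maximum_probability,
        "sum_of_squares_variance": sum_of_squares_variance,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_difference_normalized": inverse_difference_normalized,
        "inverse_difference_moment_normalized": inverse_difference_moment_normalized,
    }


def extract_features(
    volume: CTVolume,
    mask: LesionMask,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Compute the full 26-feature vector of a masked lesion."""
    config = config or ExtractionConfig()
    q_hist = rescale_to_levels(volume, mask, config.window, config.hist_levels)
    q_glcm = rescale_to_levels(volume, mask, config.window, config.glcm_levels)
    out = histogram_features(q_hist, config)
    try:
        glcm = build_glcm(q_glcm)
    except ValueError:
        if not config.degenerate_glcm_fallback:
            raise
        level = int(q_glcm.values[0])
        p = np.zeros((q_glcm.n_levels, q_glcm.n_levels))
        p[level - 1, level - 1] = 1.0
        glcm = GLCM(p=p)
    out.update(glcm_features(glcm, config))
    return {name: out[name] for name in FEATURE_NAMES}


def write_feature_table(df, path) -> None:
    """Write a cohort feature table as CSV: case_id, label, 26 features."""
    cols = ["case_id", "label"] + list(FEATURE_NAMES)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    df.loc[:, cols].to_csv(path, index=False)


def read_feature_table(path):
    """Read a feature table written by :func:`write_feature_table`."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["case_id", "label"] + list(FEATURE_NAMES)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df.loc[:, cols]


def config_to_dict(config: ExtractionConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> ExtractionConfig:
    known = {f for f in ExtractionConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown extraction settings: {sorted(unknown)}")
    d = dict(d)
    if "window" in d:
        d["window"] = tuple(d["window"])
    return ExtractionConfig(**d)
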