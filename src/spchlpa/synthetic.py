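"""Synthetic ground-glass-nodule cohorts for end-to-end testing.

Each lesion is an ellipsoid of smoothed Gaussian texture embedded in a
noisy air-like background: in-mask intensity = mean HU + a Gaussian random
field smoothed to a given correlation length and rescaled to a given
standard deviation, optionally with a brighter solid core (mimicking the
part-solid appearance of many capillary haemangiomas).  Two knobs map
monotonically onto the feature families that separate the two histologies:
the mean HU drives the intensity-scale GLCM features (autocorrelation, sum
average/variance) and the smoothness/noise pair drives the co-occurrence
similarity features (correlation, uniformity).

The default cohort mirrors the 13 SPCH vs 49 LPA study composition, with
the LPA group drawn from an easy/hard parameter mixture: two thirds of LPA
are well separated from SPCH while one third overlaps it, so that a
root-gate-plus-leaf cascade has a demonstrable advantage over a single
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, LesionMask

SPCH = "SPCH"
LPA = "LPA"


@dataclass
class ClassParams:
    """Texture parameters of one lesion class.

    mean_hu : lesion mean intensity (HU)
    noise_sd : in-mask intensity standard deviation after smoothing (HU)
    smooth_len : Gaussian smoothing kernel sigma in voxels (0 = white noise)
    core_fraction : probability that the lesion carries a dense solid core
    core_hu : added intensity of the core (HU)
    core_size_range : core extent as a range of the squared normalized
        ellipsoid radius (a threshold u keeps voxels with
        (r/R)^2 <= u, so the core volume fraction is u^{3/2})
    radius_range : min/max ellipsoid semi-axis (voxels)
    mean_hu_jitter : per-lesion SD of the lesion mean (between-patient
        heterogeneity, HU)
    noise_rel_jitter / smooth_rel_jitter : per-lesion lognormal sigma of
        noise_sd and smooth_len (relative heterogeneity)
    """

    mean_hu: float
    noise_sd: float
    smooth_len: float
    core_fraction: float = 0.0
    core_hu: float = 250.0
    core_size_range: tuple[float, float] = (0.05, 0.20)
    radius_range: tuple[float, float] = (3.0, 8.0)
    mean_hu_jitter: float = 0.0
    noise_rel_jitter: float = 0.0
    smooth_rel_jitter: float = 0.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.smooth_len < 0:
            raise ValueError("smooth_len must be >= 0")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")


@dataclass
class CohortSpec:
    """Composition and texture parameters of a synthetic cohort."""

    n_spch: int = 13
    n_lpa: int = 49
    spch: ClassParams = None
    lpa: ClassParams = None
    lpa_hard: ClassParams | None = None
    lpa_easy_fraction: float = 2.0 / 3.0
    grid_size: int = 48
    background_hu: float = -850.0
    background_noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_spch < 1 or self.n_lpa < 1:
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.lpa_easy_fraction <= 1.0:
            raise ValueError("lpa_easy_fraction must be in [0, 1]")


@dataclass
class CohortItem:
    case_id: str
    label: str
    volume: CTVolume
    mask: LesionMask
    seed: int


def generate_lesion(
    params: ClassParams,
    seed: int,
    grid_size: int = 48,
    background_hu: float = -850.0,
    background_noise_sd: float = 25.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[CTVolume, LesionMask]:
    """Generate one ellipsoidal textured nodule, fully determined by seed."""
    rng = np.random.default_rng(seed)
    n = grid_size
    lo, hi = params.radius_range
    if hi >= n / 2 - 1:
        raise ValueError(f"radius range {params.radius_range} too large for grid {n}")
    # per-lesion parameter draws (between-patient heterogeneity)
    mean_hu = params.mean_hu + rng.normal(0.0, 1.0) * params.mean_hu_jitter
    noise_sd = params.noise_sd * np.exp(
        rng.normal(0.0, 1.0) * params.noise_rel_jitter
    )
    smooth_len = params.smooth_len * np.exp(
        rng.normal(0.0, 1.0) * params.smooth_rel_jitter
    )
    semi = rng.uniform(lo, hi, size=3)
    centre = (n - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    zz, yy, xx = np.ogrid[:n, :n, :n]
    dist2 = (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
    )
    flags = dist2 <= 1.0
    if not flags.any():
        raise ValueError("degenerate lesion: no voxels inside the ellipsoid")

    field_ = rng.standard_normal((n, n, n))
    if smooth_len > 0:
        field_ = ndimage.gaussian_filter(field_, smooth_len)
    sd = field_[flags].std()
    if sd <= 0:
        sd = 1.0
    texture = field_ / sd * noise_sd

    voxels = background_hu + rng.standard_normal((n, n, n)) * background_noise_sd
    voxels[flags] = mean_hu + texture[flags]

    if rng.random() < params.core_fraction:
        core = dist2 <= rng.uniform(*params.core_size_range)
        voxels[core & flags] += params.core_hu

    vol = CTVolume(voxels=voxels, spacing=spacing)
    mask = LesionMask(flags=flags, lesion_id=f"synthetic-{seed}")
    return vol, mask


def generate_cohort(spec: CohortSpec) -> list[CohortItem]:
    """Generate the full labelled cohort of `spec`, deterministic in seed."""
    if spec.spch is None or spec.lpa is None:
        raise ValueError("spec must define spch and lpa class parameters")
    lpa_hard = spec.lpa_hard if spec.lpa_hard is not None else spec.lpa
    n_total = spec.n_spch + spec.n_lpa
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_total)
    n_easy = int(round(spec.n_lpa * spec.lpa_easy_fraction))
    items: list[CohortItem] = []
    for k in range(n_total):
        if k < spec.n_spch:
            label, params = SPCH, spec.spch
        elif k < spec.n_spch + n_easy:
            label, params = LPA, spec.lpa
        else:
            label, params = LPA, lpa_hard
        seed_k = int(seeds[k] % (2**31))
        vol, mask = generate_lesion(
            params,
            seed_k,
            grid_size=spec.grid_size,
            background_hu=spec.background_hu,
            background_noise_sd=spec.background_noise_sd,
        )
        items.append(
            CohortItem(
                case_id=f"case{k:03d}", label=label, volume=vol, mask=mask, seed=seed_k
            )
        )
    return items


def default_spec(seed: int = 0) -> CohortSpec:
    """Default 13 SPCH vs 49 LPA cohort.

    SPCH sits *between* the two LPA subgroups in intensity, mimicking its
    frequent part-solid appearance: the easy LPA subgroup (two thirds) is
    distinctly brighter with a sizeable solid component, the hard subgroup
    dimmer and smoother.  No single monotone feature separates SPCH from
    both subgroups, which is what gives the divide-and-conquer cascade its
    edge over a single linear classifier.  Heavy per-lesion parameter
    jitter reproduces the high within-class heterogeneity of real
    ground-glass cohorts (coefficients of variation above 30%).
    """
    return CohortSpec(
        spch=ClassParams(
            mean_hu=-700.0,
            noise_sd=115.0,
            smooth_len=0.8,
            core_fraction=0.55,
            core_hu=280.0,
            core_size_range=(0.02, 0.09),
            radius_range=(3.0, 8.0),
            mean_hu_jitter=38.0,
            noise_rel_jitter=0.40,
            smooth_rel_jitter=0.30,
        ),
        lpa=ClassParams(
            mean_hu=-430.0,
            noise_sd=60.0,
            smooth_len=0.7,
            core_fraction=1.0,
            core_hu=320.0,
            core_size_range=(0.28, 0.50),
            radius_range=(4.0, 10.0),
            mean_hu_jitter=60.0,
            noise_rel_jitter=0.45,
            smooth_rel_jitter=0.35,
        ),
        lpa_hard=ClassParams(
            mean_hu=-810.0,
            noise_sd=60.0,
            smooth_len=1.2,
            core_fraction=0.10,
            core_hu=160.0,
            core_size_range=(0.02, 0.08),
            radius_range=(3.0, 9.0),
            mean_hu_jitter=30.0,
            noise_rel_jitter=0.35,
            smooth_rel_jitter=0.30,
        ),
        seed=seed,
    )


def no_signal_spec(seed: int = 0) -> CohortSpec:
    """Control cohort: identical class parameters, so no class signal."""
    base = default_spec(seed).spch
    return CohortSpec(spch=base, lpa=base, lpa_hard=base, seed=seed)
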