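import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spchlpa.texture import (
    FEATURE_NAMES,
    GLCM,
    ExtractionConfig,
    QuantizedLesion,
    build_glcm,
    extract_features,
    glcm_features,
    histogram_features,
    rescale_to_levels,
)
from spchlpa.synthetic import ClassParams, generate_lesion

from conftest import make_mask, make_volume


def quantized_from_levels(levels, mask, ng):
    return QuantizedLesion(
        levels=np.asarray(levels, dtype=np.int64),
        n_levels=ng,
        mask=make_mask(mask),
    )


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_glcm(levels, flags, ng):
    """Enumerate all column-adjacent in-mask voxel pairs, symmetrized."""
    counts = np.zeros((ng, ng))
    ns, nr, nc = levels.shape
    for s in range(ns):
        for r in range(nr):
            for c in range(nc - 1):
                if flags[s, r, c] and flags[s, r, c + 1]:
                    i, j = levels[s, r, c] - 1, levels[s, r, c + 1] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_force_glcm_features(p):
    """Direct-summation evaluation of all 21 features (plain loops)."""
    ng = p.shape[0]
    lev = np.arange(1, ng + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = sum(lev[i] * px[i] for i in range(ng))
    muy = sum(lev[j] * py[j] for j in range(ng))
    sx = math.sqrt(sum((lev[i] - mux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((lev[j] - muy) ** 2 * py[j] for j in range(ng)))

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    out = {}
    out["autocorrelation"] = sum(
        lev[i] * lev[j] * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["contrast"] = sum(
        (lev[i] - lev[j]) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["correlation"] = (
        (out["autocorrelation"] - mux * muy) / (sx * sy) if sx * sy > 0 else 0.0
    )
    out["cluster_prominence"] = sum(
        (lev[i] + lev[j] - mux - muy) ** 4 * p[i, j]
        for i in range(ng)
        for j in range(ng)
    )
    out["cluster_shade"] = sum(
        (lev[i] + lev[j] - mux - muy) ** 3 * p[i, j]
        for i in range(ng)
        for j in range(ng)
    )
    out["dissimilarity"] = sum(
        abs(lev[i] - lev[j]) * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["entropy"] = ent(p.ravel())
    out["inverse_difference"] = sum(
        p[i, j] / (1 + abs(lev[i] - lev[j])) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (lev[i] - lev[j]) ** 2) for i in range(ng) for j in range(ng)
    )
    out["maximum_probability"] = p.max()
    out["sum_of_squares_variance"] = sum(
        (lev[i] - mux) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pdiff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            psum[int(lev[i] + lev[j])] += p[i, j]
            pdiff[int(abs(lev[i] - lev[j]))] += p[i, j]
    out["sum_average"] = sum(k * v for k, v in psum.items())
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * v for k, v in psum.items()
    )
    out["sum_entropy"] = ent(psum.values())
    out["difference_variance"] = out["contrast"]
    out["difference_entropy"] = ent(pdiff.values())
    hx, hy, hxy = ent(px), ent(py), out["entropy"]
    hxy1 = -sum(
        p[i, j] * math.log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, min(1.0, 1 - math.exp(-2 * (hxy2 - hxy)))))
    out["inverse_difference_normalized"] = sum(
        p[i, j] / (1 + abs(lev[i] - lev[j]) / ng)
        for i in range(ng)
        for j in range(ng)
    )
    out["inverse_difference_moment_normalized"] = sum(
        p[i, j] / (1 + ((lev[i] - lev[j]) / ng) ** 2)
        for i in range(ng)
        for j in range(ng)
    )
    return out


# ---------------------------------------------------------------------------
# quantization


class TestRescaleToLevels:
    @pytest.mark.parametrize(
        "value,expected",
        [(-1000.0, 1), (400.0, 256), (-300.0, 129), (-1200.0, 1), (900.0, 256)],
    )
    def test_window_mapping(self, value, expected):
        vol = make_volume(np.full((1, 1, 2), value))
        mask = make_mask(np.ones((1, 1, 2), dtype=bool))
        q = rescale_to_levels(vol, mask, window=(-1000, 400), n_levels=256)
        assert q.values.tolist() == [expected, expected]

    def test_degenerate_window_rejected(self):
        vol = make_volume(np.zeros((1, 1, 2)))
        mask = make_mask(np.ones((1, 1, 2), dtype=bool))
        with pytest.raises(ValueError, match="window"):
            rescale_to_levels(vol, mask, window=(400, -1000), n_levels=8)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), ng=st.integers(2, 64))
    def test_levels_always_in_range(self, seed, ng):
        rng = np.random.default_rng(seed)
        vol = make_volume(rng.uniform(-2000, 1000, size=(3, 3, 3)))
        mask = make_mask(rng.random((3, 3, 3)) < 0.6)
        if not mask.flags.any():
            mask = make_mask(np.ones((3, 3, 3), dtype=bool))
        q = rescale_to_levels(vol, mask, n_levels=ng)
        assert q.values.min() >= 1 and q.values.max() <= ng


# ---------------------------------------------------------------------------
# histogram features


class TestHistogramFeatures:
    def test_constant_sample_conventions(self):
        q = quantized_from_levels(
            np.full((1, 1, 4), 7), np.ones((1, 1, 4), bool), ng=16
        )
        f = histogram_features(q)
        assert f["uniformity"] == 1.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["p75"] == 7 and f["p975"] == 7

    def test_uniform_four_levels(self):
        q = quantized_from_levels(
            np.array([[[1, 2, 3, 4]]]), np.ones((1, 1, 4), bool), ng=4
        )
        f = histogram_features(q)
        assert f["uniformity"] == pytest.approx(0.25)
        assert f["p75"] == pytest.approx(3.25)

    def test_skewness_of_two_point_sample(self):
        # values {c, c, c+1}: m2 = 2/9, m3 = 2/27 -> skewness = 1/sqrt(2)
        q = quantized_from_levels(
            np.array([[[1, 1, 2]]]), np.ones((1, 1, 3), bool), ng=4
        )
        f = histogram_features(q)
        assert f["skewness"] == pytest.approx(1 / math.sqrt(2), abs=1e-10)


# ---------------------------------------------------------------------------
# GLCM construction and features


class TestBuildGlcm:
    def test_alternating_row(self):
        q = quantized_from_levels(
            np.array([[[1, 2, 1, 2]]]), np.ones((1, 1, 4), bool), ng=2
        )
        g = build_glcm(q)
        np.testing.assert_allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_block(self):
        q = quantized_from_levels(
            np.full((2, 2, 2), 3), np.ones((2, 2, 2), bool), ng=4
        )
        g = build_glcm(q)
        assert g.p[2, 2] == 1.0
        assert g.p.sum() == pytest.approx(1.0)

    def test_mask_excludes_pairs(self):
        mask = np.ones((1, 1, 4), bool)
        mask[0, 0, 1] = False
        q = quantized_from_levels(np.array([[[1, 2, 1, 2]]]), mask, ng=2)
        g = build_glcm(q)
        np.testing.assert_allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])

    def test_no_pairs_raises(self):
        q = quantized_from_levels(
            np.array([[[5]]]), np.ones((1, 1, 1), bool), ng=8
        )
        with pytest.raises(ValueError, match="no co-occurring pairs"):
            build_glcm(q)


class TestGlcmFeatures:
    def test_single_cell(self):
        f = glcm_features(GLCM(p=np.array([[1.0]])))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["maximum_probability"] == 1.0
        assert f["dissimilarity"] == 0.0
        assert f["correlation"] == 0.0  # zero-variance convention
        assert f["imc1"] == 0.0

    def test_diagonal_two_level(self):
        f = glcm_features(GLCM(p=np.array([[0.5, 0.0], [0.0, 0.5]])))
        assert f["contrast"] == 0.0
        assert f["correlation"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(math.log(2))
        assert f["sum_average"] == pytest.approx(3.0)

    def test_alternating_row_features(self):
        q = quantized_from_levels(
            np.array([[[1, 2, 1, 2]]]), np.ones((1, 1, 4), bool), ng=2
        )
        f = glcm_features(build_glcm(q))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)
        assert f["dissimilarity"] == pytest.approx(1.0)
        assert f["difference_variance"] == pytest.approx(1.0)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            GLCM(p=np.array([[0.5, 0.2], [0.1, 0.1]]))


class TestGlcmOracle:
    """Implementation vs brute-force enumeration on random masked lesions."""

    def test_200_random_lesions_match_exactly(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            levels = rng.integers(1, 5, size=(4, 4, 4))
            flags = rng.random((4, 4, 4)) < 0.5
            if flags.sum() < 8:
                continue
            q = quantized_from_levels(levels, flags, ng=4)
            expected = brute_force_glcm(levels, flags, 4)
            if expected.sum() == 0:
                continue
            g = build_glcm(q)
            np.testing.assert_array_equal(g.p, expected)
            ours = glcm_features(g)
            theirs = brute_force_glcm_features(expected)
            for name, val in theirs.items():
                assert ours[name] == pytest.approx(val, abs=1e-10), name
            checked += 1

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_distributions_are_normalized(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, 7, size=(3, 4, 5))
        flags = rng.random((3, 4, 5)) < 0.7
        q = quantized_from_levels(levels, flags, ng=6)
        try:
            g = build_glcm(q)
        except ValueError:
            return
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert g.p_xplusy()[1].sum() == pytest.approx(1.0, abs=1e-12)
        assert g.p_xminusy()[1].sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(g.p, g.p.T)


# ---------------------------------------------------------------------------
# end-to-end extraction


class TestExtractFeatures:
    def test_constant_lesion(self, extraction_config):
        vol = make_volume(np.full((3, 3, 3), -800.0))
        mask = make_mask(np.ones((3, 3, 3), bool))
        f = extract_features(vol, mask, extraction_config)
        assert f["uniformity"] == 1.0
        assert f["energy"] == 1.0
        assert f["contrast"] == 0.0
        assert f["correlation"] == 0.0

    def test_schema_and_determinism(self, extraction_config):
        rng = np.random.default_rng(3)
        vol = make_volume(rng.uniform(-900, -400, size=(6, 6, 6)))
        mask = make_mask(rng.random((6, 6, 6)) < 0.5)
        f1 = extract_features(vol, mask, extraction_config)
        f2 = extract_features(vol, mask, extraction_config)
        assert tuple(f1) == FEATURE_NAMES
        assert all(np.isfinite(list(f1.values())))
        assert f1 == f2

    def test_single_voxel_needs_fallback(self):
        vol = make_volume(np.full((3, 3, 3), -500.0))
        flags = np.zeros((3, 3, 3), bool)
        flags[1, 1, 1] = True
        mask = make_mask(flags)
        with pytest.raises(ValueError, match="no co-occurring pairs"):
            extract_features(vol, mask, ExtractionConfig())
        f = extract_features(
            vol, mask, ExtractionConfig(degenerate_glcm_fallback=True)
        )
        assert f["energy"] == 1.0 and f["contrast"] == 0.0

    def test_shift_covariance(self, extraction_config):
        # one GLCM level is 1400/31 HU wide; shifting by exactly that
        # amount relabels levels without changing co-occurrence structure
        rng = np.random.default_rng(11)
        base = rng.uniform(-700, -500, size=(5, 5, 5))
        shift = 1400.0 / 31.0
        mask = make_mask(np.ones((5, 5, 5), bool))
        f0 = extract_features(make_volume(base), mask, extraction_config)
        f1 = extract_features(make_volume(base + shift), mask, extraction_config)
        for name in ("contrast", "correlation", "energy"):
            assert f1[name] == pytest.approx(f0[name], rel=1e-9)

    def test_percentile_shift(self, extraction_config):
        # a whole number of 256-level widths shifts p75/p975 accordingly
        rng = np.random.default_rng(12)
        base = rng.uniform(-700, -500, size=(5, 5, 5))
        width = 1400.0 / 255.0
        mask = make_mask(np.ones((5, 5, 5), bool))
        f0 = extract_features(make_volume(base), mask, extraction_config)
        f1 = extract_features(make_volume(base + 3 * width), mask, extraction_config)
        assert f1["p75"] == pytest.approx(f0["p75"] + 3, abs=1e-9)
        assert f1["p975"] == pytest.approx(f0["p975"] + 3, abs=1e-9)


class TestSmoothnessMonotonicity:
    def test_smoother_lesions_have_higher_correlation_lower_contrast(self):
        """GLCM correlation rises and contrast falls with spatial smoothness."""
        rough = ClassParams(mean_hu=-650, noise_sd=80, smooth_len=0.4)
        smooth = ClassParams(mean_hu=-650, noise_sd=80, smooth_len=1.8)
        corr = {"rough": [], "smooth": []}
        cont = {"rough": [], "smooth": []}
        for seed in range(50):
            for name, params in (("rough", rough), ("smooth", smooth)):
                vol, mask = generate_lesion(params, seed=seed + 1, grid_size=24)
                f = extract_features(vol, mask, ExtractionConfig())
                corr[name].append(f["correlation"])
                cont[name].append(f["contrast"])
        assert np.mean(corr["smooth"]) > np.mean(corr["rough"])
        assert np.mean(cont["smooth"]) < np.mean(cont["rough"])
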