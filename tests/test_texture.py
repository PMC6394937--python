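import math

import numpy as np
import pytest

from sonotear.texture import (
    DIRECTION_OFFSETS,
    DIRECTIONS,
    TEXTURE_FEATURE_NAMES,
    DegenerateGLCMError,
    DirectedGLCM,
    build_glcm,
    mean_over_directions,
    quantize,
    texture_features,
    texture_statistics,
)

# ---------------------------------------------------------------------------
# independent oracles: plain double loops, no shared code with the package
# ---------------------------------------------------------------------------

def brute_force_glcm(levels, mask, angle, distance=1, g=8):
    dr, dc = DIRECTION_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = mask.shape
    counts = np.zeros((g, g), dtype=int)
    for r in range(h):
        for c in range(w):
            rn, cn = r + dr, c + dc
            if mask[r, c] and 0 <= rn < h and 0 <= cn < w and mask[rn, cn]:
                counts[levels[r, c], levels[rn, cn]] += 1
                counts[levels[rn, cn], levels[r, c]] += 1
    return counts


def brute_force_features(p):
    """Naive per-cell loops over the 14 statistics (`p` is a list of lists)."""
    g = len(p)
    px = [sum(p[i][j] for j in range(g)) for i in range(g)]
    py = [sum(p[i][j] for i in range(g)) for j in range(g)]
    mux = sum(i * px[i] for i in range(g))
    muy = sum(j * py[j] for j in range(g))
    sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(g)))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(g)))
    pd = [0.0] * g
    for i in range(g):
        for j in range(g):
            pd[abs(i - j)] += p[i][j]
    mud = sum(k * pd[k] for k in range(g))
    ln = lambda v: math.log(v) if v > 0 else 0.0
    auto = sum(i * j * p[i][j] for i in range(g) for j in range(g))
    hxy = -sum(p[i][j] * ln(p[i][j]) for i in range(g) for j in range(g))
    hx = -sum(px[i] * ln(px[i]) for i in range(g))
    hy = -sum(py[j] * ln(py[j]) for j in range(g))
    hxy1 = -sum(
        p[i][j] * ln(px[i] * py[j])
        for i in range(g)
        for j in range(g)
        if px[i] * py[j] > 0
    )
    return {
        "Autocorrelation": auto,
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(g) for j in range(g)),
        "Correlation": (auto - mux * muy) / (sx * sy) if sx * sy > 0 else math.nan,
        "ClusterProminence": sum(
            (i + j - mux - muy) ** 4 * p[i][j] for i in range(g) for j in range(g)
        ),
        "ClusterShade": sum(
            (i + j - mux - muy) ** 3 * p[i][j] for i in range(g) for j in range(g)
        ),
        "Dissimilarity": sum(abs(i - j) * p[i][j] for i in range(g) for j in range(g)),
        "Energy": sum(p[i][j] ** 2 for i in range(g) for j in range(g)),
        "Entropy": hxy,
        "Homogeneity": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(g) for j in range(g)
        ),
        "DifferenceVariance": sum((k - mud) ** 2 * pd[k] for k in range(g)),
        "DifferenceEntropy": -sum(pd[k] * ln(pd[k]) for k in range(g)),
        "InformationMeasureOfCorrelation": (hxy - hxy1) / max(hx, hy)
        if max(hx, hy) > 0
        else math.nan,
        "InverseDifferenceNormalized": sum(
            p[i][j] / (1 + abs(i - j) / g) for i in range(g) for j in range(g)
        ),
        "InverseDifferenceMoment": sum(
            p[i][j] / (1 + (i - j) ** 2 / g**2) for i in range(g) for j in range(g)
        ),
    }


def random_glcm(rng, g=8):
    m = rng.uniform(size=(g, g))
    m = m + m.T
    return DirectedGLCM(
        counts=np.zeros((g, g), int), probs=m / m.sum(), distance=1, angle=0
    )


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_bin_endpoints(self):
        img = np.array([[0, 32, 255]], dtype=np.uint8)
        q = quantize(img, np.ones((1, 3), bool))
        np.testing.assert_array_equal(q.levels, [[0, 1, 7]])

    def test_all_256_values_monotone_32_per_level(self):
        img = np.arange(256, dtype=np.uint8).reshape(1, -1)
        q = quantize(img, np.ones((1, 256), bool))
        levels = q.levels.ravel()
        assert (np.diff(levels) >= 0).all()
        np.testing.assert_array_equal(np.bincount(levels), [32] * 8)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="2"):
            quantize(np.zeros((2, 2), np.uint8), np.ones((2, 2), bool), n_levels=1)


# ---------------------------------------------------------------------------
# co-occurrence matrices
# ---------------------------------------------------------------------------

class TestBuildGLCM:
    def test_single_horizontal_pair(self):
        img = np.array([[0, 255]], dtype=np.uint8)
        g = build_glcm(quantize(img, np.ones((1, 2), bool)), angle=0)
        assert g.counts.sum() == 2
        assert g.counts[0, 7] == 1 and g.counts[7, 0] == 1
        assert g.probs[0, 7] == 0.5 and g.probs[7, 0] == 0.5

    def test_constant_roi_is_a_single_diagonal_cell(self):
        img = np.full((4, 4), 100, dtype=np.uint8)  # level 3
        g = build_glcm(quantize(img, np.ones((4, 4), bool)), angle=90)
        assert g.probs[3, 3] == 1.0
        assert g.probs.sum() == 1.0

    def test_no_valid_pair_raises(self):
        mask = np.eye(3, dtype=bool)  # isolated pixels for theta=0
        with pytest.raises(DegenerateGLCMError):
            build_glcm(quantize(np.zeros((3, 3), np.uint8), mask), angle=0)

    def test_bad_angle_rejected(self):
        q = quantize(np.zeros((2, 2), np.uint8), np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="angle"):
            build_glcm(q, angle=30)

    def test_random_masked_rois_match_brute_force(self, rng):
        for _ in range(25):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            mask = rng.uniform(size=(16, 16)) < 0.7
            mask[:2, :2] = True  # guarantee at least one pair everywhere
            q = quantize(img, mask)
            for angle in DIRECTIONS:
                g = build_glcm(q, angle=angle)
                np.testing.assert_array_equal(
                    g.counts, brute_force_glcm(q.levels, mask, angle)
                )

    def test_symmetry_and_normalization_invariants(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
            q = quantize(img, rng.uniform(size=(12, 12)) < 0.8)
            for angle in DIRECTIONS:
                g = build_glcm(q, angle=angle)
                np.testing.assert_array_equal(g.counts, g.counts.T)
                assert g.probs.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# texture statistics
# ---------------------------------------------------------------------------

class TestTextureStatistics:
    def test_degenerate_diagonal_matrix(self):
        p = np.zeros((8, 8))
        p[3, 3] = 1.0
        f = texture_statistics(
            DirectedGLCM(counts=np.zeros((8, 8), int), probs=p, distance=1, angle=0)
        )
        assert f["Energy"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Dissimilarity"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["InverseDifferenceNormalized"] == 1.0
        assert f["InverseDifferenceMoment"] == 1.0
        assert math.isnan(f["Correlation"])
        assert math.isnan(f["InformationMeasureOfCorrelation"])

    def test_uniform_matrix(self):
        p = np.full((8, 8), 1 / 64)
        f = texture_statistics(
            DirectedGLCM(counts=np.ones((8, 8), int), probs=p, distance=1, angle=0)
        )
        assert f["Energy"] == pytest.approx(1 / 64)
        assert f["Entropy"] == pytest.approx(math.log(64))

    def test_random_matrices_match_naive_double_loops(self, rng):
        for _ in range(100):
            g = random_glcm(rng)
            mine = texture_statistics(g)
            ref = brute_force_features(g.probs.tolist())
            for name in TEXTURE_FEATURE_NAMES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_transposition_invariance(self, rng):
        for _ in range(20):
            g = random_glcm(rng)
            gt = DirectedGLCM(
                counts=g.counts, probs=np.ascontiguousarray(g.probs.T),
                distance=1, angle=0,
            )
            a, b = texture_statistics(g), texture_statistics(gt)
            for name in TEXTURE_FEATURE_NAMES:
                assert a[name] == pytest.approx(b[name], abs=1e-12), name

    def test_contrast_dissimilarity_zero_iff_diagonal(self, rng):
        diag = np.zeros((8, 8))
        diag[np.arange(8), np.arange(8)] = 1 / 8
        f = texture_statistics(
            DirectedGLCM(counts=np.zeros((8, 8), int), probs=diag, distance=1, angle=0)
        )
        assert f["Contrast"] == 0.0 and f["Dissimilarity"] == 0.0
        g = random_glcm(rng)  # random symmetric matrix has off-diagonal mass
        f2 = texture_statistics(g)
        assert f2["Contrast"] > 0 and f2["Dissimilarity"] > 0

    def test_range_invariants_on_random_matrices(self, rng):
        for _ in range(30):
            f = texture_statistics(random_glcm(rng))
            assert 0 < f["Energy"] <= 1
            assert f["Entropy"] >= 0
            for name in ("Homogeneity", "InverseDifferenceNormalized",
                         "InverseDifferenceMoment"):
                assert 0 < f[name] <= 1
            if not math.isnan(f["Correlation"]):
                assert -1 <= f["Correlation"] <= 1


class TestMeanOverDirections:
    def test_idempotent_on_identical_vectors(self, rng):
        v = texture_statistics(random_glcm(rng))
        out = mean_over_directions([v, v, v, v])
        for name in TEXTURE_FEATURE_NAMES:
            assert out[name] == pytest.approx(v[name])

    def test_arithmetic_mean(self, rng):
        vs = []
        for k in range(4):
            v = dict(texture_statistics(random_glcm(rng)))
            v["Contrast"] = 0.01 * (k + 1)
            vs.append(v)
        assert mean_over_directions(vs)["Contrast"] == pytest.approx(0.025)

    def test_wrong_direction_count_rejected(self, rng):
        v = texture_statistics(random_glcm(rng))
        with pytest.raises(ValueError, match="4"):
            mean_over_directions([v, v, v])

    def test_nan_propagates(self):
        p = np.zeros((8, 8))
        p[3, 3] = 1.0
        v = texture_statistics(
            DirectedGLCM(counts=np.zeros((8, 8), int), probs=p, distance=1, angle=0)
        )
        assert math.isnan(mean_over_directions([v] * 4)["Correlation"])


def test_isotropic_texture_directions_agree(rng):
    """On rotation-symmetric smoothed speckle the four directional vectors are
    close, so their mean is close to any single one."""
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.normal(size=(200, 200)), 2.0)
    img = np.clip(128 + 60 * field / field.std(), 0, 255).astype(np.uint8)
    mask = np.ones_like(img, dtype=bool)
    q = quantize(img, mask)
    vectors = [texture_statistics(build_glcm(q, angle=a)) for a in DIRECTIONS]
    mean = mean_over_directions(vectors)
    # only offset-length-insensitive features are compared: the diagonal
    # directions sample pairs at distance sqrt(2), which inflates
    # difference-based statistics like Contrast even on isotropic fields
    for name in ("Energy", "Entropy", "Homogeneity",
                 "InverseDifferenceNormalized", "InverseDifferenceMoment"):
        vals = [v[name] for v in vectors]
        scale = abs(mean[name]) + 1e-3
        assert (max(vals) - min(vals)) / scale < 0.25, name
        assert abs(vectors[0][name] - mean[name]) / scale < 0.15, name


def test_phantom_tears_more_uniform_than_tendinopathy(default_phantom):
    """Tears (dark, homogeneous) have higher Energy and lower Entropy."""
    _, records, _ = default_phantom
    feats = {"tear": [], "tendinopathy": []}
    for rec in records:
        feats[rec.label].append(texture_features(rec.image, rec.mask))
    med = lambda lab, name: np.median([f[name] for f in feats[lab]])
    assert med("tear", "Energy") > med("tendinopathy", "Energy")
    assert med("tear", "Entropy") < med("tendinopathy", "Entropy")
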