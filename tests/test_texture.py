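"""Texture matrices, features and filters against naive oracles."""

import itertools

import numpy as np
import pytest

from hemoinformatics.texture import (
    FeatureConfig,
    GrayLevelImage,
    TextureMatrix,
    extract_feature_vector,
    first_order,
    glcm,
    gln,
    glrlm,
    glszm,
    lalgle,
    log_filter,
    matrix_features,
    quantize,
    wavelet_subbands,
)
from hemoinformatics.velocity_imaging import ScalarImage


def scalar(arr, spacing=1.0, mask=None):
    arr = np.asarray(arr)
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    nd = arr.ndim
    return ScalarImage(array=arr, spacing=np.full(nd, spacing), origin=np.zeros(nd), mask=mask)


def gray(arr, n_levels):
    return GrayLevelImage(np.asarray(arr), n_levels=n_levels, spacing=np.ones(np.asarray(arr).ndim))


def half_offsets(ndim):
    return [o for o in itertools.product((-1, 0, 1), repeat=ndim) if o > (0,) * ndim]


# ---------------------------------------------------------------------------
# naive oracles (independent of the implementation path)
# ---------------------------------------------------------------------------


def glcm_naive(a, ng, distance=1):
    counts = np.zeros((ng, ng))
    for off in half_offsets(a.ndim):
        off = tuple(o * distance for o in off)
        for idx in np.ndindex(a.shape):
            jdx = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= n for j, n in zip(jdx, a.shape)):
                continue
            x, y = a[idx], a[jdx]
            if x > 0 and y > 0:
                counts[x - 1, y - 1] += 1
                counts[y - 1, x - 1] += 1
    return counts


def glrlm_naive(a, ng):
    shape = a.shape
    runs = []
    for off in half_offsets(a.ndim):
        for idx in np.ndindex(shape):
            prev = tuple(i - o for i, o in zip(idx, off))
            prev_inside = all(0 <= p < n for p, n in zip(prev, shape))
            v = a[idx]
            if v <= 0:
                continue
            if prev_inside and a[prev] == v:
                continue  # not a run start
            length = 1
            nxt = tuple(i + o for i, o in zip(idx, off))
            while all(0 <= p < n for p, n in zip(nxt, shape)) and a[nxt] == v:
                length += 1
                nxt = tuple(i + o for i, o in zip(nxt, off))
            runs.append((v, length))
    max_len = max((l for _, l in runs), default=1)
    counts = np.zeros((ng, max_len))
    for v, l in runs:
        counts[v - 1, l - 1] += 1
    return counts


def glszm_naive(a, ng):
    visited = np.zeros(a.shape, dtype=bool)
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=a.ndim) if any(o)]
    zones = []
    for idx in np.ndindex(a.shape):
        if visited[idx] or a[idx] <= 0:
            continue
        level = a[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(i + o for i, o in zip(cur, off))
                if all(0 <= p < n for p, n in zip(nb, a.shape)) and not visited[nb] and a[nb] == level:
                    visited[nb] = True
                    stack.append(nb)
        zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((ng, max_size))
    for v, s in zones:
        counts[v - 1, s - 1] += 1
    return counts


def random_gray_images(n, rng):
    """Mix of 3D and 2D random label images with background holes."""
    for k in range(n):
        ng = int(rng.choice([2, 4, 8]))
        if k % 2 == 0:
            a = rng.integers(0, ng + 1, size=(6, 6, 6))
        else:
            a = rng.integers(0, ng + 1, size=(16, 16))
        yield a, ng


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


class TestQuantize:
    def test_edge_rule(self):
        img = scalar(np.array([[0.0, 0.5, 1.0]]))
        g = quantize(img, n_bins=2)
        assert g.array.tolist() == [[1, 2, 2]]

    def test_constant_image_is_level_one(self):
        g = quantize(scalar(np.full((4, 4), 0.0)), n_bins=8)
        assert set(np.unique(g.array)) == {1}

    def test_integer_labels_pass_through(self):
        a = np.array([[3, 0], [1, 7]])
        g = quantize(scalar(a), n_bins=5)
        assert g.n_levels == 7
        np.testing.assert_array_equal(g.array, a)

    def test_histogram_matches_binning_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.random(10_000)
        g = quantize(scalar(v.reshape(100, 100)), n_bins=32)
        got = np.bincount(g.array.ravel(), minlength=33)[1:]
        expected = np.zeros(32, dtype=int)
        for x in v:
            expected[min(int(x * 32), 31)] += 1
        np.testing.assert_array_equal(got, expected)

    def test_nonfinite_masked_value_raises(self):
        with pytest.raises(ValueError):
            quantize(scalar(np.array([[np.nan, 0.2]])), 4)


# ---------------------------------------------------------------------------
# matrices vs oracles
# ---------------------------------------------------------------------------


class TestMatrices:
    def test_glcm_constant_image(self):
        m = glcm(gray(np.ones((3, 3), dtype=int), 1))
        assert m.counts.shape == (1, 1)
        # 4 offsets * symmetric double counting over the 3x3 lattice
        assert m.counts[0, 0] == m.n_entities > 0

    def test_glcm_checkerboard_off_diagonal(self):
        a = np.indices((4, 4)).sum(axis=0) % 2 + 1
        m = glcm(gray(a, 2))
        # horizontal/vertical neighbours always differ; diagonal mass comes
        # only from the diagonal offsets
        sub = glcm(gray(a[:1], 2))  # single row: horizontal pairs only
        assert sub.counts[0, 0] == sub.counts[1, 1] == 0

    def test_glrlm_simple_row(self):
        # horizontal direction sees runs {(1, len 2), (2, len 1)}; the three
        # off-row directions each contribute per-voxel length-1 runs
        m = glrlm(gray(np.array([[1, 1, 2]]), 2))
        np.testing.assert_array_equal(m.counts, [[6, 1], [4, 0]])

    def test_glrlm_constant_line(self):
        m = glrlm(gray(np.full((1, 7), 3, dtype=int), 3))
        assert m.counts[2, 6] == 1

    def test_glszm_diagonal_connectivity(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 0] = a[1, 1] = 1
        m = glszm(gray(a, 1))
        assert m.counts[0, 1] == 1  # one zone of size 2 under 8-connectivity

    def test_glszm_constant_image(self):
        m = glszm(gray(np.full((4, 4, 4), 2, dtype=int), 2))
        assert m.counts[1, 63] == 1
        assert m.n_entities == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matrices_match_naive_oracles(self, seed):
        rng = np.random.default_rng(seed)
        for a, ng in random_gray_images(50, rng):
            g = gray(a, ng)
            np.testing.assert_array_equal(glcm(g).counts, glcm_naive(a, ng))
            np.testing.assert_array_equal(glrlm(g).counts, glrlm_naive(a, ng))
            np.testing.assert_array_equal(glszm(g).counts, glszm_naive(a, ng))

    @pytest.mark.parametrize("seed", range(4))
    def test_mass_conservation_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        for a, ng in random_gray_images(25, rng):
            n_masked = int((a > 0).sum())
            n_dirs = len(half_offsets(a.ndim))
            mr = glrlm(gray(a, ng))
            lengths = np.arange(1, mr.counts.shape[1] + 1)
            assert (mr.counts * lengths).sum() == n_masked * n_dirs
            mz = glszm(gray(a, ng))
            sizes = np.arange(1, mz.counts.shape[1] + 1)
            assert (mz.counts * sizes).sum() == n_masked

    def test_glcm_invariant_under_mirror_flips(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, size=(6, 6, 6))
        base = glcm(gray(a, 4)).counts
        for ax in range(3):
            np.testing.assert_array_equal(glcm(gray(np.flip(a, axis=ax), 4)).counts, base)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


class TestFirstOrder:
    def test_constant_image(self):
        f = first_order(scalar(np.full((4, 4), 2.5)))
        assert f["Variance"] == 0
        assert f["Uniformity"] == 1
        assert f["Entropy"] == 0

    def test_basic_statistics(self):
        f = first_order(scalar(np.array([[1.0, 2.0], [3.0, 4.0]])))
        assert f["Mean"] == 2.5
        assert f["Median"] == 2.5
        assert f["Maximum"] == 4.0

    def test_moments_match_formula_oracle(self):
        rng = np.random.default_rng(11)
        v = rng.lognormal(size=400)
        f = first_order(scalar(v.reshape(20, 20)))
        mu, sd = v.mean(), v.std()
        assert f["Skewness"] == pytest.approx(np.mean(((v - mu) / sd) ** 3), rel=1e-12)
        # non-excess (Pearson) kurtosis
        assert f["Kurtosis"] == pytest.approx(np.mean(((v - mu) / sd) ** 4), rel=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            first_order(scalar(np.zeros((2, 2)), mask=np.zeros((2, 2), bool)))


def matrix_feature_oracle(kind, counts):
    """Literal-formula recomputation of every matrix feature."""
    C = np.asarray(counts, dtype=float)
    nz = C.sum()
    out = {}
    if kind == "glcm":
        P = C / nz
        ng = C.shape[0]
        i = np.arange(1, ng + 1)
        out["Autocorrelation"] = sum(
            P[a, b] * (a + 1) * (b + 1) for a in range(ng) for b in range(ng)
        )
        mu_x = sum((a + 1) * P[a].sum() for a in range(ng))
        mu_y = sum((b + 1) * P[:, b].sum() for b in range(ng))
        out["ClusterShade"] = sum(
            P[a, b] * ((a + 1) + (b + 1) - mu_x - mu_y) ** 3
            for a in range(ng)
            for b in range(ng)
        )
        out["JointEnergy"] = (P**2).sum()
        pnz = P[P > 0]
        out["JointEntropy"] = -(pnz * np.log2(pnz)).sum()
        out["MaximumProbability"] = P.max()
        p_sum = {}
        for a in range(ng):
            for b in range(ng):
                p_sum[a + b + 2] = p_sum.get(a + b + 2, 0.0) + P[a, b]
        out["SumEntropy"] = -sum(p * np.log2(p) for p in p_sum.values() if p > 0)
        out["SumAverage"] = sum(k * p for k, p in p_sum.items())
    else:
        P = C / nz
        ng, nj = C.shape
        out["GrayLevelNonUniformity"] = sum(C[a].sum() ** 2 for a in range(ng)) / nz
        out["HighGrayLevel%sEmphasis" % ("Run" if kind == "glrlm" else "Zone")] = sum(
            P[a, b] * (a + 1) ** 2 for a in range(ng) for b in range(nj)
        )
        tag = "LongRun" if kind == "glrlm" else "LargeArea"
        out[f"{tag}LowGrayLevelEmphasis"] = sum(
            P[a, b] * (b + 1) ** 2 / (a + 1) ** 2 for a in range(ng) for b in range(nj)
        )
        mu_j = sum(P[a, b] * (b + 1) for a in range(ng) for b in range(nj))
        out["RunVariance" if kind == "glrlm" else "ZoneVariance"] = sum(
            P[a, b] * ((b + 1) - mu_j) ** 2 for a in range(ng) for b in range(nj)
        )
    return out


class TestMatrixFeatures:
    def test_glcm_point_mass(self):
        counts = np.zeros((5, 5))
        counts[2, 2] = 8.0  # all mass at (3, 3)
        f = matrix_features(TextureMatrix("glcm", counts, 5))
        assert f["glcm.MaximumProbability"] == 1.0
        assert f["glcm.JointEntropy"] == 0.0
        assert f["glcm.Autocorrelation"] == 9.0

    def test_glcm_uniform_two_by_two(self):
        f = matrix_features(TextureMatrix("glcm", np.full((2, 2), 3.0), 2))
        assert f["glcm.JointEnergy"] == pytest.approx(0.25)
        assert f["glcm.JointEntropy"] == pytest.approx(2.0)

    @pytest.mark.parametrize("kind", ["glcm", "glrlm", "glszm"])
    def test_features_match_literal_formula_oracle(self, kind):
        rng = np.random.default_rng(13)
        for _ in range(50):
            ng, nj = rng.integers(2, 9, size=2)
            counts = np.round(rng.random((ng, nj if kind != "glcm" else ng)) * 10)
            if kind == "glcm":
                counts = counts + counts.T  # symmetric
            if counts.sum() == 0:
                counts[0, 0] = 1
            f = matrix_features(TextureMatrix(kind, counts, ng))
            for name, expected in matrix_feature_oracle(kind, counts).items():
                got = f[f"{kind}.{name}"]
                assert got == pytest.approx(expected, rel=1e-10), name

    def test_kind_mismatch_raises(self):
        with pytest.raises(ValueError):
            lalgle(TextureMatrix("glcm", np.ones((2, 2)), 2))
        with pytest.raises(ValueError):
            gln(TextureMatrix("glcm", np.ones((2, 2)), 2))


class TestDirectionEquations:
    def test_lalgle_hand_cases(self):
        counts = np.zeros((2, 2))
        counts[0, 0] = 2.0  # single entry m(1,1)=2, Nz=2
        m = TextureMatrix("glszm", counts, 2)
        assert lalgle(m, "printed") == pytest.approx(2.0)
        assert lalgle(m, "standard") == pytest.approx(1.0)

    def test_gln_hand_cases(self):
        counts = np.zeros((3, 2))
        counts[1, 0] = 5.0  # all 5 zones at one level
        assert gln(TextureMatrix("glszm", counts, 3)) == pytest.approx(5.0)
        spread = np.zeros((4, 1))
        spread[:, 0] = 1.0  # 4 zones over 4 levels
        assert gln(TextureMatrix("glrlm", spread, 4)) == pytest.approx(1.0)

    def test_random_matrices_match_literal_formulas(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            ng, nj = rng.integers(2, 10, size=2)
            counts = np.round(rng.random((ng, nj)) * 7)
            if counts.sum() == 0:
                counts[0, 0] = 2
            nz = counts.sum()
            m = TextureMatrix("glszm", counts, ng)
            printed = sum(
                counts[a, b] ** 2 / (a + 1) ** 2 for a in range(ng) for b in range(nj)
            ) / nz
            standard = sum(
                counts[a, b] * (b + 1) ** 2 / (a + 1) ** 2
                for a in range(ng)
                for b in range(nj)
            ) / nz
            g = sum(counts[a].sum() ** 2 for a in range(ng)) / nz
            assert lalgle(m, "printed") == pytest.approx(printed, rel=1e-10)
            assert lalgle(m, "standard") == pytest.approx(standard, rel=1e-10)
            assert gln(m) == pytest.approx(g, rel=1e-10)

    def test_gln_maximized_by_concentration(self):
        """For fixed Nz, putting every entity on one level maximizes GLN
        (exhaustive over small matrices)."""
        for ng in (2, 3):
            for nz in (2, 4, 6):
                best = None
                concentrated = None
                for combo in itertools.combinations_with_replacement(range(ng), nz):
                    counts = np.zeros((ng, 1))
                    for lvl in combo:
                        counts[lvl, 0] += 1
                    val = gln(TextureMatrix("glrlm", counts, ng))
                    best = max(best, val) if best is not None else val
                    if len(set(combo)) == 1:
                        concentrated = max(concentrated or 0, val)
                assert concentrated == pytest.approx(best)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            gln(TextureMatrix("glszm", np.zeros((2, 2)), 2))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


class TestFilters:
    def test_wavelet_highpass_kills_constants(self):
        img = scalar(np.full((12, 12, 12), 3.0))
        bands = wavelet_subbands(img)
        assert set(bands) == {"".join(t) for t in itertools.product("LH", repeat=3)}
        for tag, band in bands.items():
            if "H" in tag:
                assert np.abs(band.array).max() < 1e-10

    def test_wavelet_lll_of_constant_matches_convolution_oracle(self):
        import pywt

        c = 2.0
        img = scalar(np.full((10, 10), c))
        lll = wavelet_subbands(img)["LL"].array
        # direct oracle: separable low-pass kernel sums on a constant
        lo = np.array(pywt.Wavelet("coif1").dec_lo)
        expected = c * lo.sum() ** 2
        assert np.allclose(lll[4:6, 4:6], expected, rtol=1e-10)

    def test_sinusoid_energy_in_matching_subband(self):
        z = np.sin(np.linspace(0, 12 * np.pi, 32))
        img = scalar(np.tile(z[:, None, None], (1, 8, 8)))
        bands = wavelet_subbands(img)
        hi = np.mean(bands["HLL"].array ** 2)  # high-pass along axis 0
        lo = np.mean(bands["LHH"].array ** 2)
        assert hi > 10 * lo

    def test_log_constant_is_near_zero(self):
        # residue bounded by the truncated kernel's deviation from zero sum
        out = log_filter(scalar(np.full((16, 16), 5.0)), sigma_mm=1.0)
        assert np.abs(out.array).max() < 5.0 * 1e-3

    def test_log_impulse_matches_analytic_kernel(self):
        n = 33
        a = np.zeros((n, n, n))
        a[n // 2, n // 2, n // 2] = 1.0
        sigma = 2.0
        out = log_filter(scalar(a), sigma_mm=sigma).array
        x = np.arange(n) - n // 2
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        r2 = xx**2 + yy**2 + zz**2
        g = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        analytic = g * (r2 - 3 * sigma**2) / sigma**4
        denom = np.abs(analytic).max()
        assert np.abs(out - analytic).max() / denom < 0.05

    def test_log_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            log_filter(scalar(np.ones((4, 4))), sigma_mm=0.0)


# ---------------------------------------------------------------------------
# feature battery
# ---------------------------------------------------------------------------


class TestExtractFeatureVector:
    def make_pair(self, seed=0):
        rng = np.random.default_rng(seed)
        mag = scalar(rng.random((12, 12, 12)))
        lab = scalar(rng.integers(1, 9, size=(12, 12, 12)))
        return {"MVelocity": mag, "DVelocity": lab}

    def test_finite_and_deterministic(self):
        feats1 = extract_feature_vector(self.make_pair())
        feats2 = extract_feature_vector(self.make_pair())
        assert feats1 == feats2
        assert all(np.isfinite(v) for v in feats1.values())

    def test_feature_count_matches_config_bookkeeping(self):
        cfg = FeatureConfig(wavelet=False, log_sigmas_mm=())
        feats = extract_feature_vector(self.make_pair(), cfg)
        n_glcm, n_rlm, n_szm, n_fo = 16, 14, 14, 10
        per_mag = n_fo + n_glcm + (n_rlm + 1) + (n_szm + 3)
        per_dir = per_mag  # same families, first-order on the labels
        assert len(feats) == per_mag + per_dir

    def test_direction_images_not_filtered_by_default(self):
        feats = extract_feature_vector(self.make_pair())
        assert not any(k.startswith("DVelocity.wavelet") for k in feats)
        assert any(k.startswith("MVelocity.wavelet") for k in feats)
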