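import numpy as np
import pytest

from salpinx.texture import (
    FeaturePanelConfig,
    N_LPQ,
    N_BSIF,
    N_SFTA,
    N_TOTAL,
    bsif_features,
    extract_panel,
    feature_names,
    load_default_bsif_bank,
    lpq_features,
    sfta_features,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def lpq_oracle(img, window):
    """Per-pixel windowed-DFT LPQ (no decorrelation), computed by loops."""
    r = window // 2
    a = 1.0 / window
    h, w = img.shape
    freqs = [(a, 0.0), (0.0, a), (a, a), (a, -a)]
    resp = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            win = img[i - r : i + r + 1, j - r : j + r + 1]
            row = []
            for u in freqs:
                f = 0.0 + 0.0j
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        f += win[dy + r, dx + r] * np.exp(
                            -2j * np.pi * (u[0] * dy + u[1] * dx)
                        )
                row.extend([f.real, f.imag])
            resp.append(row)
    resp = np.array(resp)
    # responses that are zero in exact arithmetic code as bit 0
    tol = 1e-9 * max(np.abs(resp).max(), 1.0)
    codes = (np.arange(len(resp)) * 0).copy()
    for k in range(8):
        codes += (resp[:, k] > tol).astype(int) << k
    hist = np.bincount(codes, minlength=256).astype(float)
    return hist / hist.sum()


def bsif_oracle(img, bank):
    """Direct per-pixel convolution + binary coding."""
    n, fh, fw = bank.shape
    r = fh // 2
    h, w = img.shape
    resp = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            win = img[i - r : i + r + 1, j - r : j + r + 1]
            resp.append([float((win * bank[k]).sum()) for k in range(n)])
    resp = np.array(resp)
    tol = 1e-9 * max(np.abs(resp).max(), 1.0)
    codes = np.zeros(len(resp), dtype=int)
    for k in range(n):
        codes += (resp[:, k] > tol).astype(int) << k
    hist = np.bincount(codes, minlength=256).astype(float)
    return hist / hist.sum()


def box_count_oracle(border):
    """Brute-force box counting on a boundary mask."""
    h, w = border.shape
    sizes, counts = [], []
    s = 1
    while s < min(h, w):
        n = 0
        for i in range(0, h, s):
            for j in range(0, w, s):
                if border[i : i + s, j : j + s].any():
                    n += 1
        sizes.append(s)
        counts.append(n)
        s *= 2
    sizes, counts = np.array(sizes, float), np.array(counts, float)
    keep = counts > 0
    slope, _ = np.polyfit(np.log(1.0 / sizes[keep]), np.log(counts[keep]), 1)
    return slope


# ---------------------------------------------------------------------------
# SFTA
# ---------------------------------------------------------------------------


class TestSFTA:
    def test_feature_count_is_45(self, rng):
        channel = rng.random((64, 64))
        assert len(sfta_features(channel)) == N_SFTA

    def test_filled_square_boundary_dimension_near_one(self):
        img = np.zeros((128, 128))
        img[32:96, 32:96] = 1.0
        feats = sfta_features(img, FeaturePanelConfig(sfta_threshold_count=1))
        # single threshold -> one binary image = the square; first feature
        # is the boundary box-counting dimension
        assert abs(feats[0] - 1.0) <= 0.15
        # cross-check against the brute-force oracle on the known boundary
        border = np.zeros((128, 128), dtype=bool)
        border[32:96, [32, 95]] = True
        border[[32, 95], 32:96] = True
        assert abs(feats[0] - box_count_oracle(border)) <= 0.1

    def test_half_filled_plane_pixel_count(self):
        img = np.zeros((256, 256))
        img[:128] = 1.0
        feats = sfta_features(img, FeaturePanelConfig(sfta_threshold_count=1))
        assert feats[2] == 32768  # region pixel count of the upper binary

    def test_rotation_180_invariance(self, rng):
        channel = rng.random((64, 64))
        a = sfta_features(channel)
        b = sfta_features(channel[::-1, ::-1])
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_constant_channel_fallback(self):
        channel = np.full((32, 32), 7.0)
        with pytest.warns(UserWarning, match="constant"):
            feats = sfta_features(channel)
        assert len(feats) == N_SFTA
        assert np.all(np.isfinite(feats))
        # all thresholds equal the constant: every region is empty, the
        # fallback mean is the constant itself
        assert np.all(feats[0::3] == 0.0)
        assert np.all(feats[1::3] == 7.0)
        assert np.all(feats[2::3] == 0.0)


# ---------------------------------------------------------------------------
# LPQ
# ---------------------------------------------------------------------------


class TestLPQ:
    def test_histogram_has_256_bins_summing_to_one(self, rng):
        h = lpq_features(rng.random((32, 32)))
        assert len(h) == N_LPQ
        assert h.min() >= 0
        assert np.isclose(h.sum(), 1.0)

    def test_constant_image_concentrates_in_one_bin(self):
        h = lpq_features(np.full((32, 32), 3.0))
        assert np.isclose(h.max(), 1.0)
        assert (h > 0).sum() == 1

    def test_ramp_matches_brute_force_oracle(self):
        img = np.add.outer(np.arange(8.0), np.arange(8.0))
        cfg = FeaturePanelConfig(lpq_window=3, lpq_decorrelation=False)
        np.testing.assert_allclose(lpq_features(img, cfg), lpq_oracle(img, 3))

    def test_random_image_matches_brute_force_oracle(self, rng):
        img = rng.random((12, 12))
        cfg = FeaturePanelConfig(lpq_window=5, lpq_decorrelation=False)
        np.testing.assert_allclose(lpq_features(img, cfg), lpq_oracle(img, 5))

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            lpq_features(np.zeros((4, 4)), FeaturePanelConfig(lpq_window=7))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            lpq_features(np.zeros((16, 16)), FeaturePanelConfig(lpq_window=4))

    def test_translation_invariance_periodic_texture(self):
        y, x = np.mgrid[0:160, 0:160]
        base = np.sin(2 * np.pi * y / 8) + np.cos(2 * np.pi * x / 8) \
            + 0.5 * np.sin(2 * np.pi * (y + x) / 8)
        shifted = np.roll(np.roll(base, 13, axis=0), 5, axis=1)
        for features in (lpq_features, bsif_features):
            a = features(base)
            b = features(shifted)
            assert np.abs(a - b).sum() < 0.05


# ---------------------------------------------------------------------------
# BSIF
# ---------------------------------------------------------------------------


class TestBSIF:
    def test_shipped_bank_is_valid(self):
        bank = load_default_bsif_bank()
        assert bank.shape == (8, 7, 7)
        assert np.allclose(bank.mean(axis=(1, 2)), 0.0, atol=1e-12)

    def test_histogram_has_256_bins_summing_to_one(self, rng):
        h = bsif_features(rng.random((32, 32)))
        assert len(h) == N_BSIF
        assert np.isclose(h.sum(), 1.0)

    def test_constant_image_all_mass_in_bin_zero(self):
        h = bsif_features(np.full((32, 32), 9.0))
        assert h[0] == 1.0

    def test_random_image_matches_brute_force_oracle(self, rng):
        img = rng.random((10, 10))
        bank = rng.standard_normal((8, 3, 3))
        bank -= bank.mean(axis=(1, 2), keepdims=True)
        cfg = FeaturePanelConfig(bsif_filterbank=bank)
        np.testing.assert_allclose(bsif_features(img, cfg), bsif_oracle(img, bank))

    def test_wrong_filter_count_rejected(self, rng):
        cfg = FeaturePanelConfig(bsif_filterbank=rng.standard_normal((5, 3, 3)))
        with pytest.raises(ValueError, match="8 filters"):
            bsif_features(rng.random((16, 16)), cfg)


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------


class TestPanel:
    def test_panel_length_and_split(self, benign_tile):
        fv = extract_panel(benign_tile, FeaturePanelConfig(normalize=False))
        assert len(fv.values) == N_TOTAL == 1114
        hema = [n for n in fv.names if n.startswith("hematoxylin.")]
        eosin = [n for n in fv.names if n.startswith("eosin.")]
        assert len(hema) == len(eosin) == 557

    def test_names_unique_and_stable(self):
        names = feature_names()
        assert len(names) == len(set(names)) == 1114
        assert names == feature_names()
        assert names[0] == "hematoxylin.sfta.000"
        assert names[-1] == "eosin.bsif.255"

    def test_identical_tiles_give_identical_vectors(self, benign_tile):
        cfg = FeaturePanelConfig(normalize=False)
        a = extract_panel(benign_tile, cfg)
        b = extract_panel(benign_tile, cfg)
        np.testing.assert_array_equal(a.values, b.values)
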