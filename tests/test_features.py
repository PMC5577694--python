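"""Texture feature families: counts, hand-computed oracles, mask honoring."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import mammotex as mx
from mammotex.features import (cooccurrence_matrix, intensity_features,
                               markovian_features, regional_features,
                               run_length_features, run_length_matrix,
                               fourier_features, wavelet_features,
                               feature_names, FAMILY_COUNTS)
from mammotex.image import MammogramImage, quantize_gray_levels


def _image(pixels, mask=None):
    pixels = np.asarray(pixels, dtype=np.uint8)
    if mask is None:
        mask = np.ones_like(pixels, dtype=bool)
    return MammogramImage(pixels=pixels, mask=mask)


class TestRegistry:
    def test_total_and_family_counts(self):
        names = feature_names()
        assert len(names) == 363
        from collections import Counter
        counts = Counter(mx.family_of(n) for n in names)
        assert counts == FAMILY_COUNTS == {
            "moment": 76, "histogram": 16, "markovian": 93, "regional": 48,
            "runlength": 60, "fourier": 33, "wavelet": 37}

    def test_extraction_matches_registry(self, textured_image):
        fv = mx.extract_features(textured_image)
        assert list(fv.index) == feature_names()
        assert np.isfinite(fv.to_numpy()).all()

    def test_extraction_deterministic(self, textured_image):
        a = mx.extract_features(textured_image)
        b = mx.extract_features(textured_image)
        assert (a.to_numpy() == b.to_numpy()).all()


class TestIntensityFeatures:
    def test_constant_image(self, constant_image):
        f = intensity_features(constant_image)
        assert f["moment.mean"] == 100.0
        assert f["moment.variance"] == 0.0
        assert all(f[f"moment.ncm.k{k:02d}"] == 0.0 for k in range(2, 20))
        assert f["histogram.bin06"] == 1.0  # 100 falls in bin [96, 112)
        assert sum(f[f"histogram.bin{i:02d}"] for i in range(16)) == 1.0

    def test_two_pixel_extremes(self):
        img = _image([[0, 255], [0, 255]],
                     mask=np.array([[True, True], [False, False]]))
        f = intensity_features(img)
        assert f["moment.mean"] == 127.5
        assert f["histogram.bin00"] == 0.5
        assert f["histogram.bin15"] == 0.5

    def test_histogram_sums_to_one(self, textured_image):
        f = intensity_features(textured_image)
        total = sum(f[f"histogram.bin{i:02d}"] for i in range(16))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_ncm_transform_consistency(self, textured_image):
        # T3(m) = m / (1 + |m|) recomputed from the raw NCM.
        f = intensity_features(textured_image)
        for k in (3, 7, 15):
            m = f[f"moment.ncm.k{k:02d}"]
            assert f[f"moment.ncm_ratio.k{k:02d}"] == pytest.approx(
                m / (1 + abs(m)))
            assert f[f"moment.ncm_slog.k{k:02d}"] == pytest.approx(
                np.sign(m) * np.log1p(abs(m)))


class TestCooccurrence:
    def test_horizontal_pairs_hand_enumerated(self):
        # Two 0-rows pairs at 0 deg: (0,0) and (1,1) each with prob 1/2.
        q = quantize_gray_levels(_image([[0, 0], [128, 128]]), 2)
        P = cooccurrence_matrix(q, 1, 0)
        assert P[0, 0] == 0.5 and P[1, 1] == 0.5
        assert P[0, 1] == 0.0

    def test_vertical_pairs_hand_enumerated(self):
        q = quantize_gray_levels(_image([[0, 0], [128, 128]]), 2)
        P = cooccurrence_matrix(q, 1, 90)
        assert P[0, 1] == 0.5 and P[1, 0] == 0.5

    def test_constant_image_single_entry(self, constant_image):
        q = quantize_gray_levels(constant_image, 64)
        P = cooccurrence_matrix(q, 1, 45)
        assert P[25, 25] == 1.0  # 100 // 4 = 25

    def test_symmetric_and_normalized(self, textured_image):
        q = quantize_gray_levels(textured_image, 64)
        for o in (0, 45, 90, 135):
            P = cooccurrence_matrix(q, 1, o)
            assert np.allclose(P, P.T)
            assert P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_masked_pairs_only(self):
        # A mask splitting the image in two: no cross-boundary pairs.
        pixels = np.array([[0, 255], [0, 255]])
        mask = np.array([[True, False], [True, False]])
        q = quantize_gray_levels(_image(pixels, mask), 2)
        P = cooccurrence_matrix(q, 1, 90)
        assert P[0, 0] == 1.0  # only the vertical dark pair survives
        with pytest.raises(ValueError, match="pair"):
            cooccurrence_matrix(q, 1, 0)


class TestMarkovian:
    def test_constant_image_limits(self, constant_image):
        f = markovian_features(quantize_gray_levels(constant_image, 64))
        for o in (0, 45, 90, 135):
            assert f[f"markovian.contrast.a{o:03d}"] == 0.0
            assert f[f"markovian.asm.a{o:03d}"] == 1.0
            assert f[f"markovian.entropy.a{o:03d}"] == 0.0

    def test_contrast_from_hand_matrix(self):
        # P diagonal at 0 deg -> contrast sum P(i,j)(i-j)^2 = 0.
        q = quantize_gray_levels(_image([[0, 0], [128, 128]]), 64)
        f = markovian_features(q)
        assert f["markovian.contrast.a000"] == 0.0
        # Vertical pairs are all (0, 32): contrast = 32^2.
        assert f["markovian.contrast.a090"] == pytest.approx(32.0 ** 2)

    def test_exactly_93_finite_values(self, textured_image):
        f = markovian_features(quantize_gray_levels(textured_image, 64))
        assert len(f) == 93
        assert np.isfinite(list(f.values())).all()

    def test_orientation_average_is_mean(self, textured_image):
        f = markovian_features(quantize_gray_levels(textured_image, 64))
        manual = np.mean([f[f"markovian.contrast.a{o:03d}"]
                          for o in (0, 45, 90, 135)])
        assert f["markovian.avg.contrast"] == pytest.approx(manual)


class TestRunLength:
    def test_constant_rows_hand_count(self):
        # 4x4 constant image, 0 deg: 4 runs of length 4.
        q = quantize_gray_levels(_image(np.full((4, 4), 80)), 16)
        counts = run_length_matrix(q, 0)
        assert counts[5, 3] == 4  # level 80//16=5, length index 4-1
        f = run_length_features(q)
        assert f["runlength.rp.a000"] == pytest.approx(4 / 16)
        assert f["runlength.sre.a000"] == pytest.approx((1 / 4) * (4 / 16))

    def test_checkerboard_all_short_runs(self):
        pix = np.zeros((8, 8), int)
        pix[(np.indices((8, 8)).sum(axis=0) % 2) == 1] = 255
        q = quantize_gray_levels(_image(pix), 2)
        f = run_length_features(q)
        assert f["runlength.rp.a000"] == 1.0
        assert f["runlength.sre.a000"] == 1.0

    def test_runs_truncated_at_mask_boundary(self):
        # A hole in the middle of a constant row splits one run into two.
        mask = np.ones((1, 5), bool)
        mask[0, 2] = False
        q = quantize_gray_levels(_image(np.full((1, 5), 64), mask), 16)
        counts = run_length_matrix(q, 0)
        assert counts[4, 1] == 2  # two runs of length 2
        assert counts.sum() == 2

    def test_sixty_values(self, textured_image):
        f = run_length_features(quantize_gray_levels(textured_image, 16))
        assert len(f) == 60
        assert np.isfinite(list(f.values())).all()


class TestRegional:
    def test_two_bright_squares_hand_count(self):
        pixels = np.zeros((40, 40), np.uint8)
        pixels[5:15, 5:15] = 200
        pixels[25:35, 25:35] = 200
        f = regional_features(_image(pixels))
        assert f["regional.log_count.t128"] == pytest.approx(np.log(3))
        assert f["regional.mean_area.t128"] == 100.0
        assert f["regional.largest_fraction.t128"] == pytest.approx(
            100 / 1600)
        assert f["regional.mean_gray.t128"] == pytest.approx(200.0)

    def test_all_dark_image_is_zero(self):
        f = regional_features(_image(np.zeros((32, 32))))
        assert all(v == 0.0 for v in f.values())

    def test_top_threshold_unreachable(self, textured_image):
        f = regional_features(textured_image)
        assert all(f[k] == 0.0 for k in f if k.endswith("t256"))
        assert len(f) == 48


class TestSpectral:
    def test_constant_image_zero_fractions(self, constant_image):
        f = fourier_features(constant_image)
        assert all(v == 0.0 for v in f.values())
        w = wavelet_features(constant_image)
        assert all(w[k] == 0.0 for k in w if ".energy." in k
                   or ".efrac." in k or ".entropy." in k)
        assert w["wavelet.approx_energy"] > 0

    def test_sinusoid_period_lands_in_right_annulus(self):
        cols = np.arange(64)
        pix = (127.5 + 120 * np.sin(2 * np.pi * cols / 8.0))
        img = _image(np.tile(np.clip(pix, 0, 255).astype(np.uint8), (64, 1)))
        f = fourier_features(img)
        fractions = [f[f"fourier.annulus.{i:02d}"] for i in range(16)]
        # Frequency 1/8 = 0.125 falls in annulus 3 (edges k/32).
        assert int(np.argmax(fractions)) == 3

    def test_fraction_partitions_bounded(self, textured_image):
        f = fourier_features(textured_image)
        ann = sum(f[f"fourier.annulus.{i:02d}"] for i in range(16))
        sec = sum(f[f"fourier.sector.{i:02d}"] for i in range(16))
        assert ann <= 1 + 1e-9
        assert sec <= 1 + 1e-9
        w = wavelet_features(textured_image)
        assert len(f) == 33 and len(w) == 37

    def test_tiny_crop_rejected(self):
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        img = _image(np.full((40, 40), 50), mask)
        with pytest.raises(ValueError, match="16x16"):
            fourier_features(img)


class TestMaskHonor:
    def test_background_pixels_do_not_leak(self, textured_image):
        altered = textured_image.pixels.copy()
        altered[~textured_image.mask] = 217  # scribble on the background
        noisy = MammogramImage(pixels=altered, mask=textured_image.mask)
        a = mx.extract_features(textured_image)
        b = mx.extract_features(noisy)
        spatial = [n for n in a.index
                   if mx.family_of(n) in ("moment", "histogram", "markovian",
                                          "runlength", "regional")]
        assert (a[spatial] == b[spatial]).all()
        # Spectral families mean-fill the background inside the bounding
        # box, so they too are untouched by background edits.
        assert np.allclose(a.to_numpy(), b.to_numpy())


def test_density_sensitive_features_track_target_pmd():
    """Designed density signal: upper histogram mass rises with target PMD."""
    rng = np.random.default_rng(5)
    targets = rng.uniform(5, 95, size=60)
    upper, means = [], []
    for i, t in enumerate(targets):
        img = mx.generate_mammogram(48, 48, float(t), 3, seed=900 + i)
        f = intensity_features(img)
        upper.append(sum(f[f"histogram.bin{b:02d}"] for b in range(8, 16)))
        means.append(f["moment.mean"])
    assert spearmanr(targets, upper).statistic > 0.5
    assert spearmanr(targets, means).statistic > 0.5
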