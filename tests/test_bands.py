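"""Spline smoothing, region PCA, weight curves and wavelength selection."""

import numpy as np
import pytest

from dbytk.bands import (
    build_roiset,
    pca_region,
    select_wavelengths,
    smooth_curve,
    weight_curve,
)
from dbytk.cube import DEFAULT_WAVELENGTHS
from dbytk.synth import make_dataset, make_spectra_bank


class TestSmoothCurve:
    def test_constant_reproduced(self):
        c = np.full(101, 0.37)
        np.testing.assert_allclose(smooth_curve(c), c, atol=1e-9)

    def test_linear_ramp_reproduced(self):
        ramp = np.linspace(0.1, 0.9, 101)
        np.testing.assert_allclose(smooth_curve(ramp), ramp, atol=1e-9)

    def test_noisy_sine_denoised(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 2 * np.pi, 101)
        clean = 0.5 + 0.2 * np.sin(x)
        noisy = clean + rng.normal(0, 0.02, size=x.size)
        sm = smooth_curve(noisy)
        rms = np.sqrt(np.mean((sm - noisy) ** 2))
        assert rms < 0.02
        tv = lambda v: np.abs(np.diff(v)).sum()
        assert tv(sm) < tv(noisy)

    def test_nonfinite_rejected(self):
        c = np.full(101, 0.3)
        c[5] = np.nan
        with pytest.raises(ValueError):
            smooth_curve(c)


class TestPCA:
    def test_two_band_perfect_correlation(self):
        # band2 == band1 with values 1,2,3: one PC carries all variance
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        res = pca_region(x, np.array([500.0, 505.0]), (500, 505))
        var = np.var([1, 2, 3], ddof=1)
        np.testing.assert_allclose(res.eigenvalues, [2 * var, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(res.loadings[0]),
                                   [1 / np.sqrt(2)] * 2, atol=1e-12)

    def test_region_band_count(self):
        rng = np.random.default_rng(0)
        x = rng.random((300, 101))
        res = pca_region(x, DEFAULT_WAVELENGTHS, (450, 850))
        assert res.loadings.shape[1] == 81  # (850-450)/5 + 1

    def test_trace_identity_and_orthonormal_loadings(self):
        rng = np.random.default_rng(1)
        x = rng.random((200, 5))
        wl = np.arange(400, 425, 5.0)
        res = pca_region(x, wl, (400, 420))
        cov = np.cov(x, rowvar=False)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov), rel=1e-9)
        gram = res.loadings @ res.loadings.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_matches_sklearn_oracle(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        x = rng.random((150, 8))
        wl = np.arange(400, 440, 5.0)
        res = pca_region(x, wl, (400, 435))
        ref = sklearn.PCA(n_components=8).fit(x)
        np.testing.assert_allclose(res.eigenvalues,
                                   ref.explained_variance_, atol=1e-8)
        for ours, theirs in zip(res.loadings, ref.components_):
            sign = np.sign(np.dot(ours, theirs))
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.random((100, 6))
        wl = np.arange(400, 430, 5.0)
        a = pca_region(x, wl, (400, 425))
        b = pca_region(3.0 * x, wl, (400, 425))
        np.testing.assert_allclose(b.eigenvalues, 9.0 * a.eigenvalues,
                                   rtol=1e-9)
        for la, lb in zip(a.loadings, b.loadings):
            sign = np.sign(np.dot(la, lb))
            np.testing.assert_allclose(la, sign * lb, atol=1e-8)

    def test_rank_deficient_sample_rejected(self):
        x = np.random.default_rng(0).random((5, 10))
        wl = np.arange(400, 450, 5.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            pca_region(x, wl, (400, 445))


class TestWeightCurve:
    def test_eigenvalue_times_loading(self):
        rng = np.random.default_rng(4)
        x = rng.random((100, 4))
        wl = np.arange(400, 420, 5.0)
        res = pca_region(x, wl, (400, 415))
        g = weight_curve(res, 2)
        np.testing.assert_allclose(
            g, res.eigenvalues[1] * res.loadings[1], rtol=1e-12
        )

    def test_zero_eigenvalue_gives_zero_curve(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        res = pca_region(x, np.array([500.0, 505.0]), (500, 505))
        np.testing.assert_allclose(weight_curve(res, 2), 0.0, atol=1e-10)

    def test_argmax_invariant_to_eigenvalue_scaling(self):
        rng = np.random.default_rng(5)
        x = rng.random((200, 7))
        wl = np.arange(400, 435, 5.0)
        res = pca_region(x, wl, (400, 430))
        for pc in range(1, 5):
            g = weight_curve(res, pc)
            assert np.argmax(np.abs(g)) == np.argmax(np.abs(res.loadings[pc - 1]))


class TestSelectWavelengths:
    def test_recovers_constructed_triple_peak(self):
        # three Gaussian peaks at exactly 500/650/800 nm over a flat floor
        wl = np.arange(450.0, 851.0, 5.0)
        g = (1.0 * np.exp(-(((wl - 500) / 12.0) ** 2))
             + 0.8 * np.exp(-(((wl - 650) / 12.0) ** 2))
             + 0.9 * np.exp(-(((wl - 800) / 12.0) ** 2)))
        # brute-force extrema oracle: all strict interior local maxima
        peaks = [wl[i] for i in range(1, len(g) - 1)
                 if g[i] > g[i - 1] and g[i] > g[i + 1]]
        assert peaks == [500.0, 650.0, 800.0]
        assert select_wavelengths(g, wl, k=3, min_sep=80) == peaks

    def test_monotone_curve_has_insufficient_extrema(self):
        wl = np.arange(450.0, 851.0, 5.0)
        with pytest.raises(ValueError, match="insufficient extrema"):
            select_wavelengths(np.linspace(0, 1, wl.size), wl, k=3)

    def test_min_sep_enforced(self):
        wl = np.arange(450.0, 851.0, 5.0)
        g = (np.exp(-(((wl - 500) / 10.0) ** 2))
             + 0.9 * np.exp(-(((wl - 540) / 10.0) ** 2))
             + 0.8 * np.exp(-(((wl - 800) / 10.0) ** 2)))
        sel = select_wavelengths(g, wl, k=2, min_sep=80)
        assert sel == [500.0, 800.0]  # 540 blocked by separation from 500

    def test_stable_across_generator_seeds(self):
        # same spectra bank, five scene seeds -> identical triple
        bank = make_spectra_bank(0)
        triples = set()
        for seed in range(1, 6):
            scenes = make_dataset(6, seed=seed, total_boxes=30,
                                  height=96, width=96, bank=bank)
            roi = build_roiset(scenes, max_pixels_per_roi=15000, seed=0)
            res = pca_region(roi.pooled(), roi.wavelengths, (450, 850))
            g = weight_curve(res, 3)
            triples.add(tuple(select_wavelengths(g, res.wavelengths)))
        assert len(triples) == 1


def test_roiset_minimum_pixels_enforced(bank):
    scenes = make_dataset(5, seed=1, total_boxes=20, height=48, width=48,
                          bank=bank)
    with pytest.raises(ValueError, match="pixels"):
        build_roiset(scenes, min_pixels=10**7)
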