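"""Decay model, binning and bi-exponential fitting."""

import numpy as np
import pytest

from mcflim.decay import (
    CHANNEL_WIDTH_PS,
    LASER_PERIOD_PS,
    N_CHANNELS,
    DecayCube,
    FitConfig,
    IRF,
    amplitude_ratios,
    bin_decays,
    delta_irf,
    fit_image,
    fit_pixel,
    gaussian_irf,
    mean_lifetime,
    model_decay,
    time_axis,
)


class TestModelDecay:
    def test_mono_exponential_limit(self, dirac):
        """With a2 = 0 and a delta IRF the curve is a pure exponential."""
        tau = 800.0
        curve = model_decay(1.0, tau, 0.0, 1.0, dirac)
        expected = np.exp(-time_axis() / tau)
        np.testing.assert_allclose(curve / curve[0], expected / expected[0], rtol=1e-9)

    def test_curve_sum_matches_geometric_oracle(self, dirac):
        """Channel sum approximates sum_i a_i tau_i / dt (1 - exp(-T/tau_i))."""
        a1, tau1, a2, tau2 = 1.5, 533.0, 1.0, 2289.0
        curve = model_decay(a1, tau1, a2, tau2, dirac)
        oracle = sum(
            a * tau / CHANNEL_WIDTH_PS * (1.0 - np.exp(-LASER_PERIOD_PS / tau))
            for a, tau in ((a1, tau1), (a2, tau2))
        )
        assert abs(curve.sum() - oracle) / oracle < 1e-3

    def test_gaussian_irf_matches_oversampled_convolution(self):
        """Discrete convolution agrees with a 10x oversampled numeric one."""
        a1, tau1, a2, tau2 = 2.0, 400.0, 1.0, 2000.0
        fwhm, peak_ch = 150.0, 10
        irf = gaussian_irf(fwhm_ps=fwhm, peak_channel=peak_ch)
        curve = model_decay(a1, tau1, a2, tau2, irf)

        over = 10
        dt = CHANNEL_WIDTH_PS / over
        tf = (np.arange(N_CHANNELS * over) + 0.5) * dt
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        irf_f = np.exp(-0.5 * ((tf - peak_ch * CHANNEL_WIDTH_PS) / sigma) ** 2)
        irf_f /= irf_f.sum()
        decay_f = a1 * np.exp(-tf / tau1) + a2 * np.exp(-tf / tau2)
        conv_f = np.convolve(irf_f, decay_f)[: tf.size]
        # discrete convolution of midpoint samples lags by half a fine bin;
        # trapezoid average recovers the fine-bin midpoint values
        mid = 0.5 * (np.r_[0.0, conv_f[:-1]] + conv_f)
        oracle = mid.reshape(N_CHANNELS, over).mean(axis=1)

        sel = oracle > 1e-3 * oracle.max()
        np.testing.assert_allclose(curve[sel], oracle[sel], rtol=5e-3)

    def test_rejects_nonpositive_lifetime(self, dirac):
        with pytest.raises(ValueError):
            model_decay(1.0, -5.0, 1.0, 2000.0, dirac)


class TestDerivedParameters:
    @pytest.mark.parametrize(
        "a1,tau1,a2,tau2,expected",
        [
            (0.0, 123.0, 1.0, 2289.0, 2289.0),
            (1.5, 533.0, 1.0, 2289.0, 1235.4),
            (1.0, 500.0, 1.0, 1500.0, 1000.0),
        ],
    )
    def test_mean_lifetime(self, a1, tau1, a2, tau2, expected):
        assert mean_lifetime(a1, tau1, a2, tau2) == pytest.approx(expected)

    def test_mean_lifetime_undefined(self):
        with pytest.raises(ValueError):
            mean_lifetime(0.0, 500.0, 0.0, 2000.0)

    @pytest.mark.parametrize(
        "a1,a2,ratio,asym",
        [(2.0, 2.0, 1.0, 0.0), (3.0, 1.0, 3.0, 0.5), (1.5, 1.0, 1.5, 0.2)],
    )
    def test_amplitude_ratios(self, a1, a2, ratio, asym):
        r, a = amplitude_ratios(a1, a2)
        assert r == pytest.approx(ratio)
        assert a == pytest.approx(asym)

    def test_ratio_undefined_for_zero_a2(self):
        with pytest.raises(ValueError):
            amplitude_ratios(1.0, 0.0)


class TestBinning:
    def test_b0_is_identity(self, rng):
        cube = rng.poisson(5.0, (6, 6, 8)).astype(float)
        np.testing.assert_array_equal(bin_decays(cube, 0), cube)

    def test_b3_kernel_covers_center_plus_48_neighbors(self):
        """Binning value 3 sums a 7x7 window: the center plus 48 neighbors."""
        img = np.zeros((15, 15, 1))
        img[7, 7, 0] = 1.0
        out = bin_decays(img, 3)
        assert int(round(out[:, :, 0].sum())) == 49
        assert out[7, 7, 0] == pytest.approx(1.0)
        assert out[7, 4, 0] == pytest.approx(1.0)  # 3 pixels away still in window
        assert out[7, 3, 0] == pytest.approx(0.0)

    def test_uniform_interior_value(self):
        c = 3.0
        cube = np.full((9, 9, 4), c)
        out = bin_decays(cube, 3)
        assert out[4, 4, 0] == pytest.approx(49 * c)

    def test_wrap_conserves_photons_exactly(self, rng):
        cube = rng.poisson(4.0, (10, 12, 5)).astype(float)
        out = bin_decays(cube, 3, boundary="wrap")
        assert out.sum() == pytest.approx(49 * cube.sum(), rel=1e-9)

    def test_truncation_loses_border_photons(self, rng):
        cube = rng.poisson(4.0, (10, 12, 5)).astype(float)
        out = bin_decays(cube, 3, boundary="truncate")
        assert out.sum() < 49 * cube.sum()


class TestFitPixel:
    def test_noiseless_roundtrip(self, dirac):
        truth = dict(a1=2.0, tau1=400.0, a2=1.0, tau2=2000.0)
        y = model_decay(truth["a1"], truth["tau1"], truth["a2"], truth["tau2"], dirac)
        fit = fit_pixel(y, dirac, FitConfig(intensity_threshold=0))
        assert fit.valid
        for name, val in truth.items():
            assert getattr(fit, name) == pytest.approx(val, rel=1e-2)

    def test_below_threshold_masked(self, dirac):
        y = np.ones(N_CHANNELS)  # 256 photons at 50 mW -> ~5 photons/mW
        fit = fit_pixel(y, dirac, FitConfig(intensity_threshold=200.0), power_mw=50.0)
        assert not fit.valid

    def test_amplitude_rescaling_invariance(self, dirac):
        """Scaling the curve scales amplitudes linearly; lifetimes are unchanged."""
        base = model_decay(5000.0, 500.0, 3000.0, 2000.0, dirac)
        assert base.min() >= 1.0  # keeps the weight floor inactive
        cfg = FitConfig(intensity_threshold=0)
        f1 = fit_pixel(base, dirac, cfg)
        f2 = fit_pixel(4.0 * base, dirac, cfg)
        assert f2.tau1 == pytest.approx(f1.tau1, rel=1e-3)
        assert f2.tau2 == pytest.approx(f1.tau2, rel=1e-3)
        assert f2.a1 == pytest.approx(4.0 * f1.a1, rel=1e-3)
        assert f2.a2 == pytest.approx(4.0 * f1.a2, rel=1e-3)

    def test_poisson_replicates_unbiased_at_resting_mc_point(self, girf):
        """Mean recovered tau_m over 200 noisy 5,000-photon decays hits truth."""
        r = 1.5
        a1, a2 = r / (1 + r), 1 / (1 + r)
        truth_tm = mean_lifetime(a1, 533.0, a2, 2289.0)
        curve = model_decay(a1, 533.0, a2, 2289.0, girf)
        curve = curve / curve.sum() * 5000.0
        rng = np.random.default_rng(123)
        cfg = FitConfig(intensity_threshold=0)
        tms = np.array([fit_pixel(rng.poisson(curve), girf, cfg).tau_m for _ in range(200)])
        se = tms.std(ddof=1) / np.sqrt(tms.size)
        assert abs(tms.mean() - truth_tm) < 3 * se


class TestFitImage:
    def test_all_zero_cube_fully_masked(self, dirac):
        cube = DecayCube(np.zeros((4, 4, N_CHANNELS)), irf=dirac)
        maps = fit_image(cube, config=FitConfig(intensity_threshold=200.0))
        assert not maps.valid.any()
        assert np.isnan(maps.tau_m).all()

    def test_two_region_contrast(self, girf, rng):
        """Regions at tau_m 600 vs 1,600 ps separate by many SDs after fitting."""
        def region_curve(tau_m):
            t1, t2 = 300.0, 2200.0
            r = (t2 - tau_m) / (tau_m - t1)
            a1, a2 = r / (1 + r), 1 / (1 + r)
            c = model_decay(a1, t1, a2, t2, girf)
            return c / c.sum() * 2000.0

        H, W = 8, 16
        expected = np.empty((H, W, N_CHANNELS))
        expected[:, : W // 2] = region_curve(600.0)
        expected[:, W // 2 :] = region_curve(1600.0)
        cube = DecayCube(rng.poisson(expected), irf=girf, power_mw=1.0)
        maps = fit_image(cube, config=FitConfig(binning=1, intensity_threshold=100.0))
        left = maps.tau_m[2:-2, 2 : W // 2 - 2]
        right = maps.tau_m[2:-2, W // 2 + 2 : -2]
        sd = max(left.std(), right.std(), 1e-9)
        assert right.mean() - left.mean() > 10 * sd

    def test_tau_m_between_components(self, girf, rng):
        curve = model_decay(1.0, 500.0, 1.0, 2000.0, girf)
        curve = curve / curve.sum() * 5000.0
        cube = DecayCube(rng.poisson(np.broadcast_to(curve, (3, 3, N_CHANNELS)).copy()),
                         irf=girf)
        maps = fit_image(cube, config=FitConfig(binning=0, intensity_threshold=0.0))
        ok = maps.valid
        assert ok.any()
        assert np.all(maps.tau_m[ok] >= maps.tau1[ok] - 1e-9)
        assert np.all(maps.tau_m[ok] <= maps.tau2[ok] + 1e-9)
        assert np.all(np.abs(maps.asym[ok]) <= 1.0 + 1e-12)


def test_irf_requires_unit_normalizable_kernel():
    with pytest.raises(ValueError):
        IRF(np.zeros(16))
    k = IRF(np.ones(16)).kernel
    assert k.sum() == pytest.approx(1.0, abs=1e-9)
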