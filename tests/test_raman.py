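import numpy as np
import pytest
from scipy.stats import t as student_t

import attenuskin as ak
from attenuskin.raman import (
    ArplsConfig,
    RamanSpectrum,
    arpls_baseline,
    difference_spectrum,
    group_statistics,
    normalize_fingerprint,
    regrid,
    remove_cosmic_rays,
    smooth,
    whittaker_baseline,
)

W = np.arange(700.0, 1901.0, 1.0)


def make_spectrum(y, w=None):
    return RamanSpectrum(W.copy() if w is None else w, np.asarray(y, dtype=float))


class TestDespike:
    def test_clean_spectrum_unchanged(self):
        y = 100 + 50 * np.sin(W / 300.0)
        out = remove_cosmic_rays(make_spectrum(y), 8.0)
        np.testing.assert_array_equal(out.intensities, y)

    def test_known_spike_restored(self, raman_pair):
        sp, truth = raman_pair
        rng = np.random.default_rng(1)
        clean = truth["background"] + truth["bands"] + rng.normal(0, 5, W.size)
        spiked = clean.copy()
        spiked[600] += 50 * 5.0  # 50-SD spike
        out = remove_cosmic_rays(make_spectrum(spiked), 8.0)
        assert abs(out.intensities[600] - clean[600]) < 3 * 5.0

    def test_boundary_spike(self):
        y = np.full(W.size, 100.0)
        y[-1] += 5000.0
        out = remove_cosmic_rays(make_spectrum(y), 8.0)
        assert out.intensities[-1] == pytest.approx(100.0)

    def test_min_channels(self):
        with pytest.raises(ValueError):
            remove_cosmic_rays(
                RamanSpectrum(np.arange(4.0), np.ones(4)), 8.0
            )


class TestSmooth:
    def test_polynomial_reproduction(self):
        # degree <= order polynomials pass through unchanged (interior)
        y = 3.0 + 0.5 * W - 1e-4 * W**2 + 1e-8 * W**3
        out = smooth(make_spectrum(y), window=11, order=3)
        np.testing.assert_allclose(out.intensities[5:-5], y[5:-5], rtol=1e-9)

    def test_constant_unchanged(self):
        out = smooth(make_spectrum(np.full(W.size, 7.0)), 11, 3)
        np.testing.assert_allclose(out.intensities, 7.0)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, W.size)
        out = smooth(make_spectrum(y), 11, 3)
        assert out.intensities.var() < y.var()

    def test_window_validation(self):
        with pytest.raises(ValueError):
            smooth(make_spectrum(np.ones(W.size)), 10, 3)
        with pytest.raises(ValueError):
            smooth(RamanSpectrum(np.arange(5.0), np.ones(5)), 7, 3)


class TestNormalize:
    def test_scale_invariance(self, raman_pair):
        sp, _ = raman_pair
        n1 = normalize_fingerprint(sp)
        n2 = normalize_fingerprint(sp.with_intensities(10.0 * sp.intensities, "x10"))
        np.testing.assert_allclose(n1.intensities, n2.intensities, rtol=1e-12)

    def test_unit_integral(self, raman_pair):
        sp, _ = raman_pair
        out = normalize_fingerprint(sp)
        mask = (out.wavenumbers >= 800) & (out.wavenumbers <= 1800)
        integral = np.trapezoid(out.intensities[mask], out.wavenumbers[mask])
        assert integral == pytest.approx(1.0, abs=1e-12)

    def test_riemann_oracle(self, raman_pair):
        sp, _ = raman_pair
        mask = (sp.wavenumbers >= 800) & (sp.wavenumbers <= 1800)
        w, y = sp.wavenumbers[mask], sp.intensities[mask]
        # fine-grid Riemann sum of the piecewise-linear interpolant
        fine = np.linspace(w[0], w[-1], 200_001)
        step = fine[1] - fine[0]
        riemann = float(np.sum(np.interp(fine[:-1] + step / 2, w, y)) * step)
        area = float(np.trapezoid(y, w))
        assert area == pytest.approx(riemann, rel=1e-6)

    def test_idempotence(self, raman_pair):
        sp, _ = raman_pair
        once = normalize_fingerprint(sp)
        twice = normalize_fingerprint(once)
        np.testing.assert_allclose(once.intensities, twice.intensities, rtol=1e-12)

    def test_axis_coverage_required(self):
        short = RamanSpectrum(np.arange(900.0, 1000.0), np.ones(100))
        with pytest.raises(ValueError):
            normalize_fingerprint(short)

    def test_nonpositive_integral(self):
        with pytest.raises(ValueError):
            normalize_fingerprint(make_spectrum(np.zeros(W.size)))


class TestArpls:
    def test_all_zero(self):
        base, corr = arpls_baseline(make_spectrum(np.zeros(W.size)))
        np.testing.assert_allclose(base, 0.0, atol=1e-12)
        np.testing.assert_allclose(corr.intensities, 0.0, atol=1e-12)

    def test_linear_background_exact(self):
        y = 100.0 + 0.3 * W
        base, corr = arpls_baseline(make_spectrum(y))
        np.testing.assert_allclose(base, y, atol=1e-6)
        np.testing.assert_allclose(corr.intensities, 0.0, atol=1e-6)

    def test_noisy_smooth_background_recovered(self, raman_pair):
        _, truth = raman_pair
        rng = np.random.default_rng(7)
        noisy = truth["background"] + rng.normal(0, 5.0, W.size)
        base, _ = arpls_baseline(make_spectrum(noisy))
        dev = np.abs(base - truth["background"])
        assert dev.max() < 5.0  # below the noise scale

    def test_truth_recovery_beats_unweighted_oracle(self, raman_pair):
        sp, truth = raman_pair
        base, _ = arpls_baseline(sp)
        rmse = np.sqrt(np.mean((base - truth["background"]) ** 2))
        oracle = whittaker_baseline(sp.intensities, 1e5)
        rmse_oracle = np.sqrt(np.mean((oracle - truth["background"]) ** 2))
        assert rmse < 10.0
        assert rmse < rmse_oracle

    def test_peak_insensitivity(self, raman_pair):
        _, truth = raman_pair
        rng = np.random.default_rng(8)
        bg = truth["background"] + rng.normal(0, 5.0, W.size)
        peak = 500.0 * np.exp(-0.5 * ((W - 1300.0) / 10.0) ** 2)
        b0, _ = arpls_baseline(make_spectrum(bg))
        b1, _ = arpls_baseline(make_spectrum(bg + peak))
        center = np.argmin(np.abs(W - 1300.0))
        assert abs(b1[center] - b0[center]) < 0.10 * 500.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ArplsConfig(lambda_smooth=-1.0).validate()
        with pytest.raises(ValueError):
            ArplsConfig(max_iter=0).validate()

    def test_nonconvergence_warns(self, raman_pair):
        sp, _ = raman_pair
        with pytest.warns(RuntimeWarning):
            arpls_baseline(sp, ArplsConfig(max_iter=2, ratio_tol=1e-12))


class TestGroupStatistics:
    def _noise_spectra(self, n, sd=3.0, seed=0):
        rng = np.random.default_rng(seed)
        base = 100 + 10 * np.sin(W / 150)
        return [make_spectrum(base + rng.normal(0, sd, W.size)) for _ in range(n)]

    def test_identical_spectra_zero_ci(self):
        spectra = [make_spectrum(np.full(W.size, 5.0)) for _ in range(4)]
        gs = group_statistics(spectra, "BN")
        np.testing.assert_allclose(gs.ci_half_width, 0.0, atol=1e-12)

    def test_closed_form_ci(self):
        n, sd = 100, 3.0
        gs = group_statistics(self._noise_spectra(n, sd, seed=1), "BN")
        expected = student_t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        assert gs.ci_half_width.mean() == pytest.approx(expected, rel=0.10)

    def test_mean_of_two(self):
        a = make_spectrum(np.full(W.size, 2.0))
        b = make_spectrum(np.full(W.size, 6.0))
        gs = group_statistics([a, b], "MM")
        np.testing.assert_allclose(gs.mean, 4.0)

    def test_single_spectrum_raises(self):
        with pytest.raises(ValueError):
            group_statistics(self._noise_spectra(1), "BN")

    def test_twenty_ci_points(self):
        gs = group_statistics(self._noise_spectra(3), "BN")
        assert gs.ci_points.size == 20
        assert gs.ci_points[0] == 0 and gs.ci_points[-1] == W.size - 1

    def test_regrid_applied_for_mismatched_axes(self):
        a = make_spectrum(np.full(W.size, 2.0))
        w2 = np.arange(700.0, 1901.0, 0.5)
        b = RamanSpectrum(w2, np.full(w2.size, 6.0))
        gs = group_statistics([a, b], "BN")
        np.testing.assert_allclose(gs.mean, 4.0)


class TestDifferenceSpectrum:
    def _groups(self, seed=0):
        rng = np.random.default_rng(seed)
        ga = group_statistics(
            [make_spectrum(10 + rng.normal(0, 1, W.size)) for _ in range(5)], "BN"
        )
        gb = group_statistics(
            [make_spectrum(8 + rng.normal(0, 2, W.size)) for _ in range(7)], "MM"
        )
        return ga, gb

    def test_self_difference_zero(self):
        ga, _ = self._groups()
        diff, _ = difference_spectrum(ga, ga)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_antisymmetry(self):
        ga, gb = self._groups(1)
        d1, h1 = difference_spectrum(ga, gb)
        d2, h2 = difference_spectrum(gb, ga)
        np.testing.assert_allclose(d1, -d2, atol=1e-12)
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    def test_welch_oracle(self):
        ga, gb = self._groups(2)
        diff, hw = difference_spectrum(ga, gb)
        # independent per-channel Welch computation on the raw matrices
        for j in (0, 100, 777, W.size - 1):
            xa, xb = ga.matrix[:, j], gb.matrix[:, j]
            na, nb = xa.size, xb.size
            va, vb = xa.var(ddof=1), xb.var(ddof=1)
            se2 = va / na + vb / nb
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            expected = student_t.ppf(0.975, df) * np.sqrt(se2)
            assert diff[j] == pytest.approx(xa.mean() - xb.mean(), abs=1e-12)
            assert hw[j] == pytest.approx(expected, abs=1e-12)

    def test_axis_mismatch(self):
        ga, _ = self._groups()
        other = group_statistics(
            [
                RamanSpectrum(np.arange(100.0), np.ones(100)),
                RamanSpectrum(np.arange(100.0), np.ones(100)),
            ],
            "MM",
        )
        with pytest.raises(ValueError):
            difference_spectrum(ga, other)


class TestPipelineOrder:
    def test_band_heights_recovered_through_full_chain(self):
        # noiseless bands + background through despike/smooth/normalize/arPLS
        cfg = ak.default_raman_config("BN", seed=0, noise_sd=0.0, cosmic_ray_rate=0.0)
        sp, truth = ak.generate_raman_spectrum(cfg, "BN")
        out = remove_cosmic_rays(sp, 8.0)
        out = smooth(out, 11, 3)
        out = normalize_fingerprint(out)
        _, out = arpls_baseline(out)
        centers = cfg.band_centers
        recovered = []
        for c in centers:
            i = np.argmin(np.abs(out.wavenumbers - c))
            recovered.append(out.intensities[i])
        true_amps = np.asarray(cfg.band_amplitudes)
        corr = np.corrcoef(recovered, true_amps)[0, 1]
        assert corr > 0.99

    def test_group_contrast_sign_after_processing(self):
        def processed_mean(group, seeds):
            spectra = []
            for s in seeds:
                cfg = ak.default_raman_config(group, seed=s)
                sp, _ = ak.generate_raman_spectrum(cfg, group)
                sp = remove_cosmic_rays(sp, 8.0)
                sp = smooth(sp, 11, 3)
                sp = normalize_fingerprint(sp)
                _, sp = arpls_baseline(sp)
                spectra.append(sp)
            return group_statistics(spectra, group)

        bn = processed_mean("BN", range(5))
        mm = processed_mean("MM", range(5))
        diff, _ = difference_spectrum(bn, mm)
        w = bn.wavenumbers
        for center in (1008.0, 1158.0, 1525.0):  # carotenoids: MM higher
            assert diff[np.argmin(np.abs(w - center))] < 0
        for center in (1450.0, 1655.0):  # CH2-CH3, amide-I: BN higher
            assert diff[np.argmin(np.abs(w - center))] > 0


class TestRegrid:
    def test_linear_interpolation(self):
        sp = RamanSpectrum(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 4.0]))
        out = regrid(sp, np.array([0.5, 1.5]))
        np.testing.assert_allclose(out.intensities, [1.0, 3.0])
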