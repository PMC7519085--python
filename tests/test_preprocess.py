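"""Apodization, block correction/summation, QC metrics and baseline removal."""

import numpy as np
import pytest

from phosfit import (
    AcquisitionParams,
    Lineshape,
    Resonance,
    SpinSystem,
    Spectrum,
    apodize,
    apodize_spectrum,
    correct_and_sum,
    estimate_baseline,
    estimate_linewidth,
    estimate_snr,
    fid_from_spectrum,
    make_block_series,
    simulate_basis,
    spectrum_from_fid,
    subtract_baseline,
    synthesize_spectrum,
)
from phosfit.errors import ParameterError
from phosfit.synth import ConcentrationProfile


def _singlet_spectrum(acq, ppm=0.0, fwhm=13.0, name="PCr"):
    b = simulate_basis(SpinSystem(name, (Resonance(ppm, 1.0),)), acq, Lineshape(fwhm))
    return Spectrum(b.values, b.axis, acq)


@pytest.fixture(scope="module")
def acq_ongrid():
    # transmitter on PCr puts the 0 ppm peak exactly on a grid point
    return AcquisitionParams(transmitter_offset=0.0)


class TestApodize:
    def test_zero_broadening_is_identity(self, acq):
        rng = np.random.default_rng(0)
        fid = rng.normal(size=64) + 1j * rng.normal(size=64)
        acq_small = AcquisitionParams(n_points=64)
        assert np.array_equal(apodize(fid, 0.0, acq_small), fid)

    def test_first_sample_unchanged(self, acq):
        fid = np.ones(acq.n_points, dtype=complex)
        out = apodize(fid, 25.0, acq)
        assert out[0] == fid[0]

    def test_negative_broadening_rejected(self, acq):
        with pytest.raises(ParameterError):
            apodize(np.ones(acq.n_points, dtype=complex), -1.0, acq)

    def test_lorentzian_broadening_adds_linewidths(self, acq):
        # 10 Hz line apodized by 10 Hz -> 20 Hz FWHM within 5%
        spec = _singlet_spectrum(acq, fwhm=10.0)
        out = apodize_spectrum(spec, 10.0)
        assert estimate_linewidth(out, 0.0) == pytest.approx(20.0, rel=0.05)

    def test_fid_spectrum_round_trip_exact(self, acq):
        spec = _singlet_spectrum(acq, fwhm=13.0)
        back = spectrum_from_fid(fid_from_spectrum(spec), acq)
        # frequency- and time-domain construction paths are exact inverses
        assert np.allclose(back.values, spec.values, rtol=0, atol=1e-12 * np.abs(spec.values).max())


class TestCorrectAndSum:
    def _series(self, acq, n, drift=0.0, phase=0.0, seed=1):
        profile = ConcentrationProfile({"PCr": 3.0})
        basis = [simulate_basis(SpinSystem("PCr", (Resonance(0.0, 1.0),)), acq, Lineshape(13.0))]
        return make_block_series(profile, basis, drift, phase, n, seed=seed)

    def test_n_identical_blocks_sum_exactly(self, acq_ongrid):
        series = self._series(acq_ongrid, 4)
        out = correct_and_sum(series)
        single = np.fft.fftshift(np.fft.fft(series.blocks[0]))
        assert np.allclose(out.values, 4 * single, rtol=1e-12)

    def test_opposed_phases_cancel_uncorrected_but_not_corrected(self, acq_ongrid):
        series = self._series(acq_ongrid, 2)
        series.blocks[1] = series.blocks[1] * np.exp(1j * np.pi)
        raw_sum = np.fft.fftshift(np.fft.fft(series.blocks[0] + series.blocks[1]))
        single = np.fft.fftshift(np.fft.fft(series.blocks[0]))
        assert np.abs(raw_sum).max() < 1e-9 * np.abs(single).max()
        corrected = correct_and_sum(series)
        assert corrected.real.max() == pytest.approx(2 * single.real.max(), rel=1e-6)

    def test_injected_offsets_recovered_within_one_bin(self, acq_ongrid):
        series = self._series(acq_ongrid, 8, drift=4.0, seed=5)
        out = correct_and_sum(series)
        applied = {c["block"]: c["freq_hz"] for c in out.meta["corrections"]}
        rel_truth = series.freq_offsets - series.freq_offsets[0]
        for i, true_off in enumerate(rel_truth):
            assert abs(applied[i] - true_off) < acq_ongrid.hz_per_point

    def test_single_clean_block_unchanged(self, acq_ongrid):
        series = self._series(acq_ongrid, 1)
        out = correct_and_sum(series)
        single = np.fft.fftshift(np.fft.fft(series.blocks[0]))
        assert np.allclose(out.values, single, rtol=1e-12)

    def test_undetectable_reference_block_excluded(self, acq_ongrid):
        series = self._series(acq_ongrid, 3, seed=2)
        series.blocks[1] = np.random.default_rng(0).normal(
            0, 1e-7, acq_ongrid.n_points
        ).astype(complex)
        with pytest.warns(UserWarning, match="excluded"):
            out = correct_and_sum(series)
        assert out.meta["blocks_excluded"] == [1]


class TestEstimateSnr:
    def test_scale_invariance(self, profile, basis14):
        spec = synthesize_spectrum(profile, basis14, target_snr=30, seed=3)
        doubled = Spectrum(spec.values * 2.0, spec.axis, spec.acq)
        assert estimate_snr(doubled) == pytest.approx(estimate_snr(spec), rel=1e-12)

    def test_single_replicate_within_20pct(self, profile, basis14):
        spec = synthesize_spectrum(profile, basis14, target_snr=30, seed=11)
        assert estimate_snr(spec) == pytest.approx(30.0, rel=0.20)

    def test_pure_noise_low_snr(self, acq):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=acq.n_points) + 1j * rng.normal(size=acq.n_points)
        assert estimate_snr(Spectrum(vals, acq.ppm_axis(), acq)) < 3.0

    def test_noiseless_reports_infinity_with_warning(self, acq):
        # spectrum with an exactly signal-free noise region
        vals = np.zeros(acq.n_points, dtype=complex)
        axis = acq.ppm_axis()
        vals[np.argmin(np.abs(axis - (-7.6)))] = 1.0
        spec = Spectrum(vals, axis, acq)
        with pytest.warns(UserWarning, match="noiseless"):
            assert estimate_snr(spec) == np.inf


class TestEstimateLinewidth:
    def test_recovers_simulated_13hz(self, acq):
        spec = _singlet_spectrum(acq, fwhm=13.0)
        assert estimate_linewidth(spec, 0.0) == pytest.approx(13.0, rel=0.05)

    def test_doubling_linewidth_doubles_estimate(self, acq):
        lw1 = estimate_linewidth(_singlet_spectrum(acq, fwhm=13.0), 0.0)
        lw2 = estimate_linewidth(_singlet_spectrum(acq, fwhm=26.0), 0.0)
        assert lw2 / lw1 == pytest.approx(2.0, rel=0.05)

    def test_never_below_grid_resolution(self, acq):
        spec = _singlet_spectrum(acq, fwhm=1.0)
        assert estimate_linewidth(spec, 0.0) >= acq.hz_per_point

    def test_missing_peak_rejected(self, acq):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=acq.n_points) + 1j * rng.normal(size=acq.n_points)
        with pytest.raises(ParameterError):
            estimate_linewidth(Spectrum(vals, acq.ppm_axis(), acq), 0.0)


class TestBaseline:
    def _cubic(self, acq, mask_window=(-15.5, -3.0)):
        axis = acq.ppm_axis()
        x = (axis - axis.mean()) / 10.0
        return 0.01 * (x**3 - 0.5 * x**2 + x + 2.0)

    def test_peak_free_smooth_curve_recovered(self, acq):
        curve = self._cubic(acq)
        spec = Spectrum(curve.astype(complex), acq.ppm_axis(), acq)
        est, mask = estimate_baseline(spec)
        err = np.abs(est - curve[mask]).max()
        assert err < 0.01 * np.ptp(curve[mask])

    def test_baseline_under_narrow_peaks(self, acq):
        curve = self._cubic(acq)
        axis = acq.ppm_axis()
        peaks = np.zeros_like(curve)
        for ppm in (-12.0, -9.5, -7.0):
            x_hz = np.asarray(acq.ppm_to_hz(axis)) - float(acq.ppm_to_hz(ppm))
            hw = 7.5  # 15 Hz FWHM
            peaks += 0.05 * hw**2 / (hw**2 + x_hz**2)
        spec = Spectrum((curve + peaks).astype(complex), axis, acq)
        est, mask = estimate_baseline(spec)
        err = np.abs(est - curve[mask]).max()
        assert err < 0.05 * np.ptp(curve[mask])

    def test_zero_input_zero_baseline(self, acq):
        spec = Spectrum(np.zeros(acq.n_points, dtype=complex), acq.ppm_axis(), acq)
        est, _ = estimate_baseline(spec)
        assert np.allclose(est, 0.0)

    def test_window_outside_axis_rejected(self, acq):
        spec = Spectrum(np.zeros(acq.n_points, dtype=complex), acq.ppm_axis(), acq)
        with pytest.raises(ParameterError):
            estimate_baseline(spec, window=(-60.0, -50.0))

    def test_subtraction_preserves_narrow_peak_heights(self, profile, basis14, acq):
        from phosfit import default_baseline

        clean = synthesize_spectrum(profile, basis14)
        withbl = synthesize_spectrum(profile, basis14, default_baseline())
        sub = subtract_baseline(withbl)
        mask = clean.window_mask(-8.1, -7.1)  # alpha-ATP
        h_clean = clean.real[mask].max()
        h_sub = sub.real[mask].max()
        assert h_sub == pytest.approx(h_clean, rel=0.05)
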