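"""Preprocessing operations: coil combination, alignment, HLSVD, ECC,
averaging, outlier rejection and elementary shape operations."""

import numpy as np
import pytest

from mrspec.core import MRSData, ParameterError, to_spectrum
from mrspec.preproc import (add, align_spectral_registration, apodize,
                            average_fids, coil_combine_wsvd, ecc_correct,
                            fshift, hlsvd_remove, phase_by_peak,
                            reject_outliers, subtract, truncate_pad, tshift)
from mrspec.quantify import fwhm_hz
from mrspec.synth import make_multicoil

DWELL = 1 / 2000.0
F0 = 123.2


def _svs(fid):
    return MRSData(fid, DWELL, F0)


def _lorentz_fid(T=1024, r=10.0, f=150.0, amp=1.0):
    t = np.arange(T) * DWELL
    return amp * np.exp((-r + 2j * np.pi * f) * t)


def _spectral_snr(data):
    spec = to_spectrum(data.signal[0, 0, 0, :, 0, 0])
    peak = np.abs(spec).max()
    noise = np.std(spec.real[:100])
    return peak / noise


class TestCoilCombination:
    def test_single_coil_passthrough(self):
        d = _svs(_lorentz_fid())
        out = coil_combine_wsvd(d)
        # unchanged up to a global phase
        ratio = out.signal[0, 0, 0, :, 0, 0] / d.signal[0, 0, 0, :, 0, 0]
        assert np.allclose(ratio, ratio[0], atol=1e-10)

    def test_combined_snr_near_matched_filter_optimum(self, rng):
        """8 coils with known sensitivities: combined SNR >= best coil and
        within 5% of the matched-filter bound sqrt(sum |c_k|^2) * SNR_1."""
        base = _svs(_lorentz_fid(amp=20.0))
        sens = (rng.standard_normal(8) + 1j * rng.standard_normal(8))
        sens /= np.abs(sens).max()
        data, noise = make_multicoil(base, sens, np.eye(8), seed=7,
                                     n_noise_samples=4096)
        combined = coil_combine_wsvd(data, noise)
        snr_c = _spectral_snr(combined)
        snrs_single = []
        for k in range(8):
            single = base.with_signal(
                data.signal[:, :, :, :, k:k + 1, :])
            snrs_single.append(_spectral_snr(single))
        # per-unit-sensitivity single-coil SNR estimated from each coil
        snr1 = np.median([s / np.abs(c) for s, c in zip(snrs_single, sens)])
        optimum = np.sqrt(np.sum(np.abs(sens) ** 2)) * snr1
        assert snr_c >= max(snrs_single)
        assert snr_c >= 0.95 * optimum

    def test_two_equal_coils_gain_sqrt2(self, rng):
        base = _svs(_lorentz_fid(amp=10.0))
        data, noise = make_multicoil(base, [1.0, 1.0], np.eye(2), seed=3,
                                     n_noise_samples=4096)
        combined = coil_combine_wsvd(data, noise)
        single = base.with_signal(data.signal[:, :, :, :, :1, :])
        gain = _spectral_snr(combined) / _spectral_snr(single)
        assert np.isclose(gain, np.sqrt(2), rtol=0.10)


class TestSpectralRegistration:
    def test_recovers_injected_shifts(self):
        fid = _lorentz_fid(amp=5.0)
        t = np.arange(len(fid)) * DWELL
        shifts = [0.0, 5.0, -3.0]
        phases = [0.0, np.deg2rad(30), np.deg2rad(-60)]
        fids = np.stack([fid * np.exp(1j * (2 * np.pi * f * t + p))
                         for f, p in zip(shifts, phases)], axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        res = align_spectral_registration(d, target="first")
        rel_f = res.frequency_shifts - res.frequency_shifts[0]
        rel_p = res.phase_shifts - res.phase_shifts[0]
        assert np.allclose(rel_f, [-s for s in shifts], atol=0.1)
        assert np.allclose(np.angle(np.exp(1j * (rel_p + phases))), 0,
                           atol=np.deg2rad(1))

    def test_identical_fids_zero_shifts(self):
        fid = _lorentz_fid()
        fids = np.repeat(fid[:, np.newaxis], 4, axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        res = align_spectral_registration(d)
        assert np.allclose(res.frequency_shifts, 0, atol=1e-3)
        assert np.allclose(res.phase_shifts, 0, atol=1e-3)

    def test_reported_shifts_reproduce_alignment(self):
        fid = _lorentz_fid(amp=2.0)
        t = np.arange(len(fid)) * DWELL
        fids = np.stack([fid, fid * np.exp(1j * (2 * np.pi * 4.0 * t + 0.3))],
                        axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        res = align_spectral_registration(d)
        for k in range(2):
            manual = fids[:, k] * np.exp(
                1j * (2 * np.pi * res.frequency_shifts[k] * t
                      + res.phase_shifts[k]))
            assert np.allclose(manual, res.aligned.signal[0, 0, 0, :, 0, k],
                               atol=1e-10)

    def test_align_diff_identical_conditions_zero_shift(self):
        from mrspec.preproc import align_diff
        d = _svs(_lorentz_fid(amp=4.0))
        df, dp, aligned = align_diff(d, d, mode="add")
        assert abs(df) < 0.05
        assert abs(np.angle(np.exp(1j * dp))) < 0.01
        assert np.allclose(aligned.signal, d.signal, rtol=1e-3, atol=1e-6)

    def test_align_diff_recovers_injected_offset(self):
        from mrspec.preproc import align_diff
        fid = _lorentz_fid(amp=4.0)
        a = _svs(fid)
        t = np.arange(len(fid)) * DWELL
        b = _svs(fid * np.exp(1j * (2 * np.pi * 6.0 * t + 0.4)))
        df, dp, aligned = align_diff(a, b, mode="add")
        assert np.isclose(df, -6.0, atol=0.1)
        assert abs(np.angle(np.exp(1j * (dp + 0.4)))) < np.deg2rad(2)

    def test_empty_window_warns_and_zeroes(self):
        fid = _lorentz_fid()
        fids = np.repeat(fid[:, np.newaxis], 2, axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        with pytest.warns(UserWarning):
            res = align_spectral_registration(d, ppm_window=(-20.0, -19.0))
        assert np.all(res.frequency_shifts == 0)


class TestHLSVD:
    def test_single_component_removed(self):
        t = np.arange(1024) * DWELL
        water = 10 * np.exp((-15 + 2j * np.pi * 0.0) * t)  # at 4.65 ppm
        d = _svs(water)
        out = hlsvd_remove(d, (4.4, 4.9), n_singular=10)
        resid = out.signal[0, 0, 0, :, 0, 0]
        assert np.sum(np.abs(resid) ** 2) < 0.01 * np.sum(np.abs(water) ** 2)

    def test_metabolite_preserved(self):
        t = np.arange(1024) * DWELL
        f_naa = (4.65 - 2.01) * F0
        water = 50 * np.exp((-15 + 2j * np.pi * 0.0) * t)
        naa = 3 * np.exp((-12 + 2j * np.pi * f_naa) * t)
        d = _svs(water + naa)
        out = hlsvd_remove(d, (4.4, 4.9), n_singular=12)
        resid = out.signal[0, 0, 0, :, 0, 0]
        # remaining signal should match the metabolite within 1% amplitude
        err = np.abs(to_spectrum(resid) - to_spectrum(naa)).max()
        assert err < 0.01 * np.abs(to_spectrum(naa)).max()

    def test_zero_fid_identity(self):
        d = _svs(np.zeros(512, complex))
        out = hlsvd_remove(d, (4.4, 4.9))
        assert np.all(out.signal == 0)

    def test_empty_band_identity(self):
        d = _svs(_lorentz_fid())
        out = hlsvd_remove(d, (4.65, 4.65))
        assert np.array_equal(out.signal, d.signal)

    def test_n_singular_too_large(self):
        d = _svs(_lorentz_fid(T=64))
        with pytest.raises(ParameterError):
            hlsvd_remove(d, (4.4, 4.9), n_singular=40)


class TestECC:
    def test_self_correction_zero_phase(self):
        d = _svs(_lorentz_fid() * np.exp(1j * 0.7))
        out = ecc_correct(d, d)
        phases = np.angle(out.signal[0, 0, 0, :, 0, 0])
        assert np.allclose(phases, 0, atol=1e-12)

    def test_common_phase_removed(self, rng):
        t = np.arange(512) * DWELL
        theta = 0.8 * np.sin(2 * np.pi * 3 * t)  # eddy-current-like phase
        s = _lorentz_fid(T=512, r=8.0, f=100.0)
        data = _svs(s * np.exp(1j * theta))
        ref = _svs(np.exp(-5 * t) * np.exp(1j * theta))
        out = ecc_correct(data, ref)
        assert np.allclose(out.signal[0, 0, 0, :, 0, 0], s, atol=1e-10)
        # magnitude unchanged pointwise
        assert np.allclose(np.abs(out.signal), np.abs(data.signal))

    def test_zero_phase_reference_is_identity(self):
        t = np.arange(256) * DWELL
        data = _svs(_lorentz_fid(T=256))
        ref = _svs(np.exp(-3 * t) + 0j)
        out = ecc_correct(data, ref)
        assert np.allclose(out.signal, data.signal, atol=1e-12)


class TestAveraging:
    def test_identical_fids_mean(self):
        fid = _lorentz_fid()
        fids = np.repeat(fid[:, np.newaxis], 5, axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        out = average_fids(d)
        assert out.n_averages == 1
        assert np.allclose(out.signal[0, 0, 0, :, 0, 0], fid)

    def test_sqrtn_snr_gain(self, rng):
        fid = _lorentz_fid(amp=5.0)
        n = 100
        noise = (rng.standard_normal((len(fid), n))
                 + 1j * rng.standard_normal((len(fid), n)))
        fids = fid[:, np.newaxis] + 0.5 * noise
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        single = d.with_signal(d.signal[:, :, :, :, :, :1])
        gain = _spectral_snr(average_fids(d)) / _spectral_snr(single)
        assert np.isclose(gain, 10.0, rtol=0.2)

    def test_plus_minus_weights_half_difference(self):
        f1, f2 = _lorentz_fid(), _lorentz_fid(f=-100.0)
        fids = np.stack([f1, f2], axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        out = average_fids(d, weights=[1.0, -1.0])
        assert np.allclose(out.signal[0, 0, 0, :, 0, 0], (f1 - f2) / 2)

    def test_weight_length_mismatch(self):
        d = MRSData(np.zeros((1, 1, 1, 64, 1, 3), complex), DWELL, F0)
        with pytest.raises(ParameterError):
            average_fids(d, weights=[1.0, 1.0])


class TestOutlierRejection:
    def test_artifact_fid_dropped(self):
        fid = _lorentz_fid(amp=3.0)
        fids = np.repeat(fid[:, np.newaxis], 16, axis=1).copy()
        t = np.arange(len(fid)) * DWELL
        fids[:, 7] += 50 * np.exp((-30 + 2j * np.pi * 400) * t)  # artifact
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        out, kept = reject_outliers(d, sd_limit=3.0)
        assert not kept[7]
        assert kept.sum() == 15

    def test_identical_kept(self):
        fid = _lorentz_fid()
        fids = np.repeat(fid[:, np.newaxis], 6, axis=1)
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        _, kept = reject_outliers(d)
        assert kept.all()

    def test_infinite_limit_keeps_all(self, rng):
        fids = (rng.standard_normal((256, 5))
                + 1j * rng.standard_normal((256, 5)))
        d = MRSData(fids[np.newaxis, np.newaxis, np.newaxis, :,
                         np.newaxis, :], DWELL, F0)
        _, kept = reject_outliers(d, sd_limit=np.inf)
        assert kept.all()


class TestShapeOps:
    def test_exponential_apodization_adds_width(self):
        """5 Hz exponential on a 5 Hz FWHM Lorentzian gives 10 Hz FWHM."""
        r = 5.0 * np.pi  # FWHM = r/pi = 5 Hz
        d = _svs(_lorentz_fid(T=4096, r=r, f=200.0))
        out = apodize(d, "exponential", 5.0)
        ax = out.axes()
        width = fwhm_hz(to_spectrum(out.signal[0, 0, 0, :, 0, 0]).real, ax.hz)
        assert np.isclose(width, 10.0, atol=0.2)

    def test_fshift_round_trip_identity(self):
        d = _svs(_lorentz_fid())
        out = fshift(fshift(d, 37.5), -37.5)
        assert np.allclose(out.signal, d.signal, atol=1e-12)

    def test_fshift_moves_peak(self):
        d = _svs(_lorentz_fid(f=100.0))
        ax = d.axes()
        df = ax.hz[1] - ax.hz[0]
        shifted = fshift(d, 10 * df)
        p0 = ax.hz[np.argmax(np.abs(to_spectrum(d.signal[0, 0, 0, :, 0, 0])))]
        p1 = ax.hz[np.argmax(np.abs(to_spectrum(
            shifted.signal[0, 0, 0, :, 0, 0])))]
        assert np.isclose(p1 - p0, 10 * df, atol=df / 2)

    def test_subtract_self_zero(self):
        d = _svs(_lorentz_fid())
        assert np.all(subtract(d, d).signal == 0)
        assert np.allclose(add(d, d).signal, 2 * d.signal)

    def test_phase_by_peak_applied_angle(self):
        d = phase_by_peak(_svs(_lorentz_fid(f=200.0)), (2.0, 4.0))
        rotated = d.with_signal(d.signal * np.exp(1j * np.pi / 3))
        out, applied = phase_by_peak(rotated, (2.0, 4.0), return_phase=True)
        assert np.isclose(applied, -np.pi / 3, atol=0.01)
        spec = to_spectrum(out.signal[0, 0, 0, :, 0, 0])
        peak = spec[np.argmax(np.abs(spec))]
        assert abs(np.angle(peak)) < 0.01

    def test_truncate_pad(self):
        d = _svs(_lorentz_fid(T=256))
        assert truncate_pad(d, 128).n_timepoints == 128
        padded = truncate_pad(d, 512)
        assert padded.n_timepoints == 512
        assert np.all(padded.signal[0, 0, 0, 256:, 0, 0] == 0)
        with pytest.raises(ParameterError):
            truncate_pad(d, 1)

    def test_tshift_integer_sample_shift(self):
        d = _svs(_lorentz_fid())
        out = tshift(d, DWELL)  # delay by one sample (periodic)
        assert np.allclose(out.signal[0, 0, 0, 1:, 0, 0],
                           d.signal[0, 0, 0, :-1, 0, 0], atol=1e-9)
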