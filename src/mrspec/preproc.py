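"""Preprocessing of raw multi-coil, multi-average FIDs.

Implements the standard toolbox of operations that take raw data to a single
fit-ready spectrum: whitened-SVD coil combination, spectral-registration
frequency/phase alignment, HLSVD nuisance-peak removal, eddy-current
correction, weighted averaging, outlier rejection and elementary shape
operations (apodisation, truncation, shifting, phasing, add/subtract).

Every operation is shape-preserving or reduces exactly one declared
dimension, and propagates metadata unchanged except for fields it
legitimately alters (documented per function).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import (FrequencyAxis, MRSData, NumericalError, ParameterError,
                   to_fid, to_spectrum)

__all__ = [
    "coil_combine_wsvd", "align_spectral_registration", "AlignmentResult",
    "align_diff",
    "hlsvd_remove", "hlsvd_components", "HLSVDComponent", "ecc_correct",
    "average_fids", "reject_outliers", "apodize", "truncate_pad", "tshift",
    "fshift", "phase_by_peak", "add", "subtract",
]


# ---------------------------------------------------------------------------
# Coil combination (whitened SVD)
# ---------------------------------------------------------------------------

def coil_combine_wsvd(data: MRSData, noise: np.ndarray | None = None,
                      reference: MRSData | None = None) -> MRSData:
    """Combine receiver coils by the whitened-SVD algorithm.

    The coil noise covariance is estimated from ``noise`` (``[coil, samples]``,
    signal-free), data are whitened by its inverse Cholesky factor, and the
    rank-1 SVD of the whitened coil x time matrix gives the combination
    weights.  Weights are derived from ``reference`` when given (e.g. an
    unsuppressed water scan), otherwise from the data themselves (averaged
    over the average dimension).  The combined FID is phased so its first
    time point is real and non-negative.  Reduces the coil dimension to 1.
    """
    nc = data.n_coils
    if nc == 1:
        return _phase_first_point(data)
    if noise is None:
        raise ParameterError("noise samples are required for whitened combination")
    noise = np.asarray(noise)
    if noise.shape[0] != nc:
        raise ParameterError("noise must have shape [coil, samples]")
    if noise.shape[1] < 2 * nc:
        raise ParameterError("need at least 2 x n_coils noise samples per coil")
    cov = noise @ noise.conj().T / (noise.shape[1] - 1)
    try:
        chol = scipy.linalg.cholesky(cov, lower=True)
        whiten = scipy.linalg.solve_triangular(chol, np.eye(nc), lower=True)
    except scipy.linalg.LinAlgError:
        raise NumericalError(
            "noise covariance is singular; provide more noise samples") from None

    src = reference if reference is not None else data
    out = np.empty(data.shape[:4] + (1,) + data.shape[5:], dtype=np.complex128)
    for ix, iy, iz in np.ndindex(data.spatial_shape):
        # weights from the average-summed (whitened) reference matrix
        ref_mat = src.signal[ix, iy, iz].mean(axis=2).T  # [coil, time]
        u, _, _ = np.linalg.svd(whiten @ ref_mat, full_matrices=False)
        w = u[:, 0]
        for ia in range(data.n_averages):
            mat = whiten @ data.signal[ix, iy, iz, :, :, ia].T
            fid = w.conj() @ mat
            out[ix, iy, iz, :, 0, ia] = fid
    combined = data.with_signal(out)
    return _phase_first_point(combined)


def _phase_first_point(data: MRSData) -> MRSData:
    """Apply a global phase so the first time point of each FID is real >= 0."""
    sig = data.signal.copy()
    first = sig[:, :, :, :1, :, :][:, :, :, 0, :, :]
    phase = np.exp(-1j * np.angle(np.where(first == 0, 1.0, first)))
    sig = sig * phase[:, :, :, np.newaxis, :, :]
    return data.with_signal(sig)


# ---------------------------------------------------------------------------
# Spectral registration
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Per-average frequency/phase shifts and the aligned data.

    Applying ``fid * exp(1j*(2*pi*frequency_shifts[k]*t + phase_shifts[k]))``
    to input average ``k`` reproduces ``aligned``.
    """

    frequency_shifts: np.ndarray  # Hz per average
    phase_shifts: np.ndarray      # rad per average
    aligned: MRSData


def _window_filter(fids: np.ndarray, axis: FrequencyAxis,
                   ppm_window) -> np.ndarray:
    """Restrict FIDs (last axis = time) to a ppm window via spectral masking."""
    if ppm_window is None:
        return fids
    mask = axis.ppm_mask(*ppm_window)
    spec = to_spectrum(fids)
    return to_fid(spec * mask)


def align_spectral_registration(data: MRSData, ppm_window=None,
                                target: str = "mean",
                                iterations: int = 2,
                                tol: float = 1e-4) -> AlignmentResult:
    """Phase/frequency-align the averages by time-domain spectral registration.

    Each FID k is corrected by ``exp(1j*(2*pi*df*t + dphi))`` with ``(df,
    dphi)`` found by least squares against the target FID (the mean of all
    averages by default, or the first), with the comparison restricted to
    ``ppm_window`` by spectral filtering.  The target is recomputed and the
    fit repeated ``iterations`` times.
    """
    if data.n_averages < 2:
        raise ParameterError("alignment requires at least 2 averages")
    if data.n_coils != 1 or not data.is_svs:
        raise ParameterError("combine coils / single voxel before alignment")
    axis = data.axes()
    t = data.time_axis
    fids = data.signal[0, 0, 0, :, 0, :].T.copy()  # [average, time]
    filt = _window_filter(fids, axis, ppm_window)
    if ppm_window is not None and np.max(np.abs(filt)) < 1e-12 * max(
            np.max(np.abs(fids)), 1e-300):
        warnings.warn("ppm window excludes all signal energy; shifts set to 0")
        return AlignmentResult(np.zeros(len(fids)), np.zeros(len(fids)),
                               data.copy())

    import scipy.optimize

    n_avg = fids.shape[0]
    total_f = np.zeros(n_avg)
    total_p = np.zeros(n_avg)
    current = fids.copy()
    for _ in range(max(1, iterations)):
        filt_cur = _window_filter(current, axis, ppm_window)
        tgt = filt_cur.mean(axis=0) if target == "mean" else filt_cur[0]
        moved = 0.0
        for k in range(n_avg):
            fk = filt_cur[k]

            # coarse init: the cross-term fk*conj(tgt) peaks at -df
            g = to_spectrum(fk * np.conj(tgt))
            hz = np.fft.fftshift(np.fft.fftfreq(len(t), d=data.dwell_time))
            i0 = int(np.argmax(np.abs(g)))
            x0 = [-hz[i0], -float(np.angle(g[i0]))]

            def resid(x, fk=fk):
                corr = fk * np.exp(1j * (2 * np.pi * x[0] * t + x[1]))
                d = corr - tgt
                return np.concatenate([d.real, d.imag])

            sol = scipy.optimize.least_squares(resid, x0=x0,
                                               method="lm", xtol=1e-12)
            df, dp = sol.x
            moved = max(moved, abs(df), abs(dp))
            total_f[k] += df
            total_p[k] += dp
            current[k] = fids[k] * np.exp(
                1j * (2 * np.pi * total_f[k] * t + total_p[k]))
        if moved < tol:
            break
    out = data.signal.copy()
    out[0, 0, 0, :, 0, :] = current.T
    return AlignmentResult(total_f, total_p, data.with_signal(out))


def align_diff(data_a: MRSData, data_b: MRSData, mode: str = "add",
               ppm_window=None):
    """Align subspectra condition B to condition A (e.g. ISIS/editing pairs).

    Finds the (frequency, phase) correction of B that maximises the energy
    of the chosen combination (``add`` or ``subtract``) of the two spectra
    inside ``ppm_window``.  Returns ``(df_hz, dphi_rad, aligned_b)``.
    """
    if data_a.n_timepoints != data_b.n_timepoints:
        raise ParameterError("subspectra must share a time axis")
    if mode not in ("add", "subtract"):
        raise ParameterError(f"unknown combination mode {mode!r}")
    sign = 1.0 if mode == "add" else -1.0
    axis = data_a.axes()
    t = data_a.time_axis
    fa = _window_filter(data_a.signal[0, 0, 0, :, 0, 0], axis, ppm_window)
    fb = _window_filter(data_b.signal[0, 0, 0, :, 0, 0], axis, ppm_window)

    # maximising |fa + s*fb*e^{i..}|^2 is least-squares matching s*fb to fa
    import scipy.optimize

    g = to_spectrum(sign * fb * np.conj(fa))
    hz = np.fft.fftshift(np.fft.fftfreq(len(t), d=data_a.dwell_time))
    i0 = int(np.argmax(np.abs(g)))
    x0 = [-hz[i0], -float(np.angle(g[i0]))]

    def neg_energy(x):
        corr = sign * fb * np.exp(1j * (2 * np.pi * x[0] * t + x[1]))
        return -float(np.sum(np.abs(fa + corr) ** 2))

    sol = scipy.optimize.minimize(neg_energy, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-12})
    df, dp = sol.x
    ramp = np.exp(1j * (2 * np.pi * df * t + dp))
    shaped = ramp[np.newaxis, np.newaxis, np.newaxis, :,
                  np.newaxis, np.newaxis]
    return float(df), float(dp), data_b.with_signal(data_b.signal * shaped)


# ---------------------------------------------------------------------------
# HLSVD nuisance-peak removal
# ---------------------------------------------------------------------------

@dataclass
class HLSVDComponent:
    """One decaying complex exponential fitted to a FID.

    ``fid(t) = amplitude * exp(1j*phase) * exp((-damping + 2j*pi*frequency)*t)``
    with ``damping >= 0`` for physically decaying components.
    """

    frequency: float  # Hz
    damping: float    # 1/s
    amplitude: float
    phase: float      # rad

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (self.amplitude * np.exp(1j * self.phase)
                * np.exp((-self.damping + 2j * np.pi * self.frequency) * t))


def hlsvd_components(fid: np.ndarray, dwell_time: float,
                     n_singular: int = 20) -> list[HLSVDComponent]:
    """Model a FID as decaying complex exponentials via Hankel-matrix SVD.

    Uses the state-space (HSVD/HLSVD) method: SVD of the L x (T-L+1) Hankel
    matrix (L = T//2), a shift-invariance solve on the rank-``n_singular``
    signal subspace for the poles, and linear least squares for the complex
    amplitudes.
    """
    fid = np.asarray(fid, dtype=np.complex128)
    T = len(fid)
    L = T // 2
    if n_singular >= min(L, T - L + 1):
        raise ParameterError(
            f"n_singular={n_singular} too large for {T}-point FID")
    hankel = scipy.linalg.hankel(fid[:L], fid[L - 1:])
    u, s, _ = scipy.linalg.svd(hankel, full_matrices=False)
    uk = u[:, :n_singular]
    # shift invariance: Uk_down = Uk_up @ A, eigenvalues of A are the poles
    a = np.linalg.lstsq(uk[:-1], uk[1:], rcond=None)[0]
    poles = np.linalg.eigvals(a)
    poles = poles[np.abs(poles) > 1e-12]
    t = np.arange(T) * dwell_time
    basis = np.power(poles[np.newaxis, :],
                     np.arange(T)[:, np.newaxis].astype(float))
    amps = np.linalg.lstsq(basis, fid, rcond=None)[0]
    comps = []
    for z, c in zip(poles, amps):
        freq = np.angle(z) / (2 * np.pi * dwell_time)
        damping = -np.log(np.abs(z)) / dwell_time
        comps.append(HLSVDComponent(frequency=float(freq),
                                    damping=float(damping),
                                    amplitude=float(np.abs(c)),
                                    phase=float(np.angle(c))))
    return comps


def hlsvd_remove(data: MRSData, ppm_band, n_components: int | None = None,
                 n_singular: int = 20) -> MRSData:
    """Remove peaks (typically residual water) inside ``ppm_band`` via HLSVD.

    All fitted components whose frequency falls inside the ppm band are
    subtracted from the FID (or the ``n_components`` largest-amplitude ones
    if given).  An empty band is the identity.
    """
    if data.n_coils != 1 or data.n_averages != 1 or not data.is_svs:
        raise ParameterError("hlsvd_remove operates on a single FID")
    fid = data.signal[0, 0, 0, :, 0, 0]
    if not np.any(np.abs(fid) > 0):
        return data.copy()
    lo, hi = min(ppm_band), max(ppm_band)
    if lo == hi:
        return data.copy()
    comps = hlsvd_components(fid, data.dwell_time, n_singular=n_singular)
    f0, ref = data.spectrometer_frequency, data.ppm_reference
    in_band = [c for c in comps
               if lo <= (ref - c.frequency / f0) <= hi]
    in_band.sort(key=lambda c: -c.amplitude)
    if n_components is not None:
        in_band = in_band[:n_components]
    t = data.time_axis
    nuisance = np.zeros_like(fid)
    for c in in_band:
        nuisance += c.evaluate(t)
    out = data.signal.copy()
    out[0, 0, 0, :, 0, 0] = fid - nuisance
    return data.with_signal(out)


# ---------------------------------------------------------------------------
# Eddy-current correction (Klose)
# ---------------------------------------------------------------------------

def ecc_correct(data: MRSData, water_reference: MRSData) -> MRSData:
    """Eddy-current correction: remove the water reference's time-varying phase.

    ``corrected(t) = data(t) * exp(-1j * arg(water_reference(t)))`` -- the
    pointwise magnitude of the data is unchanged.  Samples where the
    reference is exactly zero get an interpolated phase (with a warning).
    """
    if data.n_timepoints != water_reference.n_timepoints:
        raise ParameterError("data and water reference must share a time axis")
    wref = water_reference.signal[0, 0, 0, :, 0, 0]
    nz = np.abs(wref) > 0
    if not nz.all():
        warnings.warn("water reference contains zero samples; "
                      "interpolating their phase")
        if not nz.any():
            return data.copy()
        idx = np.arange(len(wref))
        theta = np.interp(idx, idx[nz], np.unwrap(np.angle(wref[nz])))
    else:
        theta = np.angle(wref)
    corr = np.exp(-1j * theta)
    shaped = corr[np.newaxis, np.newaxis, np.newaxis, :, np.newaxis, np.newaxis]
    return data.with_signal(data.signal * shaped)


# ---------------------------------------------------------------------------
# Averaging and outlier rejection
# ---------------------------------------------------------------------------

def average_fids(data: MRSData, weights=None) -> MRSData:
    """Weighted mean over the average dimension (default uniform 1/N)."""
    n = data.n_averages
    if weights is None:
        weights = np.full(n, 1.0 / n, dtype=np.complex128)
    else:
        weights = np.asarray(weights, dtype=np.complex128)
        if weights.shape != (n,):
            raise ParameterError(
                f"weights length {weights.shape} does not match {n} averages")
        weights = weights / n
    out = np.tensordot(data.signal, weights, axes=([5], [0]))[..., np.newaxis]
    return data.with_signal(out)


def reject_outliers(data: MRSData, ppm_window=None, sd_limit: float = 3.0):
    """Drop dissimilar averages ("unlike" operation).

    The per-FID similarity score is the RMS deviation of its windowed real
    spectrum from the leave-one-out mean; FIDs whose score exceeds
    ``mean(scores) + sd_limit * SD(scores)`` are dropped, and the screen is
    iterated once more on the survivors.  Returns ``(reduced data,
    kept_mask)``.
    """
    if data.n_averages < 3:
        raise ParameterError("outlier rejection requires at least 3 averages")
    if data.n_coils != 1 or not data.is_svs:
        raise ParameterError("combine coils / single voxel before outlier rejection")
    axis = data.axes()
    mask_w = axis.ppm_mask(*ppm_window) if ppm_window is not None else slice(None)
    spectra = to_spectrum(data.signal[0, 0, 0, :, 0, :].T).real[:, mask_w]
    n = spectra.shape[0]
    kept = np.ones(n, dtype=bool)
    for _ in range(2):  # initial pass + one iteration
        idx = np.flatnonzero(kept)
        if len(idx) < 3:
            break
        sub = spectra[idx]
        total = sub.sum(axis=0)
        scores = np.array([
            np.sqrt(np.mean((sub[i] - (total - sub[i]) / (len(idx) - 1)) ** 2))
            for i in range(len(idx))])
        sd = scores.std()
        if not np.isfinite(sd_limit) or sd == 0:
            break
        bad = scores > scores.mean() + sd_limit * sd
        if not bad.any():
            break
        kept[idx[bad]] = False
    if not kept.any():
        raise ParameterError("all averages rejected; increase sd_limit")
    out = data.signal[:, :, :, :, :, kept]
    return data.with_signal(out), kept


# ---------------------------------------------------------------------------
# Elementary shape operations
# ---------------------------------------------------------------------------

def _broadcast_time(fn_of_t: np.ndarray) -> np.ndarray:
    return fn_of_t[np.newaxis, np.newaxis, np.newaxis, :, np.newaxis, np.newaxis]


def apodize(data: MRSData, kind: str = "exponential", amount=5.0) -> MRSData:
    """Apodise the FID.

    ``exponential``: multiply by ``exp(-pi * lb * t)`` with ``amount`` = lb in
    Hz (adds ``lb`` Hz of Lorentzian FWHM).  ``lorentz_to_gauss``: ``amount =
    (lb_hz, sigma_s)`` multiplies by ``exp(+pi*lb*t - sigma^2 t^2)``.
    """
    t = data.time_axis
    if kind == "exponential":
        env = np.exp(-np.pi * float(amount) * t)
    elif kind == "lorentz_to_gauss":
        lb, sig = amount
        env = np.exp(np.pi * lb * t - (sig * t) ** 2)
    else:
        raise ParameterError(f"unknown apodization kind {kind!r}")
    return data.with_signal(data.signal * _broadcast_time(env))


def truncate_pad(data: MRSData, n_points: int, side: str = "last") -> MRSData:
    """Truncate or zero-pad the time axis to ``n_points`` (on ``side``)."""
    if n_points < 2:
        raise ParameterError("cannot truncate below 2 time points")
    T = data.n_timepoints
    sig = data.signal
    if n_points == T:
        return data.copy()
    if n_points < T:
        sl = slice(0, n_points) if side == "last" else slice(T - n_points, T)
        out = sig[:, :, :, sl]
    else:
        pad = np.zeros(sig.shape[:3] + (n_points - T,) + sig.shape[4:],
                       dtype=sig.dtype)
        parts = (sig, pad) if side == "last" else (pad, sig)
        out = np.concatenate(parts, axis=3)
    return data.with_signal(out)


def tshift(data: MRSData, seconds: float) -> MRSData:
    """Shift the FID in time by ``seconds`` (Fourier-shift resampling).

    Positive values delay the signal: ``fid'(t) = fid(t - seconds)`` under
    the periodic Fourier interpolation of the sampled FID.
    """
    axis = data.axes()
    spec = to_spectrum(data.signal, axis=3)
    ramp = np.exp(-2j * np.pi * axis.hz * seconds)
    return data.with_signal(to_fid(spec * _broadcast_time(ramp), axis=3))


def fshift(data: MRSData, hz: float) -> MRSData:
    """Shift the spectrum by ``hz`` along the frequency axis (exact inverse
    of ``fshift(-hz)``)."""
    t = data.time_axis
    ramp = np.exp(2j * np.pi * hz * t)
    return data.with_signal(data.signal * _broadcast_time(ramp))


def phase_by_peak(data: MRSData, ppm_range, return_phase: bool = False):
    """Zero-order phase by the phase of the largest-magnitude point in range.

    After correction the spectral maximum in ``ppm_range`` is purely real
    and positive.
    """
    axis = data.axes()
    mask = axis.ppm_mask(*ppm_range)
    if not mask.any():
        raise ParameterError("ppm_range is outside the spectral axis")
    spec = to_spectrum(data.signal[0, 0, 0, :, 0, 0])
    sub = spec[mask]
    angle = np.angle(sub[np.argmax(np.abs(sub))])
    out = data.with_signal(data.signal * np.exp(-1j * angle))
    if return_phase:
        return out, -angle
    return out


def add(data: MRSData, other: MRSData) -> MRSData:
    if data.shape != other.shape:
        raise ParameterError("shapes differ")
    return data.with_signal(data.signal + other.signal)


def subtract(data: MRSData, other: MRSData) -> MRSData:
    if data.shape != other.shape:
        raise ParameterError("shapes differ")
    return data.with_signal(data.signal - other.signal)
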