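"""Core data containers and the package-wide spectral conventions.

Conventions fixed here and used by every other module:

* Canonical array layout is ``[x, y, z, time, coil, average]``; singleton
  dimensions are always kept so shapes are predictable.
* The forward transform (time -> frequency) is an orthonormal FFT followed by
  ``fftshift``, so Parseval's theorem holds exactly and frequency axes are
  ascending.
* The frequency axis in Hz spans ``[-1/(2*dwell), +1/(2*dwell))``; chemical
  shift is ``ppm = ppm_reference - hz / spectrometer_frequency``, i.e. ppm
  increases with decreasing frequency offset (standard 1H NMR convention).
  A resonance at shift ``d`` ppm therefore contributes
  ``exp(1j*2*pi*(ppm_reference - d)*f0*t)`` to the FID.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MRSData",
    "BasisSet",
    "FrequencyAxis",
    "MetadataError",
    "FormatError",
    "ParameterError",
    "NumericalError",
    "to_spectrum",
    "to_fid",
    "ppm_to_hz",
    "hz_to_ppm",
    "WATER_PPM",
]

#: Default receiver-centre chemical shift (water) in ppm.
WATER_PPM = 4.65


class MetadataError(KeyError):
    """A required metadata key is missing or invalid."""


class FormatError(ValueError):
    """A file does not parse under the declared dialect."""


class ParameterError(ValueError):
    """An operation was called with invalid parameters."""


class NumericalError(ArithmeticError):
    """A numerical step failed (singular matrix, non-unitary propagator...)."""


# ---------------------------------------------------------------------------
# FFT conventions
# ---------------------------------------------------------------------------

def to_spectrum(fid: np.ndarray, axis: int = -1) -> np.ndarray:
    """Time -> frequency transform (orthonormal FFT, fftshifted)."""
    return np.fft.fftshift(np.fft.fft(fid, axis=axis, norm="ortho"), axes=axis)


def to_fid(spectrum: np.ndarray, axis: int = -1) -> np.ndarray:
    """Frequency -> time transform, inverse of :func:`to_spectrum`."""
    return np.fft.ifft(np.fft.ifftshift(spectrum, axes=axis), axis=axis, norm="ortho")


def ppm_to_hz(ppm, spectrometer_frequency: float, ppm_reference: float = WATER_PPM):
    """Chemical shift (ppm) to frequency offset (Hz) from the receiver centre."""
    return (ppm_reference - np.asarray(ppm, dtype=float)) * spectrometer_frequency


def hz_to_ppm(hz, spectrometer_frequency: float, ppm_reference: float = WATER_PPM):
    """Frequency offset (Hz) to chemical shift (ppm)."""
    return ppm_reference - np.asarray(hz, dtype=float) / spectrometer_frequency


# ---------------------------------------------------------------------------
# Frequency axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyAxis:
    """Paired Hz / ppm axes for a spectrum of fixed length.

    ``hz`` is ascending (fftshifted); ``ppm`` is consequently descending.
    """

    hz: np.ndarray
    ppm: np.ndarray

    def __len__(self) -> int:
        return len(self.hz)

    @classmethod
    def from_params(cls, n_points: int, dwell_time: float,
                    spectrometer_frequency: float,
                    ppm_reference: float = WATER_PPM) -> "FrequencyAxis":
        if n_points < 2:
            raise ParameterError("need at least 2 time points for a frequency axis")
        hz = np.fft.fftshift(np.fft.fftfreq(n_points, d=dwell_time))
        ppm = hz_to_ppm(hz, spectrometer_frequency, ppm_reference)
        return cls(hz=hz, ppm=ppm)

    def ppm_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting points with ``lo <= ppm <= hi``."""
        lo, hi = min(lo, hi), max(lo, hi)
        return (self.ppm >= lo) & (self.ppm <= hi)


# ---------------------------------------------------------------------------
# MRSData
# ---------------------------------------------------------------------------

def _canonical_signal(signal: np.ndarray) -> np.ndarray:
    """Coerce an array to the canonical 6-d ``[x,y,z,t,coil,average]`` layout.

    1-d input is taken as a bare FID; 4-d as ``[x,y,z,t]``; 5-d as
    ``[x,y,z,t,coil]``.
    """
    sig = np.asarray(signal)
    if not np.iscomplexobj(sig):
        sig = sig.astype(np.complex128)
    if sig.ndim == 1:
        sig = sig[np.newaxis, np.newaxis, np.newaxis, :, np.newaxis, np.newaxis]
    elif sig.ndim == 4:
        sig = sig[..., np.newaxis, np.newaxis]
    elif sig.ndim == 5:
        sig = sig[..., np.newaxis]
    elif sig.ndim != 6:
        raise FormatError(
            f"signal must be 1-, 4-, 5- or 6-dimensional, got {sig.ndim} dims")
    return np.ascontiguousarray(sig.astype(np.complex128, copy=False))


@dataclass
class MRSData:
    """Complex time-domain MRS(I) data plus acquisition metadata.

    Parameters
    ----------
    signal:
        Complex array, canonicalised to ``[x, y, z, time, coil, average]``.
    dwell_time:
        Seconds per time-domain sample (> 0).
    spectrometer_frequency:
        Transmitter frequency in MHz (> 0).
    nucleus:
        Nucleus label, e.g. ``"1H"``.
    ppm_reference:
        Chemical shift assigned to zero frequency offset (receiver centre).
    affine:
        4x4 voxel-to-world transform; stored and propagated opaquely.
    extra:
        Unrecognised sidecar keys, preserved verbatim through I/O.
    """

    signal: np.ndarray
    dwell_time: float
    spectrometer_frequency: float
    nucleus: str = "1H"
    ppm_reference: float = WATER_PPM
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = _canonical_signal(self.signal)
        if not self.dwell_time > 0:
            raise MetadataError("dwell_time must be > 0")
        if not self.spectrometer_frequency > 0:
            raise MetadataError("spectrometer_frequency must be > 0")
        if self.n_timepoints < 2:
            raise FormatError("time axis must have at least 2 points")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise MetadataError("affine must be 4x4")

    # -- shape helpers ------------------------------------------------------
    @property
    def shape(self):
        return self.signal.shape

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[3]

    @property
    def n_coils(self) -> int:
        return self.signal.shape[4]

    @property
    def n_averages(self) -> int:
        return self.signal.shape[5]

    @property
    def spatial_shape(self):
        return self.signal.shape[:3]

    @property
    def is_svs(self) -> bool:
        return self.spatial_shape == (1, 1, 1)

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_timepoints) * self.dwell_time

    @property
    def bandwidth(self) -> float:
        return 1.0 / self.dwell_time

    @property
    def fid(self) -> np.ndarray:
        """The single FID of fully reduced SVS data ``[1,1,1,T,1,1]``."""
        if self.is_svs and self.n_coils == 1 and self.n_averages == 1:
            return self.signal[0, 0, 0, :, 0, 0]
        raise ParameterError(
            "data still has coil/average/spatial structure; reduce it first")

    @property
    def spectrum(self) -> np.ndarray:
        return to_spectrum(self.fid)

    def axes(self) -> FrequencyAxis:
        return FrequencyAxis.from_params(
            self.n_timepoints, self.dwell_time,
            self.spectrometer_frequency, self.ppm_reference)

    def with_signal(self, signal: np.ndarray) -> "MRSData":
        """Copy of this object holding ``signal`` (metadata unchanged)."""
        return replace(self, signal=signal, affine=self.affine.copy(),
                       extra=dict(self.extra))

    def copy(self) -> "MRSData":
        return self.with_signal(self.signal.copy())

    def allclose(self, other: "MRSData", rtol=1e-12, atol=0.0) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.signal, other.signal, rtol=rtol, atol=atol)
            and np.isclose(self.dwell_time, other.dwell_time, rtol=rtol)
            and np.isclose(self.spectrometer_frequency,
                           other.spectrometer_frequency, rtol=rtol)
            and self.nucleus == other.nucleus
            and np.isclose(self.ppm_reference, other.ppm_reference, rtol=rtol)
            and np.allclose(self.affine, other.affine, rtol=rtol, atol=atol)
        )


def get_axes(data: MRSData) -> FrequencyAxis:
    """Frequency/ppm axes of ``data`` under the package convention."""
    return data.axes()


# ---------------------------------------------------------------------------
# BasisSet
# ---------------------------------------------------------------------------

@dataclass
class BasisSet:
    """Named per-metabolite unbroadened FIDs sharing one time axis.

    Relative amplitudes between metabolites are meaningful and must be
    preserved by every I/O path; the absolute scale is arbitrary and
    documented in ``scaling_note``.
    """

    names: list
    fids: np.ndarray  # [metabolite, time]
    dwell_time: float
    spectrometer_frequency: float
    ppm_reference: float = WATER_PPM
    scaling_note: str = "arbitrary common scale; relative amplitudes meaningful"

    def __post_init__(self):
        self.names = list(self.names)
        self.fids = np.atleast_2d(np.asarray(self.fids, dtype=np.complex128))
        if len(self.names) != self.fids.shape[0]:
            raise FormatError("number of names does not match number of FIDs")
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate metabolite names in basis")
        if not self.dwell_time > 0 or not self.spectrometer_frequency > 0:
            raise MetadataError("dwell_time and spectrometer_frequency must be > 0")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_timepoints(self) -> int:
        return self.fids.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dwell_time

    def axes(self) -> FrequencyAxis:
        return FrequencyAxis.from_params(
            self.n_timepoints, self.dwell_time,
            self.spectrometer_frequency, self.ppm_reference)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ParameterError(f"metabolite {name!r} not in basis") from None

    def fid_of(self, name: str) -> np.ndarray:
        return self.fids[self.index(name)]

    def subset(self, names: Sequence[str]) -> "BasisSet":
        idx = [self.index(n) for n in names]
        return BasisSet(list(names), self.fids[idx].copy(), self.dwell_time,
                        self.spectrometer_frequency, self.ppm_reference,
                        self.scaling_note)

    def drop(self, names: Sequence[str]) -> "BasisSet":
        keep = [n for n in self.names if n not in set(names)]
        return self.subset(keep)

    def add_entry(self, name: str, fid: np.ndarray) -> "BasisSet":
        if name in self.names:
            raise FormatError(f"duplicate metabolite name {name!r}")
        fids = np.vstack([self.fids, np.asarray(fid, dtype=np.complex128)])
        return BasisSet(self.names + [name], fids, self.dwell_time,
                        self.spectrometer_frequency, self.ppm_reference,
                        self.scaling_note)

    def allclose(self, other: "BasisSet", rtol=1e-12, atol=0.0) -> bool:
        return (
            self.names == other.names
            and self.fids.shape == other.fids.shape
            and np.allclose(self.fids, other.fids, rtol=rtol, atol=atol)
            and np.isclose(self.dwell_time, other.dwell_time, rtol=rtol)
            and np.isclose(self.spectrometer_frequency,
                           other.spectrometer_frequency, rtol=rtol)
        )
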