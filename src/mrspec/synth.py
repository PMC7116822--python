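"""Synthetic fixtures: basis sets, noisy known-truth spectra, multi-coil raw
data and MRSI grids.

All generators are pure functions of their specification and a seed, so
every dataset is exactly reproducible.  Noise is added in the frequency
domain as complex white Gaussian noise of SD ``noise_sd`` per point (the
orthonormal FFT makes this equivalent to white time-domain noise of the
same SD), giving exact control of spectral SNR = peak height / noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BasisSet, MRSData, ParameterError, to_fid
from .model import (FitConfig, FitParameters, MM_DEFAULT_PPM, forward_full)

__all__ = [
    "LineSpec", "AxisSpec", "GroundTruth", "make_basis", "make_svs",
    "make_multicoil", "make_mrsi", "default_panel", "default_mm_linespecs",
    "default_truth", "calibration_truth", "MODERATE_NOISE_SD",
    "WELL_SEPARATED",
]


@dataclass
class AxisSpec:
    """Acquisition grid for synthetic data."""

    n_points: int = 1024
    bandwidth: float = 2000.0          # Hz
    spectrometer_frequency: float = 123.2  # MHz
    ppm_reference: float = 4.65

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.bandwidth


@dataclass
class LineSpec:
    """Analytic lineshape specification for one metabolite.

    Each line is ``{ppm, amplitude, lorentzian_r (1/s), gaussian_s (1/s)}``;
    an optional ``multiplet = {"j": Hz, "pattern": "d"|"t"}`` splits the
    line into a doublet or triplet around its centre.
    """

    metabolite: str
    lines: list

    def __post_init__(self):
        for ln in self.lines:
            if ln.get("amplitude", 1.0) <= 0:
                raise ParameterError("line amplitudes must be > 0")


def _expand_multiplet(line: dict):
    mult = line.get("multiplet")
    if not mult:
        return [(line["ppm"], 0.0, line.get("amplitude", 1.0))]
    j = mult["j"]
    pattern = mult.get("pattern", "d")
    if pattern == "d":
        offs, wts = (-j / 2, j / 2), (0.5, 0.5)
    elif pattern == "t":
        offs, wts = (-j, 0.0, j), (0.25, 0.5, 0.25)
    else:
        raise ParameterError(f"unknown multiplet pattern {pattern!r}")
    amp = line.get("amplitude", 1.0)
    return [(line["ppm"], off, amp * w) for off, w in zip(offs, wts)]


def make_basis(linespecs, axis_spec: AxisSpec | None = None) -> BasisSet:
    """Analytic basis FIDs ``sum amp * exp((-r + 2j*pi*f) t - s^2 t^2)``."""
    ax = axis_spec or AxisSpec()
    t = np.arange(ax.n_points) * ax.dwell_time
    names, fids = [], []
    for spec in linespecs:
        fid = np.zeros(ax.n_points, dtype=complex)
        for line in spec.lines:
            r = line.get("lorentzian_r", 0.0)
            s = line.get("gaussian_s", 0.0)
            for ppm, hz_off, amp in _expand_multiplet(line):
                f = (ax.ppm_reference - ppm) * ax.spectrometer_frequency + hz_off
                fid += amp * np.exp((-r + 2j * np.pi * f) * t - (s * t) ** 2)
        names.append(spec.metabolite)
        fids.append(fid)
    return BasisSet(names, np.array(fids), ax.dwell_time,
                    ax.spectrometer_frequency, ax.ppm_reference,
                    scaling_note="analytic synthetic basis; one unit per proton")


def default_panel() -> list:
    """The standard fixture panel: five well-separated resonances plus one
    overlapping choline pair (amplitudes are proton counts)."""
    return [
        LineSpec("NAA", [{"ppm": 2.008, "amplitude": 3.0}]),
        LineSpec("Cr", [{"ppm": 3.027, "amplitude": 3.0},
                        {"ppm": 3.913, "amplitude": 2.0}]),
        LineSpec("Glu", [{"ppm": 2.348, "amplitude": 2.0}]),
        LineSpec("mI", [{"ppm": 3.56, "amplitude": 4.0}]),
        LineSpec("Lac", [{"ppm": 1.313, "amplitude": 3.0,
                          "multiplet": {"j": 6.933, "pattern": "d"}}]),
        LineSpec("Cho", [{"ppm": 3.185, "amplitude": 9.0}]),
        LineSpec("GPC", [{"ppm": 3.212, "amplitude": 9.0}]),
    ]


#: Metabolites of the default panel with no overlapping neighbour.
WELL_SEPARATED = ("NAA", "Cr", "Glu", "mI", "Lac")


def default_mm_linespecs(sigma: float = 12.0, amplitude: float = 1.0) -> list:
    """Gaussian macromolecule singlets at the default ppm positions."""
    return [LineSpec(f"MM{p:.2f}".replace(".", "")[:5],
                     [{"ppm": p, "amplitude": amplitude, "gaussian_s": sigma}])
            for p in MM_DEFAULT_PPM]


@dataclass
class GroundTruth:
    """The generating parameters of one synthetic dataset."""

    concentrations: dict
    gamma: np.ndarray = field(default_factory=lambda: np.array([11.0]))
    sigma: np.ndarray = field(default_factory=lambda: np.array([9.0]))
    eps: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    phi0: float = 0.0
    phi1: float = 0.0
    baseline: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))
    noise_sd: float = 0.0
    seed: int = 0

    def params_for(self, basis: BasisSet, config: FitConfig) -> FitParameters:
        groups = config.groups_for(basis.names)
        ng = int(groups.max()) + 1

        def per_group(arr):
            arr = np.atleast_1d(np.asarray(arr, dtype=float))
            return arr if len(arr) == ng else np.full(ng, arr[0])

        conc = np.array([self.concentrations.get(n, 0.0) for n in basis.names])
        return FitParameters(conc, per_group(self.gamma),
                             per_group(self.sigma), per_group(self.eps),
                             self.phi0, self.phi1,
                             np.asarray(self.baseline, dtype=complex))


def default_truth(seed: int = 0, noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None) -> GroundTruth:
    """Typical brain-like concentrations for the default panel (arbitrary
    basis-scaled units); ``rng`` jitters them +-20% for calibration studies."""
    conc = {"NAA": 15.0, "Cr": 8.0, "Glu": 10.0, "mI": 6.0, "Lac": 3.0,
            "Cho": 1.5, "GPC": 1.2}
    if rng is not None:
        conc = {k: float(v * rng.uniform(0.8, 1.2)) for k, v in conc.items()}
    return GroundTruth(concentrations=conc, noise_sd=noise_sd, seed=seed)


#: Complex noise SD per spectral point giving a tallest-peak SNR of ~30 for
#: the default panel at default concentrations -- a moderate, in-vivo-like
#: spectral SNR.
MODERATE_NOISE_SD = 5.0


def calibration_truth(seed: int, noise_sd: float = MODERATE_NOISE_SD) -> GroundTruth:
    """One dataset of the posterior-calibration study.

    Concentrations jitter +-20% around the default panel; the nuisance
    parameters (broadening, shift) are drawn from the fitting priors
    (truncated at a small positive floor), the self-consistent design under
    which nominal credible-interval coverage is exact.
    """
    rng = np.random.default_rng(seed)
    truth = default_truth(seed=seed, noise_sd=noise_sd, rng=rng)
    truth.gamma = np.array([max(0.1, rng.normal(5.0, 2.5))])
    truth.sigma = np.array([max(0.1, rng.normal(5.0, 2.5))])
    truth.eps = np.array([rng.normal(0.0, 2 * np.pi * 1.0)])
    truth.phi0 = rng.normal(0.0, 0.05)
    return truth


def make_svs(truth: GroundTruth, basis: BasisSet,
             config: FitConfig | None = None) -> MRSData:
    """Noisy single-voxel dataset from a known truth (seeded, reproducible).

    The clean spectrum is the forward model at the truth parameters; complex
    white noise of SD ``truth.noise_sd`` is added per frequency point and
    the result inverse-transformed to a FID.
    """
    config = config or FitConfig()
    axis = basis.axes()
    params = truth.params_for(basis, config)
    spec = forward_full(params, basis, config, axis)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        spec = spec + truth.noise_sd * (
            rng.standard_normal(len(spec))
            + 1j * rng.standard_normal(len(spec)))
    fid = to_fid(spec)
    return MRSData(fid, basis.dwell_time, basis.spectrometer_frequency,
                   ppm_reference=basis.ppm_reference)


def make_multicoil(svs: MRSData, sensitivities, noise_cov,
                   n_averages: int = 1, freq_shifts=None, phase_shifts=None,
                   seed: int = 0, n_noise_samples: int = 256):
    """Expand an SVS dataset to coils/averages with correlated noise.

    Per-coil FID = ``c_k * signal + noise`` with noise drawn from
    ``noise_cov`` across coils; optional per-average frequency (Hz) and
    phase (rad) offsets are injected for alignment-recovery tests.  Returns
    ``(MRSData [1,1,1,T,coil,average], noise array [coil, n_noise_samples])``
    drawn from the same covariance for whitening.
    """
    sens = np.asarray(sensitivities, dtype=complex)
    nc = len(sens)
    if nc < 2:
        raise ParameterError("need at least 2 coils")
    cov = np.asarray(noise_cov, dtype=complex)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ParameterError("noise covariance must be positive definite") from None
    rng = np.random.default_rng(seed)
    base = svs.signal[0, 0, 0, :, 0, 0]
    T = len(base)
    t = svs.time_axis
    freq_shifts = np.zeros(n_averages) if freq_shifts is None \
        else np.asarray(freq_shifts, dtype=float)
    phase_shifts = np.zeros(n_averages) if phase_shifts is None \
        else np.asarray(phase_shifts, dtype=float)
    if len(freq_shifts) != n_averages or len(phase_shifts) != n_averages:
        raise ParameterError("shift lists must match n_averages")
    sig = np.empty((1, 1, 1, T, nc, n_averages), dtype=complex)
    for ia in range(n_averages):
        mod = base * np.exp(1j * (2 * np.pi * freq_shifts[ia] * t
                                  + phase_shifts[ia]))
        white = (rng.standard_normal((nc, T))
                 + 1j * rng.standard_normal((nc, T))) / np.sqrt(2)
        noise = chol @ white
        sig[0, 0, 0, :, :, ia] = (np.outer(sens, mod) + noise).T
    white = (rng.standard_normal((nc, n_noise_samples))
             + 1j * rng.standard_normal((nc, n_noise_samples))) / np.sqrt(2)
    noise_only = chol @ white
    data = MRSData(sig, svs.dwell_time, svs.spectrometer_frequency,
                   ppm_reference=svs.ppm_reference)
    return data, noise_only


def make_mrsi(truth_grid, basis: BasisSet,
              config: FitConfig | None = None) -> MRSData:
    """Independent :func:`make_svs` per voxel arranged on a spatial grid.

    ``truth_grid`` is a nested list ``[nx][ny]`` of :class:`GroundTruth`
    (or None for empty voxels).  The affine is a scaled identity (10 mm
    voxels).
    """
    config = config or FitConfig()
    nx = len(truth_grid)
    ny = len(truth_grid[0])
    T = basis.n_timepoints
    sig = np.zeros((nx, ny, 1, T, 1, 1), dtype=complex)
    for ix in range(nx):
        if len(truth_grid[ix]) != ny:
            raise ParameterError("truth grid must be rectangular")
        for iy in range(ny):
            truth = truth_grid[ix][iy]
            if truth is None:
                continue
            svs = make_svs(truth, basis, config)
            sig[ix, iy, 0, :, 0, 0] = svs.signal[0, 0, 0, :, 0, 0]
    affine = np.diag([10.0, 10.0, 10.0, 1.0])
    return MRSData(sig, basis.dwell_time, basis.spectrometer_frequency,
                   ppm_reference=basis.ppm_reference, affine=affine)
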