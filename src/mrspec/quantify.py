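"""Absolute and relative quantification plus SNR/FWHM quality control.

Fitted concentrations come out of the linear-combination model in arbitrary
basis-scaled units.  This module converts them to:

* ``internal_ratio`` -- ratio to a reference metabolite (or sum of several);
* ``molar`` (mol/dm^3) / ``molal`` (mol/kg of tissue water) -- by scaling to
  the integral of the unsuppressed water spectrum, correcting for proton
  counts, T2 relaxation (``exp(-TE/T2)`` observed-signal attenuation) and
  tissue water content (Gasparovic-style compartment terms; the default
  :class:`QuantSpec` assumes pure water, the appropriate setting for
  phantoms and when no segmentation is available).

Every multiplicative factor is logged in the output table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FrequencyAxis, MRSData, ParameterError, to_spectrum
from .fitting import FitResult
from .model import voigt_transform
from .preproc import phase_by_peak

__all__ = [
    "QuantSpec", "load_constants", "water_amplitude", "reference_amplitude",
    "to_concentration", "qc_metrics", "fwhm_hz",
]


def load_constants(path=None) -> dict:
    """Load quantification constants (defaults ship with the package)."""
    if path is not None:
        return json.loads(Path(path).read_text())
    return json.loads(
        resources.files("mrspec.data").joinpath("quant_constants.json")
        .read_text())


@dataclass
class QuantSpec:
    """Constants controlling water-referenced quantification.

    ``tissue_fractions`` must sum to 1; the defaults describe a pure-water
    voxel (density 1, no CSF partial volume correction), matching the
    phantom setting.  ``t2_water``/``t2_metab`` are in seconds; ``te`` is
    the sequence echo time.  ``proton_counts`` maps metabolite name to the
    number of protons contributing to its modelled signal.
    """

    te: float = 0.0
    tissue_fractions: dict = field(
        default_factory=lambda: {"GM": 1.0, "WM": 0.0, "CSF": 0.0})
    water_concentration: float = 55.51  # mol/dm^3
    water_protons: int = 2
    t2_water: dict = field(
        default_factory=lambda: {"GM": np.inf, "WM": np.inf, "CSF": np.inf})
    t2_metab: float = np.inf
    water_densities: dict = field(
        default_factory=lambda: {"GM": 1.0, "WM": 1.0, "CSF": 1.0})
    reference_metabolite: tuple = ("Cr",)
    reference_ppm_range: tuple = (2.0, 5.0)
    proton_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.reference_metabolite, str):
            self.reference_metabolite = (self.reference_metabolite,)
        total = sum(self.tissue_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ParameterError("tissue fractions must sum to 1")
        for t2 in list(self.t2_water.values()) + [self.t2_metab]:
            if not t2 > 0:
                raise ParameterError("all T2 values must be > 0")

    @classmethod
    def from_constants(cls, field_strength: str = "3T", te: float = 0.0,
                       tissue_fractions=None, path=None, **kw) -> "QuantSpec":
        c = load_constants(path)
        return cls(
            te=te,
            tissue_fractions=tissue_fractions or {"GM": 1.0, "WM": 0.0,
                                                  "CSF": 0.0},
            water_concentration=c["water_concentration_mol_per_dm3"],
            water_protons=c["water_protons"],
            t2_water=c["t2_water_s"][field_strength],
            t2_metab=c["t2_metabolite_s"][field_strength],
            water_densities=c["tissue_water_density"],
            reference_metabolite=(c["default_reference_metabolite"],),
            reference_ppm_range=tuple(c["default_reference_ppm_range"]),
            **kw)


# ---------------------------------------------------------------------------
# Signal amplitudes
# ---------------------------------------------------------------------------

def _absorption_spectrum(fid: np.ndarray) -> np.ndarray:
    """Spectrum for integration: the first time-domain point is halved so a
    causal decaying signal yields a pure absorption line without the flat
    offset the plain DFT spreads across all bins."""
    f = np.asarray(fid, dtype=complex).copy()
    f[..., 0] *= 0.5
    return to_spectrum(f)


def water_amplitude(water_ref: MRSData, integration_range=None) -> float:
    """Integrated real part of the phased unsuppressed water spectrum.

    The spectrum is zero-order phased by its largest peak, then the real
    part is integrated (trapezoid rule over the Hz axis) across
    ``integration_range`` in ppm (default: the full axis).
    """
    axis = water_ref.axes()
    if integration_range is None:
        integration_range = (axis.ppm.min(), axis.ppm.max())
    mask = axis.ppm_mask(*integration_range)
    if not mask.any():
        raise ParameterError("integration range outside the spectral axis")
    phased = phase_by_peak(water_ref, integration_range)
    spec = _absorption_spectrum(phased.signal[0, 0, 0, :, 0, 0])
    return float(np.trapezoid(spec.real[mask], axis.hz[mask]))


def reference_amplitude(result: FitResult, basis=None,
                        spec: QuantSpec | None = None) -> float:
    """Integral of the fitted-scale reference basis over the reference range.

    Each reference metabolite's basis FID is broadened by its group's fitted
    parameters, scaled by its fitted concentration, zero-order phased by the
    tallest in-range peak and the real part integrated over
    ``reference_ppm_range``.
    """
    spec = spec or QuantSpec()
    basis = basis if basis is not None else result.basis
    axis = result.axis if result.axis is not None else basis.axes()
    groups = result.config.groups_for(basis.names) if result.config is not None \
        else np.zeros(len(basis), dtype=int)
    mask = axis.ppm_mask(*spec.reference_ppm_range)
    if not mask.any():
        raise ParameterError("reference ppm range outside the spectral axis")
    p = result.point_estimate
    total = 0.0
    for name in spec.reference_metabolite:
        if name not in basis.names:
            raise ParameterError(f"reference metabolite {name!r} not in basis")
        i = basis.names.index(name)
        g = groups[i]
        t = basis.time_axis
        fid = p.conc[i] * basis.fids[i] * np.exp(
            -(p.gamma[g] + p.sigma[g] ** 2 * t) * t + 1j * p.eps[g] * t)
        s = _absorption_spectrum(fid)
        sub = s[mask]
        if np.max(np.abs(sub)) > 0:
            sub = sub * np.exp(-1j * np.angle(sub[np.argmax(np.abs(sub))]))
        total += float(np.trapezoid(sub.real, axis.hz[mask]))
    return total


# ---------------------------------------------------------------------------
# Concentration conversion
# ---------------------------------------------------------------------------

def to_concentration(result: FitResult, water_amp: float | None = None,
                     spec: QuantSpec | None = None,
                     mode: str = "internal_ratio") -> pd.DataFrame:
    """Convert fitted amplitudes to the requested concentration scale.

    ``internal_ratio``: each concentration divided by the summed reference
    concentration.  ``molar``/``molal``: water-referenced absolute units;
    requires ``water_amp`` from :func:`water_amplitude`.  The returned table
    logs every factor used.
    """
    spec = spec or QuantSpec()
    names = list(result.metab_names)
    conc = np.asarray(result.point_estimate.conc, dtype=float)
    ref_idx = []
    for rname in spec.reference_metabolite:
        if rname not in names:
            raise ParameterError(f"reference metabolite {rname!r} not fitted")
        ref_idx.append(names.index(rname))
    c_ref = conc[ref_idx].sum()

    table = pd.DataFrame({"metabolite": names, "raw_conc": conc})
    if result.has_samples:
        # posterior-SD percentage uncertainty (an uncertainty proxy)
        sds = result.samples[:, :len(names)].std(axis=0)
        means = result.samples[:, :len(names)].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            table["pct_uncertainty"] = 100 * sds / np.abs(means)
    else:
        table["pct_uncertainty"] = np.nan
    if mode == "internal_ratio":
        if c_ref == 0:
            raise ParameterError("reference concentration is zero")
        table["internal_ratio"] = conc / c_ref
        table["reference"] = "+".join(spec.reference_metabolite)
        return table
    if mode not in ("molar", "molal"):
        raise ParameterError(f"unknown quantification mode {mode!r}")
    if water_amp is None:
        raise ParameterError("water amplitude required for absolute units")
    s_ref = reference_amplitude(result, result.basis, spec)

    fr = spec.tissue_fractions
    dens = spec.water_densities
    relax_m = np.exp(-spec.te / spec.t2_metab)
    # compartment-weighted visible water signal per unit true water
    water_vis = sum(fr[c] * dens[c] * np.exp(-spec.te / spec.t2_water[c])
                    for c in fr)
    water_content = sum(fr[c] * dens[c] for c in fr)
    f_csf = fr.get("CSF", 0.0)

    n_ref = sum(spec.proton_counts.get(r, 1) for r in spec.reference_metabolite)
    # concentration of the reference in mol/dm^3 of tissue water
    conc_ref = ((s_ref / water_amp) * (spec.water_protons / n_ref)
                * spec.water_concentration * (water_vis / relax_m))
    if mode == "molar":
        scale_tissue = 1.0 / max(1.0 - f_csf, 1e-12)
        col = "molar"
    else:
        scale_tissue = 1.0 / max(water_content, 1e-12)
        col = "molal"
    conc_ref = conc_ref * scale_tissue
    per_raw = conc_ref / c_ref if c_ref != 0 else np.nan
    values = conc * per_raw
    # proton-count normalisation per metabolite relative to the reference
    # basis convention (basis amplitudes already carry proton counts when
    # simulated per proton, so no per-metabolite factor is applied here).
    table[col] = values
    table["S_ref"] = s_ref
    table["S_water"] = water_amp
    table["relax_metab"] = relax_m
    table["water_visibility"] = water_vis
    table["tissue_scale"] = scale_tissue
    table["water_concentration"] = spec.water_concentration
    table["reference"] = "+".join(spec.reference_metabolite)
    return table


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def fwhm_hz(spectrum_real: np.ndarray, hz: np.ndarray) -> float:
    """Full width at half maximum of the tallest peak, by half-height
    crossings with linear interpolation."""
    i = int(np.argmax(spectrum_real))
    half = spectrum_real[i] / 2.0
    if half <= 0:
        return float("nan")

    def cross(direction):
        j = i
        while 0 < j < len(spectrum_real) - 1:
            j += direction
            if spectrum_real[j] <= half:
                x0, x1 = hz[j - direction], hz[j]
                y0, y1 = spectrum_real[j - direction], spectrum_real[j]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
        return hz[j]

    return float(abs(cross(+1) - cross(-1)))


def qc_metrics(result: FitResult, basis=None, noise_range=(-3.0, -1.0),
               data: MRSData | None = None) -> pd.DataFrame:
    """Per-metabolite SNR and linewidth of the fitted basis spectra.

    FWHM is measured on the fitted (scaled, broadened) basis spectrum at its
    tallest peak.  SNR is the filtered peak height over the SD of the real
    part of the filtered data spectrum in ``noise_range`` (ppm), with a
    time-domain exponential matched filter ``exp(-pi*FWHM*t)`` applied to
    both.  ``noise_range`` must contain no signal.
    """
    import warnings

    basis = basis if basis is not None else result.basis
    axis = result.axis if result.axis is not None else basis.axes()
    groups = result.config.groups_for(basis.names) if result.config is not None \
        else np.zeros(len(basis), dtype=int)
    nmask = axis.ppm_mask(*noise_range)
    if not nmask.any():
        raise ParameterError("noise range outside the spectral axis")
    fit_lo, fit_hi = (result.config.ppm_fit_range if result.config
                      else (0.2, 4.2))
    if noise_range[0] < fit_hi and noise_range[1] > fit_lo:
        warnings.warn("noise range overlaps the fit range")
    t = basis.time_axis
    p = result.point_estimate
    if data is not None:
        data_fid = data.signal[0, 0, 0, :, 0, 0]
    else:
        # reconstruct data FID from model + residual on the fit range
        from .core import to_fid
        full = result.fit_spectrum.copy()
        full[axis.ppm_mask(fit_lo, fit_hi)] += result.residual
        data_fid = to_fid(full)
    rows = []
    for i, name in enumerate(basis.names):
        g = groups[i]
        spec_fit = p.conc[i] * voigt_transform(
            basis.fids[i], p.gamma[g], p.sigma[g], p.eps[g], basis.dwell_time)
        mag = np.abs(spec_fit)
        if mag.max() == 0:
            rows.append({"metabolite": name, "snr": 0.0, "fwhm_hz": np.nan})
            continue
        phased = (spec_fit * np.exp(-1j * np.angle(
            spec_fit[np.argmax(mag)]))).real
        width = fwhm_hz(phased, axis.hz)
        filt = np.exp(-np.pi * width * t)
        fid_fit = p.conc[i] * basis.fids[i] * np.exp(
            -(p.gamma[g] + p.sigma[g] ** 2 * t) * t + 1j * p.eps[g] * t)
        spec_filt = voigt_transform(fid_fit * filt, 0, 0, 0, basis.dwell_time)
        peak = float(np.max(np.abs(spec_filt)))
        noise_spec = to_spectrum(data_fid * filt)
        noise_sd = float(np.std(noise_spec.real[nmask]))
        rows.append({"metabolite": name,
                     "snr": peak / noise_sd if noise_sd > 0 else np.inf,
                     "fwhm_hz": width})
    return pd.DataFrame(rows)
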