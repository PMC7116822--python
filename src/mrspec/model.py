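"""The linear-combination forward model, baseline, priors and likelihood.

Model for the complex spectrum on the fit range::

    Y(v) = B(v) + exp(1j*(phi0 + v*phi1)) * sum_g sum_{l in g} C_l * M_l(v)
    M_l(v; gamma_g, sigma_g, eps_g) = F[ m_l(t) * exp(-(gamma + sigma^2 t) t
                                                      + 1j*eps*t) ]

where ``v`` is the frequency offset in Hz from the receiver centre, ``B`` an
order-N complex polynomial baseline (2(N+1) real coefficients), ``C_l >= 0``
the metabolite concentrations (arbitrary basis-scaled units), and each
metabolite belongs to exactly one broadening/shift group g with Lorentzian
rate ``gamma_g`` (1/s), Gaussian rate ``sigma_g`` (1/s) and frequency shift
``eps_g`` (rad/s).

The likelihood treats the complex residual on the fit range as Gaussian
white noise in its real and imaginary parts and integrates the noise SD out
under a Jeffreys (1/s) prior, giving the marginal form
``-(N/2)*log(pi*SSE) + lgamma(N/2) - log(2)`` with ``N`` real residual
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import (BasisSet, FrequencyAxis, ParameterError, to_spectrum)

__all__ = [
    "FitParameters", "FitConfig", "PriorSettings", "voigt_transform",
    "baseline_design", "forward", "forward_full", "log_likelihood",
    "log_prior", "default_mm_basis", "MM_DEFAULT_PPM",
]

#: Default macromolecule peak positions (ppm).
MM_DEFAULT_PPM = (0.9, 1.2, 1.4, 1.7, 2.08, 3.0)

#: Sentinel group name for the default macromolecule peaks.
MM_GROUP = "MM"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PriorSettings:
    """Widths/centres of the default priors (all configurable).

    Concentrations: half-Gaussian, zero mean, SD ``conc_sd`` (positivity
    enforced).  gamma/sigma: Gaussian centred at ``broadening_center`` with
    SD ``broadening_sd`` (numeric values of the 1/s rates; the centre adds
    ~10 Hz of combined line broadening on top of the basis), truncated at 0.
    Shifts/phases: zero-centred Gaussians.
    """

    conc_sd: float = 1e3
    broadening_center: float = 5.0
    broadening_sd: float = 2.5
    eps_sd: float = 2 * np.pi * 20.0   # rad/s
    phi0_sd: float = np.pi
    phi1_sd: float = 1e-2              # rad/Hz


@dataclass
class FitConfig:
    """Options controlling the fit."""

    ppm_fit_range: tuple = (0.2, 4.2)
    baseline_order: int = 2            # -1 disables the baseline
    metabolite_groups: dict | None = None
    add_default_mm: bool = False
    algorithm: str = "newton"          # {"newton", "mh"}
    mh_samples: int = 2000
    mh_burn_in: int = 1000
    seed: int | None = None
    priors: str = "on"                 # {"on", "uniform"}
    prior_settings: PriorSettings = field(default_factory=PriorSettings)

    def n_baseline_coeffs(self) -> int:
        return 0 if self.baseline_order < 0 else self.baseline_order + 1

    def groups_for(self, names) -> np.ndarray:
        """Integer group index per metabolite (default: one group for
        metabolites, a separate one for MM entries)."""
        if self.metabolite_groups is None:
            mapping = {n: (MM_GROUP if n.startswith(MM_GROUP) else "metab")
                       for n in names}
        else:
            mapping = dict(self.metabolite_groups)
            missing = [n for n in names if n not in mapping]
            if missing:
                raise ParameterError(
                    f"metabolite_groups does not cover {missing}")
        labels = []
        for n in names:
            if mapping[n] not in labels:
                labels.append(mapping[n])
        return np.array([labels.index(mapping[n]) for n in names])

    def to_dict(self) -> dict:
        return {
            "ppm_fit_range": list(self.ppm_fit_range),
            "baseline_order": self.baseline_order,
            "metabolite_groups": self.metabolite_groups,
            "add_default_mm": self.add_default_mm,
            "algorithm": self.algorithm,
            "mh_samples": self.mh_samples,
            "mh_burn_in": self.mh_burn_in,
            "seed": self.seed,
            "priors": self.priors,
        }


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class FitParameters:
    """One point in model parameter space.

    ``conc`` per basis metabolite (>= 0); ``gamma``, ``sigma`` (1/s, >= 0)
    and ``eps`` (rad/s) per metabolite group; global phases ``phi0`` (rad)
    and ``phi1`` (rad/Hz); complex ``baseline`` coefficients (degree 0..N).
    """

    conc: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    eps: np.ndarray
    phi0: float = 0.0
    phi1: float = 0.0
    baseline: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))

    def __post_init__(self):
        self.conc = np.atleast_1d(np.asarray(self.conc, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        self.baseline = np.atleast_1d(np.asarray(self.baseline,
                                                 dtype=complex))
        if not (len(self.gamma) == len(self.sigma) == len(self.eps)):
            raise ParameterError("gamma/sigma/eps must share the group count")

    @property
    def n_groups(self) -> int:
        return len(self.gamma)

    def copy(self) -> "FitParameters":
        return FitParameters(self.conc.copy(), self.gamma.copy(),
                             self.sigma.copy(), self.eps.copy(),
                             self.phi0, self.phi1, self.baseline.copy())

    # -- flat real vector (sampled parameters only; baseline excluded) ------
    def pack(self) -> np.ndarray:
        return np.concatenate([
            self.conc, self.gamma, self.sigma, self.eps,
            [self.phi0, self.phi1]])

    @classmethod
    def unpack(cls, vec, n_metab: int, n_groups: int,
               baseline=None) -> "FitParameters":
        vec = np.asarray(vec, dtype=float)
        i = n_metab
        conc = vec[:i]
        gamma = vec[i:i + n_groups]; i += n_groups
        sigma = vec[i:i + n_groups]; i += n_groups
        eps = vec[i:i + n_groups]; i += n_groups
        phi0, phi1 = vec[i], vec[i + 1]
        if baseline is None:
            baseline = np.zeros(0, complex)
        return cls(conc, gamma, sigma, eps, phi0, phi1, baseline)

    def param_names(self, metab_names, group_labels=None) -> list:
        ng = self.n_groups
        glab = (group_labels if group_labels is not None
                else [f"g{j}" for j in range(ng)])
        names = list(metab_names)
        names += [f"gamma_{g}" for g in glab]
        names += [f"sigma_{g}" for g in glab]
        names += [f"eps_{g}" for g in glab]
        names += ["phi0", "phi1"]
        return names


# ---------------------------------------------------------------------------
# Model pieces
# ---------------------------------------------------------------------------

def voigt_transform(basis_fid: np.ndarray, gamma: float, sigma: float,
                    eps: float, dwell_time: float) -> np.ndarray:
    """Broaden and shift one basis FID; return its spectrum.

    ``F[m(t) * exp(-(gamma + sigma^2 t) t + 1j*eps*t)]`` on the package FFT
    convention.  ``gamma`` and ``sigma`` in 1/s, ``eps`` in rad/s (positive
    eps moves a peak by +eps/2pi Hz along the Hz axis).
    """
    t = np.arange(np.shape(basis_fid)[-1]) * dwell_time
    env = np.exp(-(gamma + sigma ** 2 * t) * t + 1j * eps * t)
    return to_spectrum(np.asarray(basis_fid) * env)


def baseline_design(axis: FrequencyAxis, order: int, fit_range) -> np.ndarray:
    """Real polynomial design matrix on the in-range points.

    Columns are powers 0..order of the Hz coordinate rescaled to [-1, 1]
    over the fit range (for conditioning); the complex baseline is
    ``M @ re_coeffs + 1j * (M @ im_coeffs)``.
    """
    if order < 0:
        raise ParameterError("baseline_design requires order >= 0")
    mask = axis.ppm_mask(*fit_range)
    hz = axis.hz[mask]
    lo, hi = hz.min(), hz.max()
    x = np.zeros_like(hz) if hi == lo else 2 * (hz - lo) / (hi - lo) - 1
    return np.vander(x, order + 1, increasing=True)


def _metab_spectra(params: FitParameters, basis: BasisSet,
                   groups: np.ndarray) -> np.ndarray:
    """Broadened metabolite spectra [metab, freq] for the current params."""
    t = basis.time_axis
    envs = {}
    for g in np.unique(groups):
        envs[g] = np.exp(-(params.gamma[g] + params.sigma[g] ** 2 * t) * t
                         + 1j * params.eps[g] * t)
    env = np.array([envs[g] for g in groups])
    return to_spectrum(basis.fids * env)


def forward_full(params: FitParameters, basis: BasisSet, config: FitConfig,
                 axis: FrequencyAxis) -> np.ndarray:
    """Model spectrum on the full frequency axis (baseline zero off-range)."""
    if len(axis) != basis.n_timepoints:
        raise ParameterError("axis length does not match basis")
    groups = config.groups_for(basis.names)
    if params.n_groups < groups.max() + 1:
        raise ParameterError("params do not cover all metabolite groups")
    spectra = _metab_spectra(params, basis, groups)
    mix = params.conc @ spectra
    phase = np.exp(1j * (params.phi0 + axis.hz * params.phi1))
    out = phase * mix
    if config.baseline_order >= 0 and len(params.baseline):
        mask = axis.ppm_mask(*config.ppm_fit_range)
        design = baseline_design(axis, config.baseline_order,
                                 config.ppm_fit_range)
        out[mask] = out[mask] + design @ params.baseline
    return out


def forward(params: FitParameters, basis: BasisSet, config: FitConfig,
            axis: FrequencyAxis) -> np.ndarray:
    """Model spectrum restricted to the fit range."""
    mask = axis.ppm_mask(*config.ppm_fit_range)
    return forward_full(params, basis, config, axis)[mask]


# ---------------------------------------------------------------------------
# Likelihood and priors
# ---------------------------------------------------------------------------

def marginal_loglik_from_sse(sse: float, n_real: int) -> float:
    """Marginal Gaussian log-likelihood with the noise SD integrated out
    under a Jeffreys 1/s prior: ``-(N/2) log(pi*SSE) + lgamma(N/2) - log 2``."""
    if sse <= 0:
        return np.inf
    return float(-(n_real / 2) * np.log(np.pi * sse)
                 + gammaln(n_real / 2) - np.log(2.0))


def log_likelihood(params: FitParameters, data_spectrum: np.ndarray,
                   basis: BasisSet, config: FitConfig,
                   axis: FrequencyAxis) -> float:
    """Marginalised log-likelihood of the in-range data under the model.

    ``data_spectrum`` must already be restricted to the fit range.  Returns
    ``+inf`` for a perfect fit (SSE = 0).
    """
    model = forward(params, basis, config, axis)
    if len(model) != len(data_spectrum):
        raise ParameterError("data and model are on different grids")
    r = data_spectrum - model
    sse = float(np.sum(r.real ** 2) + np.sum(r.imag ** 2))
    return marginal_loglik_from_sse(sse, 2 * len(r))


def _halfnorm_logpdf(x, sd):
    if np.any(x < 0):
        return -np.inf
    return float(np.sum(-x ** 2 / (2 * sd ** 2))
                 + len(np.atleast_1d(x)) * np.log(2.0 / (sd * np.sqrt(2 * np.pi))))


def _norm_logpdf(x, mu, sd):
    x = np.atleast_1d(x)
    return float(np.sum(-(x - mu) ** 2 / (2 * sd ** 2))
                 - len(x) * np.log(sd * np.sqrt(2 * np.pi)))


def log_prior(params: FitParameters, config: FitConfig) -> float:
    """Joint log-prior (up to the documented normalisation constants).

    Concentrations: broad zero-mean half-Gaussians (positivity enforced).
    gamma/sigma: Gaussians centred at 5 with SD 2.5 (1/s units), truncated
    at zero.  eps/phi0/phi1: broad zero-centred Gaussians.  In uniform mode
    the density is flat (0) inside the positivity bounds.
    """
    if np.any(params.conc < 0) or np.any(params.gamma < 0) \
            or np.any(params.sigma < 0):
        return -np.inf
    if config.priors == "uniform":
        return 0.0
    ps = config.prior_settings
    lp = _halfnorm_logpdf(params.conc, ps.conc_sd)
    lp += _norm_logpdf(params.gamma, ps.broadening_center, ps.broadening_sd)
    lp += _norm_logpdf(params.sigma, ps.broadening_center, ps.broadening_sd)
    lp += _norm_logpdf(params.eps, 0.0, ps.eps_sd)
    lp += _norm_logpdf(params.phi0, 0.0, ps.phi0_sd)
    lp += _norm_logpdf(params.phi1, 0.0, ps.phi1_sd)
    return lp


# ---------------------------------------------------------------------------
# Default macromolecule basis
# ---------------------------------------------------------------------------

def default_mm_basis(n_points: int, dwell_time: float,
                     spectrometer_frequency: float,
                     ppm_reference: float = 4.65,
                     sigma: float = 12.0,
                     amplitude: float = 1.0) -> BasisSet:
    """Gaussian-lineshape macromolecule singlets at the default positions.

    One entry per peak (``MM09`` ... ``MM30``); all are assigned to their own
    group by the default grouping so their shift/broadening is optimised
    separately from the metabolites.
    """
    t = np.arange(n_points) * dwell_time
    names, fids = [], []
    for ppm in MM_DEFAULT_PPM:
        f = (ppm_reference - ppm) * spectrometer_frequency
        fid = amplitude * np.exp(2j * np.pi * f * t - (sigma * t) ** 2)
        names.append(f"{MM_GROUP}{ppm:.2f}".replace(".", "")[:5])
        fids.append(fid)
    return BasisSet(names, np.array(fids), dwell_time, spectrometer_frequency,
                    ppm_reference, scaling_note="synthetic MM singlets")
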