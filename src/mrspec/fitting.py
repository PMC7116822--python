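"""Point estimation and posterior sampling of the spectral model.

``init_newton`` produces a deterministic point estimate (non-negative least
squares warm start, bounded least-squares refinement, then bounded
truncated-Newton ascent of the log-posterior).  ``sample_mh`` runs
component-wise Gaussian random-walk Metropolis-Hastings over all model
parameters except the baseline coefficients, which stay fixed at their
point-estimate values; proposal scales adapt toward a 20-50% acceptance
rate during burn-in and are frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .core import BasisSet, FrequencyAxis, MRSData, ParameterError
from .model import (FitConfig, FitParameters, baseline_design,
                    default_mm_basis, forward, forward_full, log_prior,
                    marginal_loglik_from_sse, to_spectrum)

__all__ = [
    "FitResult", "init_newton", "sample_mh", "fit_spectrum",
    "zscore_statistic", "combine_metabolites",
]


# ---------------------------------------------------------------------------
# FitResult
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Point estimate, posterior samples and summaries of one spectral fit."""

    point_estimate: FitParameters
    samples: np.ndarray            # [n_samples, n_params]; empty for newton
    param_names: list
    metab_names: list
    fit_spectrum: np.ndarray       # model on the full axis
    residual: np.ndarray           # data - model on the fit range
    config_echo: dict
    seed: int | None = None
    converged: bool = True
    basis: BasisSet | None = None
    axis: FrequencyAxis | None = None
    config: FitConfig | None = None
    combined: dict = field(default_factory=dict)

    @property
    def has_samples(self) -> bool:
        return self.samples.size > 0

    @property
    def covariance(self) -> np.ndarray:
        if not self.has_samples:
            return np.zeros((len(self.param_names),) * 2)
        return np.cov(self.samples, rowvar=False)

    @property
    def percentiles(self) -> pd.DataFrame:
        if not self.has_samples:
            raise ParameterError("no posterior samples (newton-only fit)")
        pct = np.percentile(self.samples, [5, 50, 95], axis=0)
        return pd.DataFrame(pct.T, index=self.param_names,
                            columns=["p5", "p50", "p95"])

    def concentration(self, name: str) -> float:
        if name in self.combined:
            return float(np.mean(self.combined[name]))
        return float(self.point_estimate.conc[self.metab_names.index(name)])

    def concentration_sd(self, name: str) -> float:
        if name in self.combined:
            return float(np.std(self.combined[name]))
        if self.has_samples:
            return float(np.std(self.samples[:, self.metab_names.index(name)]))
        return float("nan")

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.metab_names):
            row = {"metabolite": name,
                   "conc": float(self.point_estimate.conc[i])}
            if self.has_samples:
                s = self.samples[:, i]
                row.update(sd=float(s.std()), p5=float(np.percentile(s, 5)),
                           p50=float(np.percentile(s, 50)),
                           p95=float(np.percentile(s, 95)))
            rows.append(row)
        for name, s in self.combined.items():
            rows.append({"metabolite": name, "conc": float(np.mean(s)),
                         "sd": float(np.std(s)),
                         "p5": float(np.percentile(s, 5)),
                         "p50": float(np.percentile(s, 50)),
                         "p95": float(np.percentile(s, 95))})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Incremental model evaluation (used by both stages)
# ---------------------------------------------------------------------------

class _ModelCache:
    """Evaluate the in-range model cheaply under single-parameter updates.

    Per group it caches the time-domain concentration-weighted FID sum and
    the broadening envelope, so any single-parameter update costs one FFT;
    phase updates reuse the cached group spectra entirely.
    """

    def __init__(self, data_inrange, basis: BasisSet, config: FitConfig,
                 axis: FrequencyAxis):
        self.data = np.asarray(data_inrange)
        self.basis = basis
        self.config = config
        self.axis = axis
        self.mask = axis.ppm_mask(*config.ppm_fit_range)
        self.hz = axis.hz[self.mask]
        self.t = basis.time_axis
        self.groups = config.groups_for(basis.names)
        self.n_groups = int(self.groups.max()) + 1
        self.group_idx = [np.flatnonzero(self.groups == g)
                          for g in range(self.n_groups)]
        self.n_real = 2 * len(self.data)
        if config.baseline_order >= 0:
            self.design = baseline_design(axis, config.baseline_order,
                                          config.ppm_fit_range)
        else:
            self.design = None

    # -- state --------------------------------------------------------------
    def set_params(self, params: FitParameters):
        self.params = params.copy()
        self.env = [None] * self.n_groups
        self.combo = [None] * self.n_groups   # time-domain weighted sum
        self.partial = [None] * self.n_groups  # in-range spectrum per group
        for g in range(self.n_groups):
            self._refresh_env(g)
            self._refresh_combo(g)
        self._refresh_phase()
        self._refresh_baseline()

    def _refresh_env(self, g):
        p = self.params
        self.env[g] = np.exp(-(p.gamma[g] + p.sigma[g] ** 2 * self.t) * self.t
                             + 1j * p.eps[g] * self.t)

    def _refresh_combo(self, g):
        idx = self.group_idx[g]
        self.combo[g] = self.params.conc[idx] @ self.basis.fids[idx]
        self._refresh_partial(g)

    def _refresh_partial(self, g):
        self.partial[g] = to_spectrum(self.combo[g] * self.env[g])[self.mask]

    def _refresh_phase(self):
        p = self.params
        self.phase = np.exp(1j * (p.phi0 + self.hz * p.phi1))

    def _refresh_baseline(self):
        if self.design is not None and len(self.params.baseline):
            self.bline = self.design @ self.params.baseline
        else:
            self.bline = 0.0

    # -- evaluation ----------------------------------------------------------
    def model(self) -> np.ndarray:
        return self.bline + self.phase * sum(self.partial)

    def sse(self) -> float:
        r = self.data - self.model()
        return float(r.real @ r.real + r.imag @ r.imag)

    def loglik(self) -> float:
        return marginal_loglik_from_sse(self.sse(), self.n_real)

    def logpost(self) -> float:
        lp = log_prior(self.params, self.config)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglik()

    # -- single-parameter updates -------------------------------------------
    def update(self, kind: str, index, value) -> None:
        p = self.params
        if kind == "conc":
            g = self.groups[index]
            p.conc[index] = value
            self._refresh_combo(g)
        elif kind in ("gamma", "sigma", "eps"):
            getattr(p, kind)[index] = value
            self._refresh_env(index)
            self._refresh_partial(index)
        elif kind == "phi0":
            p.phi0 = value
            self._refresh_phase()
        elif kind == "phi1":
            p.phi1 = value
            self._refresh_phase()
        else:
            raise ParameterError(f"unknown parameter kind {kind!r}")


# ---------------------------------------------------------------------------
# Newton initialisation
# ---------------------------------------------------------------------------

def _pack_bounds(n_metab, n_groups):
    lo = np.concatenate([
        np.zeros(n_metab), np.zeros(n_groups), np.zeros(n_groups),
        np.full(n_groups, -np.inf), [-np.inf, -np.inf]])
    hi = np.full(len(lo), np.inf)
    return lo, hi


def init_newton(data_spectrum: np.ndarray, basis: BasisSet, config: FitConfig,
                axis: FrequencyAxis | None = None) -> FitParameters:
    """Deterministic point estimate of the model parameters.

    A variable-projection stage first fits the nonlinear parameters
    (broadening, shift, phases; deterministic start gamma = sigma = 5/s,
    eps = phi0 = phi1 = 0) by bounded least squares, solving the
    concentrations (non-negative) and baseline coefficients exactly at each
    step; a bounded truncated-Newton ascent of the full log-posterior (or
    log-likelihood in uniform-prior mode) then polishes all parameters,
    keeping the best iterate seen.  Deterministic given its inputs.
    """
    if len(basis) == 0:
        raise ParameterError("empty basis")
    if axis is None:
        axis = basis.axes()
    mask = axis.ppm_mask(*config.ppm_fit_range)
    data_in = (data_spectrum[mask] if len(data_spectrum) == len(axis)
               else np.asarray(data_spectrum))
    if len(data_in) != int(mask.sum()):
        raise ParameterError("data length matches neither the axis nor the fit range")
    groups = config.groups_for(basis.names)
    n_groups = int(groups.max()) + 1
    n_metab = len(basis)

    # --- variable projection: linear params solved exactly per nonlinear ----
    t = basis.time_axis
    n_bl = config.n_baseline_coeffs()
    design = (baseline_design(axis, config.baseline_order,
                              config.ppm_fit_range) if n_bl else None)
    hz_in = axis.hz[mask]

    def linear_solve(theta):
        """Best (conc >= 0, baseline) for nonlinear params theta."""
        gamma = theta[:n_groups]
        sigma = theta[n_groups:2 * n_groups]
        eps = theta[2 * n_groups:3 * n_groups]
        phi0, phi1 = theta[3 * n_groups], theta[3 * n_groups + 1]
        env = np.exp(-(gamma[groups, None] + sigma[groups, None] ** 2 * t) * t
                     + 1j * eps[groups, None] * t)
        spectra = to_spectrum(basis.fids * env)[:, mask]
        phased = spectra * np.exp(1j * (phi0 + hz_in * phi1))
        cols = [np.concatenate([phased.real.T, phased.imag.T], axis=0)]
        if n_bl:
            z = np.zeros_like(design)
            cols.append(np.block([[design], [z]]))          # real baseline
            cols.append(np.block([[z], [design]]))          # imag baseline
        a = np.hstack(cols)
        b = np.concatenate([data_in.real, data_in.imag])
        lb = np.concatenate([np.zeros(n_metab), np.full(2 * n_bl, -np.inf)])
        ub = np.full(n_metab + 2 * n_bl, np.inf)
        sol = scipy.optimize.lsq_linear(a, b, bounds=(lb, ub),
                                        method="bvls", tol=1e-14)
        conc = sol.x[:n_metab]
        bl = (sol.x[n_metab:n_metab + n_bl]
              + 1j * sol.x[n_metab + n_bl:]) if n_bl else np.zeros(0, complex)
        return conc, bl, sol.fun  # fun = residual vector a@x - b

    def varpro_resid(theta):
        return linear_solve(theta)[2]

    theta0 = np.concatenate([np.full(n_groups, 5.0), np.full(n_groups, 5.0),
                             np.zeros(n_groups), [0.0, 0.0]])
    th_lo = np.concatenate([np.zeros(2 * n_groups),
                            np.full(n_groups, -np.inf), [-np.inf, -np.inf]])
    th_hi = np.full_like(theta0, np.inf)
    x_scale = np.concatenate([np.full(2 * n_groups, 2.0),
                              np.full(n_groups, 2 * np.pi), [0.1, 1e-3]])
    sol = scipy.optimize.least_squares(
        varpro_resid, theta0, bounds=(th_lo, th_hi), method="trf",
        x_scale=x_scale, xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=300)
    theta = sol.x
    conc, bl, _ = linear_solve(theta)
    params = FitParameters(conc, theta[:n_groups],
                           theta[n_groups:2 * n_groups],
                           theta[2 * n_groups:3 * n_groups],
                           theta[3 * n_groups], theta[3 * n_groups + 1], bl)

    # --- truncated-Newton ascent of the log-posterior -----------------------
    cache = _ModelCache(data_in, basis, config, axis)

    def neg_logpost(vec):
        p = FitParameters.unpack(vec, n_metab, n_groups, params.baseline)
        cache.set_params(p)
        lp = cache.logpost()
        if not np.isfinite(lp):
            return 1e12 if lp < 0 else -1e12
        return -lp

    lo, hi = _pack_bounds(n_metab, n_groups)
    best_vec = params.pack()
    best_val = neg_logpost(best_vec)
    converged = True
    res = scipy.optimize.minimize(
        neg_logpost, best_vec, method="TNC",
        bounds=list(zip(lo, hi)),
        options={"maxfun": 1000, "xtol": 1e-12, "ftol": 1e-12})
    if np.isfinite(res.fun) and res.fun < best_val:
        best_vec = res.x
    elif not res.success:
        converged = False
    out = FitParameters.unpack(best_vec, n_metab, n_groups, params.baseline)
    out._converged = converged
    return out


# ---------------------------------------------------------------------------
# Metropolis-Hastings
# ---------------------------------------------------------------------------

def _mh_param_list(n_metab, n_groups):
    plist = [("conc", i) for i in range(n_metab)]
    for kind in ("gamma", "sigma", "eps"):
        plist += [(kind, g) for g in range(n_groups)]
    plist += [("phi0", None), ("phi1", None)]
    return plist


def _get_param(params, kind, idx):
    if kind in ("phi0", "phi1"):
        return getattr(params, kind)
    return getattr(params, kind)[idx]


def sample_mh(data_spectrum: np.ndarray, basis: BasisSet, config: FitConfig,
              init: FitParameters, axis: FrequencyAxis | None = None,
              likelihood: bool = True) -> FitResult:
    """Component-wise random-walk Metropolis-Hastings posterior sampling.

    All parameters except the baseline coefficients (fixed at ``init``) are
    sampled; proposal SDs adapt during burn-in (target 20-50% acceptance)
    and freeze afterwards.  The reported point estimate is the arithmetic
    mean of the posterior samples.  ``likelihood=False`` samples the prior
    alone (diagnostic mode).
    """
    if axis is None:
        axis = basis.axes()
    mask = axis.ppm_mask(*config.ppm_fit_range)
    data_in = (data_spectrum[mask] if len(data_spectrum) == len(axis)
               else np.asarray(data_spectrum))
    n_metab, n_groups = len(basis), int(config.groups_for(basis.names).max()) + 1
    cache = _ModelCache(data_in, basis, config, axis)
    cache.set_params(init)

    ps = config.prior_settings
    uniform = config.priors == "uniform"

    def prior_term(kind, value):
        """Per-scalar log-prior (constants omitted; they cancel in MH)."""
        if kind in ("conc",) and value < 0:
            return -np.inf
        if kind in ("gamma", "sigma") and value < 0:
            return -np.inf
        if uniform:
            return 0.0
        if kind == "conc":
            return -value ** 2 / (2 * ps.conc_sd ** 2)
        if kind in ("gamma", "sigma"):
            return (-(value - ps.broadening_center) ** 2
                    / (2 * ps.broadening_sd ** 2))
        if kind == "eps":
            return -value ** 2 / (2 * ps.eps_sd ** 2)
        if kind == "phi0":
            return -value ** 2 / (2 * ps.phi0_sd ** 2)
        return -value ** 2 / (2 * ps.phi1_sd ** 2)

    rng = np.random.default_rng(config.seed)
    plist = _mh_param_list(n_metab, n_groups)
    scales = {}
    for k, (kind, idx) in enumerate(plist):
        if kind == "conc":
            scales[k] = max(0.05 * abs(init.conc[idx]), 0.02 * max(
                init.conc.max(), 1e-3))
        elif kind in ("gamma", "sigma"):
            scales[k] = 0.5
        elif kind == "eps":
            scales[k] = 2 * np.pi * 0.2
        elif kind == "phi0":
            scales[k] = 0.02
        else:
            scales[k] = 1e-4
    accept = np.zeros(len(plist))
    tries = np.zeros(len(plist))
    pterm = np.array([prior_term(kind, _get_param(init, kind, idx))
                      for kind, idx in plist])
    if not np.all(np.isfinite(pterm)):
        raise ParameterError("initial parameters violate the prior support")
    current_ll = cache.loglik() if likelihood else 0.0
    n_total = config.mh_burn_in + config.mh_samples
    samples = np.empty((config.mh_samples, len(plist)))
    adapt_every = 50
    for it in range(n_total):
        adapting = it < config.mh_burn_in
        for k, (kind, idx) in enumerate(plist):
            old = _get_param(cache.params, kind, idx)
            prop = old + scales[k] * rng.standard_normal()
            tries[k] += 1
            new_pt = prior_term(kind, prop)
            logu = np.log(rng.random())
            if not np.isfinite(new_pt):
                continue
            cache.update(kind, idx, prop)
            new_ll = cache.loglik() if likelihood else 0.0
            if logu < (new_ll + new_pt) - (current_ll + pterm[k]):
                current_ll = new_ll
                pterm[k] = new_pt
                accept[k] += 1
            else:
                cache.update(kind, idx, old)
        if adapting and (it + 1) % adapt_every == 0:
            rate = accept / np.maximum(tries, 1)
            for k in range(len(plist)):
                if rate[k] < 0.2:
                    scales[k] *= 0.7
                elif rate[k] > 0.5:
                    scales[k] *= 1.4
            accept[:] = 0
            tries[:] = 0
        if not adapting:
            samples[it - config.mh_burn_in] = cache.params.pack()
    if tries.sum() > 0 and accept.sum() == 0:
        raise ParameterError(
            "Metropolis-Hastings accepted no moves after adaptation; "
            "review priors and proposal scales")

    mean_vec = samples.mean(axis=0)
    point = FitParameters.unpack(mean_vec, n_metab, n_groups,
                                 init.baseline.copy())
    fit_full = forward_full(point, basis, config, axis)
    residual = data_in - fit_full[mask]
    return FitResult(
        point_estimate=point, samples=samples,
        param_names=point.param_names(basis.names),
        metab_names=list(basis.names),
        fit_spectrum=fit_full, residual=residual,
        config_echo=config.to_dict(), seed=config.seed,
        basis=basis, axis=axis, config=config)


# ---------------------------------------------------------------------------
# High-level fit
# ---------------------------------------------------------------------------

def fit_spectrum(data: MRSData | np.ndarray, basis: BasisSet,
                 config: FitConfig | None = None) -> FitResult:
    """Fit one processed spectrum: Newton point estimate, then (if
    ``config.algorithm == "mh"``) Metropolis-Hastings sampling.

    Accepts reduced :class:`MRSData` or a bare complex spectrum on the basis
    axis.  With ``config.add_default_mm`` the default macromolecule peaks
    are appended to the basis (their own group) before fitting.
    """
    config = config or FitConfig()
    if isinstance(data, MRSData):
        spec = data.spectrum
        axis = data.axes()
        if data.n_timepoints != basis.n_timepoints:
            raise ParameterError("data and basis time axes differ; resample first")
    else:
        spec = np.asarray(data)
        axis = basis.axes()
    if config.add_default_mm:
        mm = default_mm_basis(basis.n_timepoints, basis.dwell_time,
                              basis.spectrometer_frequency,
                              basis.ppm_reference)
        work = basis
        for name, fid in zip(mm.names, mm.fids):
            work = work.add_entry(name, fid)
        basis = work
    init = init_newton(spec, basis, config, axis)
    if config.algorithm == "mh":
        return sample_mh(spec, basis, config, init, axis)
    mask = axis.ppm_mask(*config.ppm_fit_range)
    fit_full = forward_full(init, basis, config, axis)
    return FitResult(
        point_estimate=init, samples=np.empty((0, 0)),
        param_names=init.param_names(basis.names),
        metab_names=list(basis.names),
        fit_spectrum=fit_full, residual=spec[mask] - fit_full[mask],
        config_echo=config.to_dict(), seed=config.seed,
        converged=getattr(init, "_converged", True),
        basis=basis, axis=axis, config=config)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def zscore_statistic(mu: float, sd: float, truth: float) -> float:
    """How many posterior SDs the estimate lies from the true value:
    ``|mu - truth| / sd``."""
    if sd <= 0:
        raise ParameterError("sd must be > 0")
    return abs(mu - truth) / sd


def combine_metabolites(result: FitResult, names=None,
                        anticorrelation_threshold: float | None = None,
                        label: str | None = None) -> FitResult:
    """Add derived summed-concentration parameters to a fit result.

    Explicit rule: ``names`` lists metabolites whose samples are summed
    row-wise into a new entry.  Threshold rule: every metabolite pair whose
    posterior sample correlation is below ``anticorrelation_threshold``
    (e.g. -0.5) is combined.
    """
    if not result.has_samples and names is not None:
        # fall back to point estimates (no uncertainty available)
        idx = [result.metab_names.index(n) for n in names]
        result.combined[label or "+".join(names)] = np.atleast_1d(
            result.point_estimate.conc[idx].sum())
        return result
    if names is not None:
        idx = []
        for n in names:
            if n not in result.metab_names:
                raise ParameterError(f"unknown metabolite {n!r}")
            idx.append(result.metab_names.index(n))
        result.combined[label or "+".join(names)] = \
            result.samples[:, idx].sum(axis=1)
        return result
    if anticorrelation_threshold is None:
        raise ParameterError("give either names or anticorrelation_threshold")
    nm = len(result.metab_names)
    corr = np.corrcoef(result.samples[:, :nm], rowvar=False)
    for i in range(nm):
        for j in range(i + 1, nm):
            if corr[i, j] < anticorrelation_threshold:
                key = f"{result.metab_names[i]}+{result.metab_names[j]}"
                result.combined[key] = (result.samples[:, i]
                                        + result.samples[:, j])
    return result
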