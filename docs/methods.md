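# Methods

This note documents the models, conventions and numerical choices behind
`mrspec`, and what its synthetic-fixture tests do and do not demonstrate
about real data.

## Data model and spectral conventions

All signal arrays use the canonical layout `[x, y, z, time, coil, average]`
with singleton dimensions retained.  The forward transform (time to
frequency) is an orthonormal FFT followed by `fftshift`, so Parseval's
theorem holds exactly and the Hz axis is ascending over
`[-1/(2*dwell), +1/(2*dwell))`.  Chemical shift follows the standard proton
convention, `ppm = ppm_reference - hz / f0`, with the receiver centre
(`ppm_reference`) defaulting to water at 4.65 ppm.  A resonance at shift
`d` ppm therefore contributes `exp(2j*pi*(ppm_reference - d)*f0*t)` to the
FID; the density-matrix simulator, the analytic fixture generator and the
fitting model all share this single definition, and a cross-module test
asserts it.

NIfTI files store the native complex datatype; a real/imaginary pair
stacked on a trailing axis of length 2 is accepted as a fallback read
dialect.  The JSON sidecar requires `dwell_time` (s), `spectrometer_frequency`
(MHz) and `nucleus`; `ppm_reference`, `echo_time` and `repetition_time` are
optional and unknown keys round-trip verbatim.  The affine is stored and
propagated opaquely — no orientation mathematics is performed.

## Spectral model

The complex spectrum on the fit range (default 0.2–4.2 ppm) is modelled as

    Y(v) = B(v) + exp(i(phi0 + v*phi1)) * sum_g sum_{l in g} C_l M_l(v)
    M_l(v; gamma_g, sigma_g, eps_g) = F[ m_l(t) exp(-(gamma_g + sigma_g^2 t) t
                                                    + i eps_g t) ]

* `C_l >= 0` — metabolite amplitudes in arbitrary basis-scaled units.
* `gamma_g` (Lorentzian rate, 1/s) and `sigma_g` (Gaussian rate, 1/s)
  produce a Voigt lineshape; `eps_g` (rad/s) is a frequency shift.  Each
  metabolite belongs to exactly one group `g`; by default all metabolites
  share one group and macromolecule entries get their own, so their shift
  and broadening are optimised separately.
* `phi0` (rad) and `phi1` (rad/Hz, `v` the Hz offset from the receiver
  centre) are global zero- and first-order phases.
* `B(v)` is a complex polynomial of order N (default 2) in the Hz
  coordinate rescaled to [-1, 1] over the fit range for conditioning —
  2(N+1) real coefficients including the degree-0 term, so the baseline
  can shift uniformly.

The likelihood treats the real and imaginary parts of the in-range residual
as i.i.d. Gaussian noise and integrates the unknown noise SD out under a
Jeffreys (1/s) prior, giving the closed form
`-(N/2) log(pi*SSE) + lgamma(N/2) - log 2` with `N` real residual values.
A quadrature test verifies this constant-for-constant against direct
numerical integration.

### Priors

Concentrations get broad zero-mean half-Gaussians (SD 1e3 in basis-scaled
units; hard positivity).  `gamma` and `sigma` get Gaussians centred at 5
with SD 2.5, truncated at zero.  These constants are applied to the raw
numeric value of the 1/s decay rates — i.e. one "Hz" of prior width equals
one unit of decay rate; this is the single documented unit mapping, chosen
so the centre adds roughly 10 1/s of combined broadening on top of the
basis linewidth.  Shifts and phases get broad zero-centred Gaussians
(`eps`: SD 2*pi*20 rad/s; `phi0`: SD pi; `phi1`: SD 1e-2 rad/Hz).  All
widths are configurable and a uniform mode (flat within the positivity
bounds) can replace them.

### Optimisation

The deterministic point estimate (`init_newton`) uses variable projection:
for any value of the few nonlinear parameters (`gamma`, `sigma`, `eps`,
`phi0`, `phi1`; start 5, 5, 0, 0, 0) the concentrations and baseline
coefficients are solved exactly by bounded linear least squares (BVLS),
and the outer problem is solved by bounded trust-region least squares with
per-parameter scaling.  A bounded truncated-Newton ascent of the full log
posterior then polishes all parameters jointly, keeping the best iterate.
On noiseless fixtures this recovers all parameters to machine precision;
the acceptance threshold is 1%.

The posterior is explored by component-wise Gaussian random-walk
Metropolis–Hastings over all parameters except the baseline coefficients,
which remain fixed at their point-estimate values (removing baseline
uncertainty from the posterior — a deliberate variance/robustness
trade-off).  Proposal SDs adapt every 50 sweeps during burn-in toward a
20–50% acceptance rate and are frozen afterwards, preserving detailed
balance in the retained samples.  Defaults: 1000 burn-in sweeps, 2000
retained, thinning 1.  Bounds are enforced by prior support (reject), not
by transform, so the prior densities stay literal.  Sweeps are cheap
because the evaluator caches the per-group concentration-weighted
time-domain sum and broadening envelope: every single-parameter update
costs one FFT.  Chains are exactly reproducible from a seed; per-voxel
MRSI seeds derive deterministically from (global seed, voxel index), which
makes parallel and serial execution bit-identical.

Point estimates from the sampler are posterior means; percentage
uncertainty is reported as 100*SD/mean of the samples (for Newton-only
fits, from the inverse-Hessian proxy).  This is an uncertainty proxy, not
a literal Cramér–Rao bound.

## Density-matrix simulation

Spin systems are evolved in the full 2^N Zeeman product space with the
strong-coupling Hamiltonian `H = sum 2*pi*nu_i Iz_i + sum_{i<j} 2*pi*J_ij
I_i.I_j`, `nu_i = (shift_i - ppm_reference)*b0 + spatial_offset`.  Ideal
pulses are hard rotations of the total spin; shaped pulses are propagated
piecewise-constant over their envelope samples with the RF amplitude
calibrated so the on-resonance flip equals the nominal angle, including a
gradient Zeeman term when a slice gradient is active.  Coherence-order
filters zero matrix elements whose order (`M_col - M_row`) is not listed;
the detected pathway has order -1.  Detection is
`-2j * tr(rho(t) F^-)`, normalised so one proton after an ideal 90° yields
unit amplitude — amplitudes therefore scale with proton counts and
relative amplitudes between metabolites are preserved, which is the
invariant fitting needs.  Magnetic equivalence is handled either by
explicit spins (e.g. the lactate AX3 system) or, for mutually uncoupled
singlet groups, by weighting a representative spin (`n_equivalent`).

Spatial localisation uses the one-dimensional projection scheme: each
gradient axis is simulated over `spatial_points` offsets (default 30)
spanning the slice, with the spatial coordinate expressed as
gradient-induced frequency per unit gradient (Hz/(mT/m)); the per-axis
mean density matrices at acquisition start combine as
`rho_x + rho_y + rho_z - 2*rho_ideal` (axes without gradients contribute
the ideal result).  An "ideal localisation" mode (single propagation at
zero offset) is the default and is what the acceptance checks use; the
projection path is exercised by a crusher-selection test at desk scale
(<= a few hundred spatial points).  Relaxation during the sequence is not
modelled.  Whether a coherence filter follows every pulse is left to the
sequence description — filters are explicit events.

## Preprocessing

* **Coil combination** — whitened SVD: noise covariance from signal-free
  samples, inverse-Cholesky whitening, rank-1 SVD of the whitened
  coil-by-time matrix (from a water reference when supplied, else the
  averaged data).  The sign/phase ambiguity is fixed by making the first
  point of the combined FID real and non-negative.
* **Alignment** — time-domain spectral registration per average against the
  mean (default, two iterations) or first spectrum, restricted to a ppm
  window by spectral masking; a cross-correlation of the two FIDs
  initialises the frequency/phase before Levenberg–Marquardt refinement,
  which keeps recovery exact for drifts of tens of Hz.
* **HLSVD removal** — Hankel SVD (window T/2), shift-invariance solve for
  the poles, linear amplitudes; components whose frequency lies in the ppm
  band (default 20 singular values) are subtracted.  An empty band is the
  identity.
* **Eddy-current correction** — Klose: subtract the water reference's
  pointwise phase; data magnitude is untouched; zero reference samples get
  interpolated phase with a warning.
* **Outlier rejection** — leave-one-out RMS of the windowed real spectrum;
  drop scores above mean + k*SD (k default 3), iterated once.
* **Shape operations** — exponential / Lorentz-to-Gauss apodisation,
  truncate/zero-pad, Fourier time shift (the resampling kernel is a
  documented dialect choice), frequency shift, zero-order phase by the
  largest peak in range, add/subtract.

## Quantification and QC

Water-referenced scaling follows the compartment (Gasparovic-style) form:
the reference metabolite's fitted, broadened basis spectrum is integrated
(real part, zero-order phased) over the reference range — creatine over
2–5 ppm by default — and ratioed against the integral of the phased
unsuppressed water spectrum.  Absolute molar (mol/dm^3) and molal (mol/kg)
concentrations apply the water concentration (55.51 mol/dm^3 pure water),
the proton-count ratio of water to reference, `exp(-TE/T2)` relaxation
ratios and tissue-water visibility terms; the default `QuantSpec` assumes
a pure-water voxel (phantom setting; also the fallback when segmentation
is unavailable).  Relaxation and density constants ship as an editable
JSON config of literature-style defaults per field strength — fixture
values, not measurements.  Every multiplicative factor is logged in the
output table.  Before integration the first FID point is halved — the
standard correction that removes the flat spectral offset a plain DFT of a
causal signal spreads across all bins, without which windowed integrals
are biased by tens of percent.  The water integration range defaults to
the full spectrum and is configurable.  Whether the reference integral
uses the broadened (fitted) or raw basis is a dialect choice; the fitted
spectrum is used here.

QC per metabolite: FWHM of the tallest peak of the fitted basis spectrum
by interpolated half-height crossings; SNR as that peak's height over the
SD of the real spectrum in a signal-free noise region, after applying a
time-domain exponential matched filter `exp(-pi*FWHM*t)` to both.

## Synthetic fixtures and what the tests show

The generator panel is five well-separated resonances (NAA, Cr with two
singlets, Glu, mI, a Lac doublet) plus an overlapping choline pair
(Cho/GPC, 0.027 ppm apart) and optionally six Gaussian macromolecule
singlets at 0.9–3.0 ppm.  Default acquisition: 1024 points, 2 kHz
bandwidth, 123.2 MHz.  Typical brain-like amplitudes (NAA 15, Cr 8, ...)
are arbitrary basis-scaled units.  Noise is complex white Gaussian added
in the frequency domain (equivalent, under the orthonormal FFT, to white
time-domain noise of the same SD), giving exact spectral-SNR control; the
"moderate SNR" level (noise SD 5) puts the tallest peak near SNR 30,
typical of short-TE in vivo spectra.

The posterior-calibration study uses the self-consistent Bayesian design:
concentrations jitter ±20% around the panel defaults and the nuisance
truth (broadening, small shift and phase) is drawn from the fitting
priors, under which nominal credible-interval coverage is exact in
expectation.  Coverage is scored for the well-separated metabolites over
100 seeded datasets (60 in the faster acceptance script), with an
acceptance floor of 0.80 against the nominal 0.90 to absorb binomial and
chain-autocorrelation noise.

What passing these tests does **not** show: robustness to realistic
lineshape distortions (eddy currents beyond the modelled phase, B0
inhomogeneity), measured macromolecule baselines, vendor raw-data quirks,
or fitting bias when the true broadening sits far from the prior centre —
with fixed truth broadening well above the prior centre the intervals
undercover, which is the expected behaviour of informative priors, not a
sampler defect.

## Known limitations

* No spline baseline; the polynomial baseline is deliberately rigid.
* No concentration-ratio (soft-constraint) priors between metabolites.
* Baseline coefficients carry no posterior uncertainty (fixed after the
  point estimate).
* Simulator: no relaxation, no frequency-selective water suppression, no
  full 3D grid simulation.
* Quantification assumes the supplied tissue fractions and relaxation
  constants; no segmentation or T1-saturation correction is performed.
* Orientation handling stores and propagates the affine only.
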