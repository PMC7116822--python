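"""Density-matrix simulation of metabolite responses to pulse sequences.

Spin systems (chemical shifts, scalar couplings, multiplicities) are evolved
through a sequence of RF pulses, delays and coherence-order filters to
produce basis spectra for linear-combination fitting.

Conventions
-----------
* The rotating-frame Hamiltonian is ``H = sum_i 2*pi*nu_i*Iz_i +
  sum_{i<j} 2*pi*J_ij * I_i . I_j`` (full strong-coupling form, rad/s) with
  ``nu_i = (shift_i - ppm_reference) * b0 + spatial_offset``.
* Detection is ``FID[k] = -2j * trace(rho(t_k) * F-)`` with ``F- = sum I-_i``;
  the ``-2j`` normalisation makes an ideal 90-acquire experiment on one
  proton yield amplitude 1, so amplitudes scale with proton counts.  With
  the Hamiltonian above a spin at shift d appears at d ppm on the package
  frequency axis.
* Coherence order of a matrix element ``|r><c|`` is ``M_c - M_r`` (sum of
  magnetic quantum numbers); the detected pathway has order -1.
* The spatial coordinate of a one-dimensional projection simulation is the
  gradient-induced frequency offset per unit gradient, in Hz/(mT/m); a
  rephasing gradient area of A mT.ms/m applies a z-rotation of
  ``2*pi * A*1e-3 * x`` radians at coordinate ``x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .core import BasisSet, FormatError, NumericalError, ParameterError

__all__ = [
    "SpinSystem", "SequenceDescription", "RFPulse", "Delay", "CoherenceFilter",
    "Acquisition", "DensityState", "hamiltonian", "propagate",
    "coherence_filter", "acquire", "simulate_basis", "simulate_system",
    "spin_operators", "equilibrium_state", "SPIN_SYSTEM_LIBRARY",
    "load_spin_systems", "pulse_acquire_sequence", "steam_sequence",
]


# ---------------------------------------------------------------------------
# Spin systems
# ---------------------------------------------------------------------------

@dataclass
class SpinSystem:
    """A (possibly coupled) proton spin system.

    ``shifts`` are chemical shifts in ppm per simulated spin; ``j_matrix``
    holds scalar couplings in Hz (symmetric, zero diagonal);
    ``n_equivalent`` weights each simulated spin by the number of magnetically
    equivalent protons it represents (valid for mutually uncoupled groups).
    """

    name: str
    shifts: np.ndarray
    j_matrix: np.ndarray | None = None
    n_equivalent: np.ndarray | None = None

    def __post_init__(self):
        self.shifts = np.atleast_1d(np.asarray(self.shifts, dtype=float))
        n = len(self.shifts)
        if self.j_matrix is None:
            self.j_matrix = np.zeros((n, n))
        self.j_matrix = np.asarray(self.j_matrix, dtype=float)
        if self.j_matrix.shape != (n, n):
            raise ParameterError("j_matrix shape does not match number of spins")
        if not np.allclose(self.j_matrix, self.j_matrix.T):
            raise ParameterError("j_matrix must be symmetric")
        if np.any(np.diag(self.j_matrix) != 0):
            raise ParameterError("j_matrix diagonal must be zero")
        if self.n_equivalent is None:
            self.n_equivalent = np.ones(n)
        self.n_equivalent = np.atleast_1d(np.asarray(self.n_equivalent,
                                                     dtype=float))
        if len(self.n_equivalent) != n or np.any(self.n_equivalent < 1):
            raise ParameterError("n_equivalent must be >= 1 per spin")

    @property
    def n_spins(self) -> int:
        return len(self.shifts)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins


#: Curated literature-style spin systems for common metabolites (editable
#: fixture values; singlet groups are represented by uncoupled weighted spins).
SPIN_SYSTEM_LIBRARY = {
    "NAA": SpinSystem("NAA", shifts=[2.008], n_equivalent=[3]),
    "Cr": SpinSystem("Cr", shifts=[3.027, 3.913], n_equivalent=[3, 2]),
    "Cho": SpinSystem("Cho", shifts=[3.185], n_equivalent=[9]),
    "Lac": SpinSystem(
        "Lac",
        shifts=[4.097, 1.313, 1.313, 1.313],
        j_matrix=[[0, 6.933, 6.933, 6.933],
                  [6.933, 0, 0, 0],
                  [6.933, 0, 0, 0],
                  [6.933, 0, 0, 0]],
    ),
    "Glu": SpinSystem(
        "Glu",
        shifts=[2.348, 2.120],
        j_matrix=[[0, 8.5], [8.5, 0]],
    ),
}


def load_spin_systems(path) -> dict:
    """Load spin systems from a JSON file ``{name: {shifts, j_matrix, n_equivalent}}``."""
    raw = json.loads(Path(path).read_text())
    out = {}
    for name, d in raw.items():
        out[name] = SpinSystem(name, shifts=d["shifts"],
                               j_matrix=d.get("j_matrix"),
                               n_equivalent=d.get("n_equivalent"))
    return out


# ---------------------------------------------------------------------------
# Spin operators
# ---------------------------------------------------------------------------

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
_SM = np.array([[0, 0], [1, 0]], dtype=complex)  # I-


def _kron_chain(ops):
    out = ops[0]
    for op in ops[1:]:
        out = np.kron(out, op)
    return out


def spin_operators(n_spins: int) -> dict:
    """Single-spin operators embedded in the 2**n product space.

    Returns ``{"x": [Ix_1..], "y": ..., "z": ..., "m": [Iminus_1..]}``.
    """
    eye = np.eye(2, dtype=complex)
    ops = {"x": [], "y": [], "z": [], "m": []}
    for i in range(n_spins):
        for key, s in (("x", _SX), ("y", _SY), ("z", _SZ), ("m", _SM)):
            chain = [eye] * n_spins
            chain[i] = s
            ops[key].append(_kron_chain(chain))
    return ops


def _magnetic_quantum_numbers(n_spins: int) -> np.ndarray:
    """Total Mz of each Zeeman product state (bit 0 set = spin down)."""
    states = np.arange(2 ** n_spins)
    m = np.zeros(len(states))
    for i in range(n_spins):
        up = (states >> (n_spins - 1 - i)) & 1 == 0
        m += np.where(up, 0.5, -0.5)
    return m


# ---------------------------------------------------------------------------
# States and Hamiltonian
# ---------------------------------------------------------------------------

@dataclass
class DensityState:
    """A density matrix in the Zeeman product basis plus its spatial offset."""

    rho: np.ndarray
    spatial_offset: float = 0.0  # Hz (gradient-induced at this position)

    @property
    def n_spins(self) -> int:
        return int(np.log2(self.rho.shape[0]))


def equilibrium_state(system: SpinSystem, spatial_offset: float = 0.0) -> DensityState:
    """Thermal equilibrium ``rho = sum_i n_equivalent_i * Iz_i``."""
    ops = spin_operators(system.n_spins)
    rho = sum(w * opz for w, opz in zip(system.n_equivalent, ops["z"]))
    return DensityState(rho=np.asarray(rho, dtype=complex),
                        spatial_offset=spatial_offset)


def hamiltonian(system: SpinSystem, b0_frequency: float,
                spatial_offset_hz: float = 0.0,
                ppm_reference: float = 0.0) -> np.ndarray:
    """Strong-coupling rotating-frame Hamiltonian in rad/s.

    ``H = sum 2*pi*((shift_i - ppm_reference)*b0 + offset)*Iz_i
    + sum_{i<j} 2*pi*J_ij*(IxIx + IyIy + IzIz)``; Hermitian.
    """
    ops = spin_operators(system.n_spins)
    n = system.n_spins
    H = np.zeros((system.dim, system.dim), dtype=complex)
    for i in range(n):
        nu = (system.shifts[i] - ppm_reference) * b0_frequency + spatial_offset_hz
        H += 2 * np.pi * nu * ops["z"][i]
    for i in range(n):
        for j in range(i + 1, n):
            if system.j_matrix[i, j] != 0:
                H += 2 * np.pi * system.j_matrix[i, j] * (
                    ops["x"][i] @ ops["x"][j]
                    + ops["y"][i] @ ops["y"][j]
                    + ops["z"][i] @ ops["z"][j])
    return H


# ---------------------------------------------------------------------------
# Sequence events
# ---------------------------------------------------------------------------

@dataclass
class RFPulse:
    """An RF pulse: ideal (instantaneous) if ``shape`` is None, else shaped.

    ``shape`` holds complex envelope samples (arbitrary scale; the overall
    amplitude is calibrated so the on-resonance flip equals ``flip``),
    ``duration`` the pulse length in seconds, ``phase`` the RF phase in
    degrees, ``grad`` a slice-selection gradient in mT/m active during the
    pulse on ``grad_axis``.
    """

    flip: float                 # degrees
    phase: float = 0.0          # degrees
    shape: np.ndarray | None = None
    duration: float = 0.0       # s
    grad: float = 0.0           # mT/m
    grad_axis: str | None = None

    kind = "rf_pulse"


@dataclass
class Delay:
    """Free evolution for ``duration`` seconds with an optional rephasing
    gradient area (mT.ms/m) applied as an instantaneous z-rotation."""

    duration: float
    rephase_area: float = 0.0
    grad_axis: str | None = None

    kind = "delay"


@dataclass
class CoherenceFilter:
    """Keep only matrix elements whose coherence order is listed."""

    keep_orders: tuple

    kind = "filter"


@dataclass
class Acquisition:
    points: int
    bandwidth: float            # Hz
    receiver_phase: float = 0.0  # degrees


@dataclass
class SequenceDescription:
    """Ordered event list plus acquisition settings for one sequence."""

    events: list
    acquisition: Acquisition
    name: str = "sequence"
    spatial_extent: float = 1.0  # half-width of slice in Hz/(mT/m) coordinate

    def __post_init__(self):
        for ev in self.events:
            if getattr(ev, "duration", 0.0) < 0:
                raise ParameterError("event durations must be >= 0")
            if ev.kind == "filter":
                if not all(float(o).is_integer() for o in ev.keep_orders):
                    raise ParameterError("coherence orders must be integers")

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        evs = []
        for ev in self.events:
            if ev.kind == "rf_pulse":
                evs.append({
                    "rf_pulse": {
                        "flip": ev.flip, "phase": ev.phase,
                        "duration": ev.duration, "grad": ev.grad,
                        "grad_axis": ev.grad_axis,
                        "shape": (None if ev.shape is None else
                                  [[float(c.real), float(c.imag)]
                                   for c in np.asarray(ev.shape, dtype=complex)]),
                    }})
            elif ev.kind == "delay":
                evs.append({"delay": {"duration": ev.duration,
                                      "rephase_area": ev.rephase_area,
                                      "grad_axis": ev.grad_axis}})
            elif ev.kind == "filter":
                evs.append({"filter": {"keep_orders": list(ev.keep_orders)}})
        return json.dumps({
            "name": self.name,
            "spatial_extent": self.spatial_extent,
            "events": evs,
            "acquisition": {"points": self.acquisition.points,
                            "bandwidth": self.acquisition.bandwidth,
                            "receiver_phase": self.acquisition.receiver_phase},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SequenceDescription":
        d = json.loads(text)
        if "acquisition" not in d:
            raise FormatError("sequence description lacks an acquisition block")
        events = []
        for ev in d.get("events", []):
            (key, body), = ev.items()
            if key == "rf_pulse":
                shape = body.get("shape")
                if shape is not None:
                    shape = np.array([complex(re, im) for re, im in shape])
                events.append(RFPulse(flip=body["flip"],
                                      phase=body.get("phase", 0.0),
                                      shape=shape,
                                      duration=body.get("duration", 0.0),
                                      grad=body.get("grad", 0.0),
                                      grad_axis=body.get("grad_axis")))
            elif key == "delay":
                events.append(Delay(duration=body["duration"],
                                    rephase_area=body.get("rephase_area", 0.0),
                                    grad_axis=body.get("grad_axis")))
            elif key == "filter":
                events.append(CoherenceFilter(tuple(body["keep_orders"])))
            else:
                raise FormatError(f"unknown sequence event {key!r}")
        acq = d["acquisition"]
        return cls(events=events,
                   acquisition=Acquisition(points=acq["points"],
                                           bandwidth=acq["bandwidth"],
                                           receiver_phase=acq.get(
                                               "receiver_phase", 0.0)),
                   name=d.get("name", "sequence"),
                   spatial_extent=d.get("spatial_extent", 1.0))


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _check_unitary(u: np.ndarray):
    err = np.linalg.norm(u.conj().T @ u - np.eye(len(u)))
    if err > 1e-8:
        raise NumericalError(f"non-unitary propagator (deviation {err:.2e})")


def _total_ops(n_spins):
    ops = spin_operators(n_spins)
    return (sum(ops["x"]), sum(ops["y"]), sum(ops["z"]))


def propagate(state: DensityState, event, H: np.ndarray,
              axis: str | None = None) -> DensityState:
    """Apply one sequence event to ``state`` under free Hamiltonian ``H``.

    ``axis`` names the gradient axis currently being simulated; gradient
    terms of events on other axes are ignored (their pulses act as ideal /
    their rephasers as no-ops).
    """
    n = state.n_spins
    if event.kind == "filter":
        return coherence_filter(state, event.keep_orders)
    if event.kind == "delay":
        rho = state.rho
        if event.duration > 0:
            u = scipy.linalg.expm(-1j * H * event.duration)
            _check_unitary(u)
            rho = u @ rho @ u.conj().T
        if event.rephase_area != 0 and axis is not None \
                and event.grad_axis == axis and state.spatial_offset != 0:
            fz = _total_ops(n)[2]
            phi = 2 * np.pi * event.rephase_area * 1e-3 * state.spatial_offset
            u = scipy.linalg.expm(-1j * phi * fz)
            rho = u @ rho @ u.conj().T
        return DensityState(rho, state.spatial_offset)
    if event.kind == "rf_pulse":
        fx, fy, fz = _total_ops(n)
        phase = np.deg2rad(event.phase)
        flip = np.deg2rad(event.flip)
        if event.shape is None or event.duration == 0:
            u = scipy.linalg.expm(
                -1j * flip * (fx * np.cos(phase) + fy * np.sin(phase)))
            _check_unitary(u)
            return DensityState(u @ state.rho @ u.conj().T,
                                state.spatial_offset)
        env = np.asarray(event.shape, dtype=complex)
        dt = event.duration / len(env)
        total = np.sum(np.abs(env)) * dt
        if total == 0:
            raise ParameterError("shaped pulse has zero integral")
        w1_scale = flip / total
        grad_on = (axis is not None and event.grad_axis == axis
                   and event.grad != 0)
        offset = state.spatial_offset * event.grad if grad_on else 0.0
        rho = state.rho
        u_total = np.eye(2 ** n, dtype=complex)
        for c in env:
            w1 = w1_scale * np.abs(c)
            ph = phase + np.angle(c)
            h_step = H + 2 * np.pi * offset * fz \
                + w1 * (fx * np.cos(ph) + fy * np.sin(ph))
            u_total = scipy.linalg.expm(-1j * h_step * dt) @ u_total
        _check_unitary(u_total)
        return DensityState(u_total @ rho @ u_total.conj().T,
                            state.spatial_offset)
    raise ParameterError(f"unknown event kind {event.kind!r}")


def coherence_filter(state: DensityState, keep_orders) -> DensityState:
    """Zero all matrix elements whose coherence order is not kept (idempotent)."""
    n = state.n_spins
    m = _magnetic_quantum_numbers(n)
    order = np.round(m[np.newaxis, :] - m[:, np.newaxis]).astype(int)
    keep = np.isin(order, np.asarray(list(keep_orders), dtype=int))
    return DensityState(np.where(keep, state.rho, 0.0), state.spatial_offset)


def acquire(state: DensityState, points: int, bandwidth: float,
            H: np.ndarray, system: SpinSystem | None = None,
            receiver_phase: float = 0.0) -> np.ndarray:
    """Detect ``FID[k] = -2j * trace(rho(t_k) F-)`` sampled at ``bandwidth``.

    The density matrix evolves freely under ``H`` between samples.
    """
    n = state.n_spins
    ops = spin_operators(n)
    fminus = sum(ops["m"])
    dwell = 1.0 / bandwidth
    u = scipy.linalg.expm(-1j * H * dwell)
    _check_unitary(u)
    rho = state.rho.copy()
    fid = np.empty(points, dtype=complex)
    for k in range(points):
        fid[k] = np.trace(rho @ fminus)
        rho = u @ rho @ u.conj().T
    return -2j * fid * np.exp(1j * np.deg2rad(receiver_phase))


# ---------------------------------------------------------------------------
# Full simulations
# ---------------------------------------------------------------------------

def _run_events(system: SpinSystem, seq: SequenceDescription,
                b0_frequency: float, ppm_reference: float,
                spatial_offset: float, axis: str | None) -> DensityState:
    H = hamiltonian(system, b0_frequency, 0.0, ppm_reference)
    state = equilibrium_state(system, spatial_offset)
    for ev in seq.events:
        state = propagate(state, ev, H, axis=axis)
    return state


def simulate_system(system: SpinSystem, seq: SequenceDescription,
                    b0_frequency: float, ppm_reference: float = 4.65,
                    spatial_points: int = 1,
                    mode: str = "ideal") -> np.ndarray:
    """Simulate one metabolite's FID for a sequence.

    ``mode="ideal"`` ignores spatial localisation (single propagation at
    zero offset).  ``mode="projection"`` runs the extended one-dimensional
    projection: each gradient axis is simulated over ``spatial_points``
    offsets spanning the slice and the per-axis mean density matrices at
    acquisition start are combined as ``rho_x + rho_y + rho_z - 2*rho_ideal``
    (axes without gradients contribute their ideal result).
    """
    if seq.acquisition is None:
        raise FormatError("sequence has no acquisition")
    acq = seq.acquisition
    H0 = hamiltonian(system, b0_frequency, 0.0, ppm_reference)
    ideal = _run_events(system, seq, b0_frequency, ppm_reference, 0.0, None)
    axes_used = sorted({ev.grad_axis for ev in seq.events
                        if getattr(ev, "grad_axis", None) is not None
                        and (getattr(ev, "grad", 0.0) != 0
                             or getattr(ev, "rephase_area", 0.0) != 0)})
    if mode == "ideal" or spatial_points <= 1 or not axes_used:
        rho = ideal.rho
    elif mode == "projection":
        offsets = np.linspace(-seq.spatial_extent, seq.spatial_extent,
                              spatial_points)
        rho = -2.0 * ideal.rho + (3 - len(axes_used)) * ideal.rho
        for ax in axes_used:
            acc = np.zeros_like(ideal.rho)
            for off in offsets:
                st = _run_events(system, seq, b0_frequency, ppm_reference,
                                 off, ax)
                acc += st.rho
            rho = rho + acc / spatial_points
    else:
        raise ParameterError(f"unknown simulation mode {mode!r}")
    state = DensityState(rho, 0.0)
    return acquire(state, acq.points, acq.bandwidth, H0,
                   receiver_phase=acq.receiver_phase)


def simulate_basis(systems, seq: SequenceDescription, b0_frequency: float,
                   ppm_reference: float = 4.65, spatial_points: int = 30,
                   mode: str = "ideal") -> BasisSet:
    """Simulate a basis set (shared time axis, consistent relative scale).

    ``systems`` is a mapping name -> :class:`SpinSystem` or an iterable of
    spin systems.  The common amplitude scale is one unit per proton, so
    relative amplitudes between metabolites are meaningful.
    """
    if isinstance(systems, dict):
        items = list(systems.values())
    else:
        items = list(systems)
    names, fids = [], []
    for system in items:
        names.append(system.name)
        fids.append(simulate_system(system, seq, b0_frequency, ppm_reference,
                                    spatial_points=spatial_points, mode=mode))
    dwell = 1.0 / seq.acquisition.bandwidth
    return BasisSet(names, np.array(fids), dwell, b0_frequency, ppm_reference,
                    scaling_note="density-matrix simulation; one unit per proton")


# ---------------------------------------------------------------------------
# Sequence skeletons
# ---------------------------------------------------------------------------

def pulse_acquire_sequence(points: int, bandwidth: float) -> SequenceDescription:
    """Ideal 90x - acquire."""
    return SequenceDescription(
        events=[RFPulse(flip=90.0), CoherenceFilter((-1,))],
        acquisition=Acquisition(points=points, bandwidth=bandwidth),
        name="pulse-acquire")


def steam_sequence(points: int, bandwidth: float, te: float = 0.011,
                   tm: float = 0.032) -> SequenceDescription:
    """Ideal-pulse STEAM skeleton with the canonical coherence pathway.

    90x - (TE/2, keep order -1) - 90x - (TM, keep order 0) - 90x -
    (TE/2, keep order -1) - acquire.  The stimulated-echo pathway retains
    half the pulse-acquire amplitude.
    """
    return SequenceDescription(
        events=[
            RFPulse(flip=90.0),
            CoherenceFilter((-1,)),
            Delay(duration=te / 2),
            RFPulse(flip=90.0),
            CoherenceFilter((0,)),
            Delay(duration=tm),
            RFPulse(flip=90.0),
            CoherenceFilter((-1,)),
            Delay(duration=te / 2),
        ],
        acquisition=Acquisition(points=points, bandwidth=bandwidth),
        name="steam")
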