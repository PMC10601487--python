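"""Semiclassical nonadiabatic ensemble dynamics on MSH/MRC/Frenkel models.

Methods
-------
* Ehrenfest mean field (``mf``): electronic amplitudes evolve under the
  instantaneous diabatic Hamiltonian (diagonal V_X(R), constant off-diagonal
  couplings Gamma); nuclei feel the density-weighted mean force. Under the
  Condon approximation the coherence contribution to the force vanishes
  because the couplings carry no gradient.
* Symmetrical quasi-classical with triangle windows (``sqc``):
  Meyer-Miller mapping variables with triangle-window initial sampling and
  binning (zero-point parameter gamma, default 1/3); populations are window
  counts with ensemble renormalization.

Integrators: velocity-Verlet for the nuclei, fourth-order Runge-Kutta for
the electronic variables with ``substeps`` updates per nuclear step and the
diagonal of the Hamiltonian interpolated linearly across the step.

Initial nuclear conditions are Wigner samples of a harmonic reference
(Gaussian, position variance coth(beta*omega/2)/(2*omega), momentum variance
(omega/2)*coth(beta*omega/2) per mode). Sampling is always performed in the
normal-mode basis; for an MRC target the sample is mapped through the
orthogonal basis matrix, which keeps paired MSH/MRC trajectories
bit-consistent.

Randomness: trajectory k draws from ``numpy.random.default_rng([seed, k])``,
so any trajectory is reproducible independently of the ensemble size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import EstimatorDegenerateError, InvalidInputError
from .mrc import MRCModel, coords_mrc_to_msh, coords_msh_to_mrc, mrc_to_msh
from .msh import FrenkelModel, MSHModel
from .units import FS_TO_AU_TIME, beta_from_temperature

__all__ = [
    "SimConfig",
    "PhaseSpaceState",
    "PopulationTrace",
    "EquivalenceReport",
    "sample_wigner",
    "ehrenfest_propagate",
    "sqc_propagate",
    "propagate",
    "equivalence_report",
    "rc_trajectory_average",
    "matching_digits",
]


@dataclass(frozen=True)
class SimConfig:
    """Propagation settings.

    ``init_nuclear`` is a state index (Wigner sample around that state's PES
    minimum), a length-(F-1) vector of reaction-coordinate components (bath
    relaxed at that y; MRC models only), or a full explicit center array.
    """

    method: str = "mf"
    dt_fs: float = 0.1
    substeps: int = 20
    n_traj: int = 1
    seed: int = 0
    temperature: float = 300.0
    t_final_fs: float = 1000.0
    init_electronic: int = 0
    init_nuclear: object = None  # default: same as init_electronic
    zpe_gamma: float = 1.0 / 3.0
    output_stride: int = 1
    energy_drift_tol: float = 1e-3  # hartree; exceeding it warns, not fatal

    def __post_init__(self):
        if self.method not in ("mf", "sqc"):
            raise InvalidInputError(f"unknown method: {self.method!r}")
        if self.dt_fs <= 0 or self.substeps < 1 or self.n_traj < 1:
            raise InvalidInputError("dt > 0, substeps >= 1, n_traj >= 1 required")
        if self.output_stride < 1:
            raise InvalidInputError("output_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final_fs / self.dt_fs))


@dataclass(frozen=True)
class PhaseSpaceState:
    """Mass-weighted phase-space point tagged with its basis."""

    positions: np.ndarray
    momenta: np.ndarray
    basis: str  # "normal_mode" | "primary_secondary"

    def __post_init__(self):
        if self.basis not in ("normal_mode", "primary_secondary"):
            raise InvalidInputError(f"unknown basis tag: {self.basis!r}")
        if np.shape(self.positions) != np.shape(self.momenta):
            raise InvalidInputError("positions and momenta must have matching shapes")


@dataclass
class PopulationTrace:
    """Time series of electronic observables and averaged RC components."""

    times: np.ndarray  # fs
    sigma: np.ndarray  # (T, F, F) complex; diagonal = populations
    rc_mean: np.ndarray | None = None  # (T, F-1) mean y_i(t); MRC runs only
    energy: np.ndarray | None = None  # (T,) ensemble-mean total energy (a.u.)
    max_energy_drift: float = 0.0
    n_traj: int = 1

    @property
    def populations(self) -> np.ndarray:
        return self.sigma.diagonal(axis1=1, axis2=2).real


def _model_basis(model) -> str:
    return "primary_secondary" if isinstance(model, MRCModel) else "normal_mode"


def _nm_model(model):
    """Normal-mode twin used for Wigner sampling (identity for MSH/Frenkel)."""
    return mrc_to_msh(model) if isinstance(model, MRCModel) else model


def _resolve_center(model, center) -> np.ndarray:
    """Normal-mode-basis center for Wigner sampling."""
    if center is None:
        center = 0
    if np.ndim(center) == 0:
        X = int(center)
        if not (0 <= X < model.electronic.f_states):
            raise InvalidInputError(f"unknown center state index {X}")
        return _nm_model(model).state_minimum(X)
    arr = np.asarray(center, dtype=float)
    if isinstance(model, MRCModel):
        if arr.shape == (model.subspaces,):
            w = np.zeros(model.nuclear_shape)
            w[:, 0] = arr
            w[:, 1:] = -np.outer(arr, model.bath_couplings / model.bath_omegas**2)
            return coords_mrc_to_msh(model, w)
        if arr.shape == model.nuclear_shape:
            return coords_mrc_to_msh(model, arr)
        raise InvalidInputError("explicit center shape does not match the model")
    if arr.shape != model.nuclear_shape:
        raise InvalidInputError("explicit center shape does not match the model")
    return arr


def _wigner_draw(rng, omegas, center_R, beta):
    coth = 1.0 / np.tanh(0.5 * beta * omegas)
    sig_R = np.sqrt(coth / (2.0 * omegas))
    sig_P = np.sqrt(0.5 * omegas * coth)
    R = center_R + sig_R * rng.standard_normal(omegas.shape)
    P = sig_P * rng.standard_normal(omegas.shape)
    return R, P


def sample_wigner(model, center, temperature: float, n: int, seed: int):
    """Draw n independent Wigner phase-space samples of the harmonic
    reference, centered at a state's PES minimum or an explicit center.

    Samples are drawn in the normal-mode basis and mapped to the
    primary/secondary basis when the target model is MRC. Trajectory k uses
    its own stream ``default_rng([seed, k])``.
    """
    beta = beta_from_temperature(temperature)
    nm = _nm_model(model)
    omegas = nm.mode_frequencies()
    center_R = _resolve_center(model, center)
    out = []
    for k in range(n):
        rng = np.random.default_rng([seed, k])
        R, P = _wigner_draw(rng, omegas, center_R, beta)
        if isinstance(model, MRCModel):
            out.append(
                PhaseSpaceState(
                    coords_msh_to_mrc(model, R),
                    coords_msh_to_mrc(model, P),
                    "primary_secondary",
                )
            )
        else:
            out.append(PhaseSpaceState(R, P, "normal_mode"))
    return out


def _sample_sqc_mapping(rng, F: int, m: int, gamma: float) -> np.ndarray:
    """Triangle-window initial mapping variables for occupied state m:
    actions uniform over {n_m in (1,2), n_j in (0,1), n_m + n_j < 2}."""
    while True:
        n = rng.uniform(0.0, 1.0, size=F)
        n[m] += 1.0
        if np.all(n[np.arange(F) != m] < 2.0 - n[m]):
            break
    theta = rng.uniform(0.0, 2.0 * np.pi, size=F)
    return np.sqrt(n + gamma) * np.exp(-1j * theta)


def _sqc_window_counts(pops: np.ndarray, gamma: float) -> np.ndarray:
    """Triangle-window indicator per state for each trajectory.

    ``pops`` is |c|^2 = n + gamma, shape (B, F). Returns (B, F) 0/1 floats.
    """
    n = pops - gamma
    B, F = n.shape
    out = np.zeros((B, F))
    jmax = np.argmax(n, axis=1)
    nmax = n[np.arange(B), jmax]
    others_ok = np.ones(B, dtype=bool)
    for j in range(F):
        col = n[:, j]
        sel = jmax != j
        others_ok &= ~sel | ((col > 0.0) & (col < 1.0) & (nmax + col < 2.0))
    hit = (nmax > 1.0) & (nmax < 2.0) & others_ok
    out[np.arange(B)[hit], jmax[hit]] = 1.0
    return out


def _batch_msh_quantities(model):
    """Precompute state-independent pieces for batched evaluation."""
    if isinstance(model, MSHModel):
        w2 = model.bath.omegas**2
        shifts = model.shifts  # (F, F-1, N)
        shift_w = w2 * shifts
        const = 0.5 * np.einsum("xij,xij->x", shift_w, shifts)
        return w2, shifts, shift_w, const
    if isinstance(model, FrenkelModel):
        w2 = model._omega2()
        F = model.f_states
        shifts = np.zeros((F,) + model.nuclear_shape)
        for X in range(F):
            shifts[X] = model._shift(X)
        shift_w = w2 * shifts
        const = 0.5 * np.einsum("xij,xij->x", shift_w, shifts)
        return w2, shifts, shift_w, const
    raise InvalidInputError("unsupported model type for batched evaluation")


class _Propagator:
    """Batched evaluator for one model; dispatches on model type."""

    def __init__(self, model):
        self.model = model
        self.is_mrc = isinstance(model, MRCModel)
        self.eps = model.electronic.epsilons
        self.gam = model.electronic.gammas
        if self.is_mrc:
            self.Om2 = model.omega_rc**2
            self.wa2 = model.bath_omegas**2
            self.ca = model.bath_couplings
            self.ca_over_wa2 = self.ca / self.wa2
            self.S = model.primary_shifts  # (F, F-1)
            self.S_const = 0.5 * self.Om2 * np.sum(self.S**2, axis=1)
        else:
            self.w2, self.shifts, self.shift_w, self.shift_const = _batch_msh_quantities(model)

    def potentials(self, R: np.ndarray) -> np.ndarray:
        """(B, F) diabatic potentials."""
        if self.is_mrc:
            y = R[:, :, 0]
            x = R[:, :, 1:]
            bath_disp = x + y[:, :, None] * self.ca_over_wa2
            bath_V = 0.5 * np.einsum("a,bia,bia->b", self.wa2, bath_disp, bath_disp)
            base = 0.5 * self.Om2 * np.sum(y * y, axis=1) + bath_V
            cross = self.Om2 * (y @ self.S.T)
            return self.eps + base[:, None] + cross + self.S_const
        base = 0.5 * np.einsum("bij,ij->b", R * R, np.broadcast_to(self.w2, R.shape[1:]))
        cross = np.einsum("bij,xij->bx", R, self.shift_w)
        return self.eps + base[:, None] + cross + self.shift_const

    def mean_force(self, R: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """- sum_X w_X grad V_X, batched; weights shape (B, F)."""
        sw = weights.sum(axis=1)
        if self.is_mrc:
            y = R[:, :, 0]
            x = R[:, :, 1:]
            bath_disp = x + y[:, :, None] * self.ca_over_wa2
            out = np.empty_like(R)
            out[:, :, 0] = -(
                self.Om2 * (sw[:, None] * y + weights @ self.S)
                + sw[:, None] * (bath_disp @ self.ca)
            )
            out[:, :, 1:] = -sw[:, None, None] * (self.wa2 * bath_disp)
            return out
        Sbar = np.einsum("bx,xij->bij", weights, self.shifts)
        return -self.w2 * (sw[:, None, None] * R + Sbar)


def _rk4_electronic(c, V0, V1, gam, dt, substeps):
    """RK4 for i dc/dt = H(t) c with H = diag(V) + Gamma, V interpolated
    linearly from V0 to V1 across the nuclear step.

    The state-averaged potential is subtracted before propagating: it only
    contributes a global phase (populations, coherences, and forces are
    invariant) but dominates the stiffness, so removing it sharply reduces
    the integrator's phase and norm error.
    """
    shift = 0.5 * (V0 + V1).mean(axis=-1, keepdims=True)
    V0 = V0 - shift
    V1 = V1 - shift
    h = dt / substeps
    dV = V1 - V0

    def deriv(cc, Vs):
        return -1j * (cc @ gam.T + Vs * cc)

    for s in range(substeps):
        s0 = s / substeps
        Va = V0 + dV * s0
        Vb = V0 + dV * (s0 + 0.5 / substeps)
        Vc = V0 + dV * ((s + 1.0) / substeps)
        k1 = deriv(c, Va)
        k2 = deriv(c + 0.5 * h * k1, Vb)
        k3 = deriv(c + 0.5 * h * k2, Vb)
        k4 = deriv(c + h * k3, Vc)
        c = c + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return c


def _prepare_ensemble(model, config: SimConfig, initial_ensemble):
    """Stack nuclear initial conditions and draw electronic variables."""
    basis = _model_basis(model)
    F = model.electronic.f_states
    if initial_ensemble is None:
        center = config.init_nuclear if config.init_nuclear is not None else config.init_electronic
        initial_ensemble = sample_wigner(
            model, center, config.temperature, config.n_traj, config.seed
        )
    states = list(initial_ensemble)
    for st in states:
        if st.basis != basis:
            raise InvalidInputError(
                f"phase-space basis {st.basis!r} does not match the model ({basis!r})"
            )
    R = np.stack([np.asarray(s.positions, float).reshape(model.nuclear_shape) for s in states])
    P = np.stack([np.asarray(s.momenta, float).reshape(model.nuclear_shape) for s in states])
    B = R.shape[0]
    c = np.empty((B, F), dtype=complex)
    if config.method == "mf":
        c[:] = 0.0
        c[:, config.init_electronic] = 1.0
    else:
        for k in range(B):
            rng = np.random.default_rng([config.seed, k, 1])
            c[k] = _sample_sqc_mapping(rng, F, config.init_electronic, config.zpe_gamma)
    return R, P, c


def propagate(
    model,
    initial_ensemble,
    config: SimConfig,
    _return_raw: bool = False,
    return_final: bool = False,
):
    """Propagate an ensemble and return a :class:`PopulationTrace`.

    ``initial_ensemble`` is a list of :class:`PhaseSpaceState` (or None to
    Wigner-sample ``config.n_traj`` trajectories internally).
    ``return_final`` additionally returns the final batched phase-space
    arrays and electronic variables (R, P, c).
    """
    prop = _Propagator(model)
    gam = prop.gam
    gamma_zpe = config.zpe_gamma if config.method == "sqc" else 0.0
    R, P, c = _prepare_ensemble(model, config, initial_ensemble)
    B, F = c.shape
    dt = config.dt_fs * FS_TO_AU_TIME
    n_steps = config.n_steps
    stride = config.output_stride
    n_out = n_steps // stride + 1

    def weights(cc):
        w = np.abs(cc) ** 2
        return w - gamma_zpe if config.method == "sqc" else w

    times = np.empty(n_out)
    sigma = np.zeros((n_out, F, F), dtype=complex)
    rc_mean = np.zeros((n_out, model.subspaces)) if prop.is_mrc else None
    energy = np.empty(n_out)
    raw_pops = np.empty((B, n_out, F)) if _return_raw else None

    V0 = prop.potentials(R)
    Fc = prop.mean_force(R, weights(c))
    e0 = None
    max_drift = 0.0

    def record(i_out, step):
        nonlocal e0, max_drift
        times[i_out] = step * config.dt_fs
        pops = np.abs(c) ** 2
        if raw_pops is not None:
            raw_pops[:, i_out] = pops
        coh = np.einsum("bj,bk->jk", c, c.conj()) / B
        if config.method == "sqc":
            counts = _sqc_window_counts(pops, gamma_zpe)
            tot = counts.sum()
            if i_out == 0 and tot == 0:
                raise EstimatorDegenerateError("no trajectory lands in any window at t=0")
            col = counts.sum(axis=0)
            diag = col / tot if tot > 0 else np.full(F, np.nan)
        else:
            diag = pops.mean(axis=0)
        sigma[i_out] = coh
        sigma[i_out][np.diag_indices(F)] = diag
        if rc_mean is not None:
            rc_mean[i_out] = R[:, :, 0].mean(axis=0)
        e_traj = (
            0.5 * np.einsum("bij,bij->b", P, P)
            + np.einsum("bx,bx->b", weights(c), V0)
            + np.real(np.einsum("bj,jk,bk->b", c.conj(), gam, c))
        )
        energy[i_out] = e_traj.mean()
        if e0 is None:
            e0 = e_traj.copy()
        else:
            max_drift = max(max_drift, float(np.max(np.abs(e_traj - e0))))

    record(0, 0)
    i_out = 1
    for step in range(1, n_steps + 1):
        P += 0.5 * dt * Fc
        R += dt * P
        V1 = prop.potentials(R)
        c = _rk4_electronic(c, V0, V1, gam, dt, config.substeps)
        Fc = prop.mean_force(R, weights(c))
        P += 0.5 * dt * Fc
        V0 = V1
        if step % stride == 0:
            record(i_out, step)
            i_out += 1
    if max_drift > config.energy_drift_tol:
        warnings.warn(
            f"max per-trajectory energy drift {max_drift:.3e} hartree exceeds "
            f"the {config.energy_drift_tol:.1e} threshold",
            stacklevel=2,
        )
    trace = PopulationTrace(
        times=times,
        sigma=sigma,
        rc_mean=rc_mean,
        energy=energy,
        max_energy_drift=max_drift,
        n_traj=B,
    )
    if _return_raw:
        return trace, raw_pops
    if return_final:
        return trace, (R, P, c)
    return trace


def ehrenfest_propagate(model, initial_ensemble, config: SimConfig) -> PopulationTrace:
    """Ehrenfest mean-field propagation (forces config.method = 'mf')."""
    if config.method != "mf":
        config = replace(config, method="mf")
    return propagate(model, initial_ensemble, config)


def sqc_propagate(model, initial_ensemble, config: SimConfig) -> PopulationTrace:
    """SQC triangle-window propagation (forces config.method = 'sqc')."""
    if config.method != "sqc":
        config = replace(config, method="sqc")
    return propagate(model, initial_ensemble, config)


def matching_digits(a: np.ndarray, b: np.ndarray) -> int:
    """Number of agreeing significant figures between two population vectors
    (min over components, on the scale of the largest component)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    err = float(np.max(np.abs(a - b)))
    if err == 0.0:
        return 16
    ref = float(max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300))
    return int(max(0, min(16, math.floor(-math.log10(err / ref)))))


@dataclass
class EquivalenceReport:
    times: np.ndarray  # fs
    digits: np.ndarray  # per-step min matching significant figures
    trace_msh: PopulationTrace
    trace_mrc: PopulationTrace


def equivalence_report(
    msh_model: MSHModel, mrc_model: MRCModel, config: SimConfig
) -> EquivalenceReport:
    """Propagate identical seeded trajectories on an MSH model and on its
    transformed MRC model and count agreeing significant figures of the
    electronic populations at every output step.

    Initial nuclear conditions are Wigner-sampled once in the normal-mode
    basis and mapped to the MRC basis; electronic variables are shared
    verbatim. The reported value at each step is the minimum over
    trajectories and states.
    """
    center = config.init_nuclear if config.init_nuclear is not None else config.init_electronic
    nm_states = sample_wigner(msh_model, center, config.temperature, config.n_traj, config.seed)
    rc_states = [
        PhaseSpaceState(
            coords_msh_to_mrc(mrc_model, s.positions),
            coords_msh_to_mrc(mrc_model, s.momenta),
            "primary_secondary",
        )
        for s in nm_states
    ]
    trace_a, raw_a = propagate(msh_model, nm_states, config, _return_raw=True)
    trace_b, raw_b = propagate(mrc_model, rc_states, config, _return_raw=True)
    n_out = trace_a.times.size
    digits = np.empty(n_out, dtype=int)
    for i in range(n_out):
        digits[i] = min(
            matching_digits(raw_a[k, i], raw_b[k, i]) for k in range(raw_a.shape[0])
        )
    return EquivalenceReport(times=trace_a.times, digits=digits, trace_msh=trace_a, trace_mrc=trace_b)


def rc_trajectory_average(results) -> np.ndarray:
    """Trajectory-count-weighted mean of the RC component series <y_i(t)>
    over one or more :class:`PopulationTrace` results from MRC runs."""
    if isinstance(results, PopulationTrace):
        results = [results]
    traces = [t for t in results]
    if any(t.rc_mean is None for t in traces):
        raise InvalidInputError("rc averaging needs MRC-basis trajectories")
    wsum = sum(t.n_traj for t in traces)
    return sum(t.n_traj * t.rc_mean for t in traces) / wsum
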