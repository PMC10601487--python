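"""Spectral densities, energy-gap time correlation functions, and
equal-reorganization bath discretization.

Conventions (centralized here; changing a convention is a one-line edit):

* ``J(omega) = (beta*omega/2) * int_0^inf dt C(t) cos(omega*t)`` maps the
  classical energy-gap autocorrelation ``C(t)`` to the spectral density.
* ``E_r = beta*C(0)/2`` is the reorganization energy from the gap variance.
* Consequently ``E_r = (2/pi) * int_0^inf J(omega)/omega domega``; the
  analytic Debye density is written ``J = er*omega*omega_c/(omega^2 +
  omega_c^2)`` so its ``er`` parameter *is* the reorganization energy under
  this normalization, and the Ohmic density ``J = eta*omega*
  exp(-omega/omega_c)`` carries ``E_r = (2/pi)*eta*omega_c``.

All quantities are in Hartree atomic units (hbar = 1, mass-weighted
coordinates) unless a loader says otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exceptions import InvalidDensityError, InvalidInputError
from .units import CM1_TO_HARTREE, FS_TO_AU_TIME

__all__ = [
    "GapTCF",
    "SpectralDensity",
    "DiscretizedBath",
    "ohmic_density",
    "debye_density",
    "tabulated_density",
    "analytic_density",
    "tcf_to_spectral_density",
    "reorg_from_tcf",
    "reorg_from_density",
    "discretize",
    "goa_effective_density",
    "read_tabulated_density",
    "read_gap_tcf",
]

#: default omega grid for tabulated outputs: 0..5000 cm^-1, 2048 points
DEFAULT_OMEGA_GRID = np.linspace(0.0, 5000.0 * CM1_TO_HARTREE, 2048)


@dataclass(frozen=True)
class GapTCF:
    """Classical energy-gap time autocorrelation series.

    Attributes
    ----------
    times : ndarray
        Uniform time grid starting at 0 (a.u.).
    values : ndarray
        Real autocorrelation values C(t) (energy^2, a.u.).
    beta : float
        Inverse temperature 1/(k_B T) (1/hartree).
    """

    times: np.ndarray
    values: np.ndarray
    beta: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.size < 2 or values.shape != times.shape:
            raise InvalidInputError("TCF needs matching 1-d grids of length >= 2")
        if times[0] != 0.0:
            raise InvalidInputError("TCF time grid must start at t = 0")
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=0.0):
            raise InvalidInputError("TCF time grid must be uniform")
        if self.beta <= 0:
            raise InvalidInputError("beta must be positive")
        if values[0] < 0:
            raise InvalidInputError("C(0) must be nonnegative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class SpectralDensity:
    """Bath spectral density J(omega): analytic (ohmic/debye) or tabulated.

    Callable; evaluates vectorized over ``omega``. Tabulated densities use a
    monotone piecewise-cubic interpolant and evaluate to zero (with a
    warning) beyond the table.
    """

    kind: str
    params: dict = field(default_factory=dict)
    table: np.ndarray | None = None  # (M, 2): omega, J

    def __post_init__(self):
        if self.kind not in ("ohmic", "debye", "tabulated"):
            raise InvalidInputError(f"unknown spectral density kind: {self.kind!r}")
        if self.kind == "tabulated":
            tab = np.asarray(self.table, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
                raise InvalidInputError("table must have shape (M>=2, 2)")
            if np.any(np.diff(tab[:, 0]) <= 0):
                raise InvalidInputError("tabulated omega grid must be strictly increasing")
            if np.any(tab[:, 1] < 0):
                raise InvalidInputError("J(omega) must be nonnegative")
            object.__setattr__(self, "table", tab)
            object.__setattr__(
                self, "_interp", PchipInterpolator(tab[:, 0], tab[:, 1], extrapolate=False)
            )
        else:
            for key in ("eta", "er"):
                if key in self.params and self.params[key] < 0:
                    raise InvalidInputError(f"{key} must be nonnegative")
            if self.params.get("omega_c", 1.0) <= 0:
                raise InvalidInputError("omega_c must be positive")

    def __call__(self, omega):
        w = np.asarray(omega, dtype=float)
        if self.kind == "ohmic":
            eta, wc = self.params["eta"], self.params["omega_c"]
            out = eta * np.abs(w) * np.exp(-np.abs(w) / wc)
        elif self.kind == "debye":
            er, wc = self.params["er"], self.params["omega_c"]
            out = er * np.abs(w) * wc / (w * w + wc * wc)
        else:
            lo, hi = self.table[0, 0], self.table[-1, 0]
            if np.any((w < lo) | (w > hi)):
                warnings.warn(
                    "evaluating tabulated spectral density outside its grid; "
                    "returning zero there",
                    stacklevel=2,
                )
            out = np.nan_to_num(self._interp(w), nan=0.0)
            out = np.clip(out, 0.0, None)
        return out if np.ndim(omega) else float(out)


def ohmic_density(eta: float, omega_c: float) -> SpectralDensity:
    """Ohmic density J = eta*omega*exp(-omega/omega_c); maximum at omega_c."""
    if eta <= 0 or omega_c <= 0:
        raise InvalidInputError("eta and omega_c must be positive")
    return SpectralDensity("ohmic", {"eta": eta, "omega_c": omega_c})


def debye_density(er: float, omega_c: float) -> SpectralDensity:
    """Debye (overdamped) density J = er*omega*omega_c/(omega^2+omega_c^2).

    ``er`` is the reorganization energy carried by the density under the
    module convention E_r = (2/pi) int J/omega domega.
    """
    if er <= 0 or omega_c <= 0:
        raise InvalidInputError("er and omega_c must be positive")
    return SpectralDensity("debye", {"er": er, "omega_c": omega_c})


def tabulated_density(omegas, values) -> SpectralDensity:
    tab = np.column_stack([np.asarray(omegas, float), np.asarray(values, float)])
    return SpectralDensity("tabulated", table=tab)


def analytic_density(kind: str, **params) -> SpectralDensity:
    """Dispatch to :func:`ohmic_density` (eta, omega_c) or
    :func:`debye_density` (er, omega_c)."""
    if kind == "ohmic":
        return ohmic_density(params["eta"], params["omega_c"])
    if kind == "debye":
        return debye_density(params["er"], params["omega_c"])
    raise InvalidInputError(f"unknown analytic kind: {kind!r}")


@dataclass(frozen=True)
class DiscretizedBath:
    """Equal-reorganization discretization of a spectral density.

    Each of the N modes carries the same reorganization share er/N:
    ``(1/2) omega_j^2 req_j^2 = er/N`` exactly by construction, with
    ``req_j = sqrt(2 er/N)/omega_j`` and coupling coefficients
    ``c_j = omega_j^2 req_j / 2``.
    """

    omegas: np.ndarray
    er: float

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.omegas, dtype=float))
        object.__setattr__(self, "omegas", w)
        if np.any(w <= 0):
            raise InvalidInputError("mode frequencies must be positive")
        if np.any(np.diff(w) <= 0):
            raise InvalidInputError("mode frequencies must be strictly ascending")
        if self.er <= 0:
            raise InvalidInputError("total reorganization energy must be positive")

    @property
    def n_modes(self) -> int:
        return self.omegas.size

    @property
    def req(self) -> np.ndarray:
        """Per-mode equilibrium displacement scale (mass-weighted, a.u.)."""
        return np.sqrt(2.0 * self.er / self.n_modes) / self.omegas

    @property
    def couplings(self) -> np.ndarray:
        return 0.5 * self.omegas**2 * self.req

    def total_reorg(self) -> float:
        """(1/2) sum_j omega_j^2 req_j^2; equals ``er`` by construction."""
        return float(0.5 * np.sum(self.omegas**2 * self.req**2))


def reorg_from_tcf(tcf: GapTCF) -> float:
    """Reorganization energy from the gap variance: E_r = beta*C(0)/2."""
    return 0.5 * tcf.beta * float(tcf.values[0])


def reorg_from_density(J: SpectralDensity, omega_max: float | None = None) -> float:
    """E_r = (2/pi) int_0^omega_max J(omega)/omega domega (default: infinity)."""
    if J.kind == "debye":
        er, wc = J.params["er"], J.params["omega_c"]
        hi = np.pi / 2 if omega_max is None else np.arctan(omega_max / wc)
        return er * hi / (np.pi / 2)
    if J.kind == "ohmic":
        eta, wc = J.params["eta"], J.params["omega_c"]
        frac = 1.0 if omega_max is None else 1.0 - np.exp(-omega_max / wc)
        return (2.0 / np.pi) * eta * wc * frac
    grid = J.table[:, 0]
    if omega_max is not None:
        grid = np.append(grid[grid < omega_max], omega_max)
    # avoid 0/0 at the origin: J(0)=0 with J/omega finite; drop omega=0 node
    g = grid[grid > 0]
    return (2.0 / np.pi) * float(np.trapezoid(J(g) / g, g))


def tcf_to_spectral_density(
    tcf: GapTCF,
    omega_grid: np.ndarray | None = None,
    damping_tau: float | None = None,
    decay_tol: float = 0.05,
) -> SpectralDensity:
    """Cosine-transform a gap TCF into a tabulated spectral density.

    J(omega) = (beta*omega/2) * int_0^inf dt C(t) cos(omega t), evaluated by
    trapezoidal quadrature over the series, optionally pre-multiplied by an
    exponential window exp(-t/damping_tau) for noisy input. Warns when the
    series has not decayed to ~0 by its last point.
    """
    if omega_grid is None:
        omega_grid = DEFAULT_OMEGA_GRID
    w = np.asarray(omega_grid, dtype=float)
    c = tcf.values.copy()
    if damping_tau is not None:
        c = c * np.exp(-tcf.times / damping_tau)
    scale = np.max(np.abs(c)) if c.size else 0.0
    if scale > 0 and abs(c[-1]) > decay_tol * scale:
        warnings.warn(
            "gap TCF has not decayed at its last point; transform may be "
            "contaminated by truncation ringing (consider damping_tau)",
            stacklevel=2,
        )
    # trapezoid weights on the uniform grid
    wt = np.full(c.size, tcf.dt)
    wt[0] *= 0.5
    wt[-1] *= 0.5
    integral = np.cos(np.outer(w, tcf.times)) @ (wt * c)
    J = 0.5 * tcf.beta * w * integral
    J[w == 0.0] = 0.0
    J = np.clip(J, 0.0, None)
    return SpectralDensity("tabulated", table=np.column_stack([w, J]))


def _fraction_grid(n_modes: int, fraction: str) -> np.ndarray:
    j = np.arange(1, n_modes + 1, dtype=float)
    if fraction == "midpoint":
        return (j - 0.5) / n_modes
    if fraction == "endpoint":
        return j / (n_modes + 1)
    raise InvalidInputError(f"unknown fraction convention: {fraction!r}")


def discretize(
    J: SpectralDensity,
    n_modes: int,
    er_total: float | None = None,
    fraction: str = "midpoint",
    omega_max: float | None = None,
) -> DiscretizedBath:
    """Discretize J(omega) into N modes of equal reorganization share.

    Frequencies solve F(omega_j) = q_j * F(omega_max) with
    F(omega) = int_0^omega J/omega' domega' and the midpoint fractions
    q_j = (j-1/2)/N (``fraction="endpoint"`` selects j/(N+1)). Displacements
    req_j = sqrt(2 er_total/N)/omega_j put exactly er_total/N of
    reorganization on each mode. ``er_total`` defaults to the reorganization
    energy carried by J itself.
    """
    if n_modes < 1:
        raise InvalidInputError("n_modes must be >= 1")
    if n_modes == 1:
        warnings.warn("N=1 discretization is degenerate (single median mode)", stacklevel=2)
    if er_total is None:
        er_total = reorg_from_density(J, omega_max=omega_max)
    if er_total <= 0:
        raise InvalidInputError("er_total must be positive")

    q = _fraction_grid(n_modes, fraction)
    if J.kind == "debye":
        wc = J.params["omega_c"]
        top = np.pi / 2 if omega_max is None else np.arctan(omega_max / wc)
        omegas = wc * np.tan(q * top)
    elif J.kind == "ohmic":
        wc = J.params["omega_c"]
        top = 1.0 if omega_max is None else 1.0 - np.exp(-omega_max / wc)
        omegas = -wc * np.log1p(-q * top)
    else:
        grid = J.table[:, 0]
        if omega_max is not None:
            grid = np.append(grid[grid < omega_max], omega_max)
        g = grid[grid > 0]
        if g.size < 2:
            raise InvalidDensityError("tabulated density has no positive-frequency support")
        integrand = J(g) / g
        F = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(g))])
        if not np.isfinite(F[-1]) or F[-1] <= 0:
            raise InvalidDensityError("cumulative integral of J/omega is not finite and positive")
        omegas = np.interp(q * F[-1], F, g)
    if np.any(~np.isfinite(omegas)):
        raise InvalidDensityError("discretization produced non-finite frequencies")
    return DiscretizedBath(omegas=np.sort(omegas), er=float(er_total))


def goa_effective_density(Omega: float, eta: float, omega_c: float):
    """Asymptotic (Leggett-prescription) effective spectral density of a
    harmonic primary mode Omega bilinearly damped by an Ohmic secondary
    bath J_b = eta*omega*exp(-omega/omega_c) — the Brownian-oscillator
    closed form, accurate for Omega << omega_c:

        J_eff(omega) = Gamma(omega)*omega*Omega^4
                       / ((Omega^2-omega^2)^2 + Gamma(omega)^2*omega^2),

    with the damping kernel Gamma(omega) = 2*J_b(omega)/omega =
    2*eta*exp(-omega/omega_c) implied by the package's equal-share
    secondary-coupling convention c_a^2 = 2*omega_a^2*er_b/N. Returned on
    an arbitrary overall scale (shape oracle): validation only, never used
    in model construction.
    """
    if Omega <= 0 or eta <= 0 or omega_c <= 0:
        raise InvalidInputError("Omega, eta, omega_c must be positive")

    def j_eff(omega):
        w = np.asarray(omega, dtype=float)
        gam = 2.0 * eta * np.exp(-np.abs(w) / omega_c)
        out = gam * w * Omega**4 / ((Omega**2 - w * w) ** 2 + (gam * w) ** 2)
        return out if np.ndim(omega) else float(out)

    return j_eff


def _read_two_column(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            rows.append((float(parts[0]), float(parts[1])))
    if len(rows) < 2:
        raise InvalidInputError(f"{path}: fewer than two data rows")
    return np.array(rows)


def read_tabulated_density(path) -> SpectralDensity:
    """Read '# omega_cm-1 J_au' two-column text into a tabulated density."""
    tab = _read_two_column(path)
    tab[:, 0] *= CM1_TO_HARTREE
    return SpectralDensity("tabulated", table=tab)


def read_gap_tcf(path, beta: float) -> GapTCF:
    """Read '# t_fs C_au2' two-column text into a :class:`GapTCF`."""
    tab = _read_two_column(path)
    return GapTCF(times=tab[:, 0] * FS_TO_AU_TIME, values=tab[:, 1], beta=beta)
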