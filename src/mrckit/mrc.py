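"""Exact transformation between the multistate harmonic (MSH) model and the
multistate reaction coordinate (MRC) model.

The reaction coordinate y is the unit direction a_j proportional to
omega_j^2 R_j^eq in normal-mode space, i.e. the direction along which the
state PES minima differ. A Householder reflection P maps e_1 onto a; the
reflected Hessian K = P Lambda P has the reaction coordinate in its first
row/column, and diagonalizing its trailing (N-1) x (N-1) block yields the
secondary bath frequencies omega_alpha and the bilinear couplings c_alpha.

The primary frequency is defined by requiring that the *relaxed* reaction
coordinate carries the entire reorganization energy,

    Omega^2 = sum_j omega_j^4 (R_j^eq)^2 / sum_j omega_j^2 (R_j^eq)^2 ,

which is exactly the Schur complement of K with respect to the secondary
block: K_11 = Omega^2 + sum_alpha c_alpha^2/omega_alpha^2. The MRC
potential is therefore written in full Caldeira-Leggett form with the
counterterm inside the completed square,

    V_X = eps_X + sum_i [ (1/2) Omega^2 (y_i + S^(i,X))^2
          + sum_alpha (1/2) omega_alpha^2 (x_{i,alpha} + c_alpha y_i/omega_alpha^2)^2 ],

which reproduces the MSH potential identically (to roundoff) under the
orthogonal coordinate map. This convention is controlled by
:data:`COUNTERTERM_IN_POTENTIAL`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, NumericalFailureError
from .msh import ElectronicParams, MSHModel, PolyhedronVertices, build_msh
from .spectral import DiscretizedBath

__all__ = [
    "ReactionCoordinateFrame",
    "MRCModel",
    "primary_mode",
    "householder_reflector",
    "secondary_bath",
    "primary_shifts",
    "msh_to_mrc",
    "mrc_to_msh",
    "coords_msh_to_mrc",
    "coords_mrc_to_msh",
    "mrc_potential",
    "mrc_gradient",
    "build_goa_model",
    "goa_normal_modes",
]

#: The quadratic-in-y completion implied by exact MSH equivalence is carried
#: inside the potential (Caldeira-Leggett completed-square form). Flipping
#: this to False would drop the counterterm sum_a c_a^2/(2 omega_a^2) y^2
#: and break exact equivalence; it exists only to document the convention.
COUNTERTERM_IN_POTENTIAL = True

_DEGENERATE_REFLECTOR_TOL = 1e-12


@dataclass(frozen=True)
class ReactionCoordinateFrame:
    """Unit reaction-coordinate direction a in normal-mode space and its
    normalization kappa = sqrt(sum omega_j^4 (R_j^eq)^2)."""

    direction: np.ndarray
    kappa: float

    def __post_init__(self):
        a = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", a)
        if not np.isclose(np.linalg.norm(a), 1.0, rtol=0, atol=1e-10):
            raise InvalidInputError("reaction-coordinate direction must be a unit vector")


@dataclass(frozen=True)
class MRCModel:
    """Primary/secondary re-expression of an MSH model.

    Attributes
    ----------
    omega_rc : float
        Primary (reaction-coordinate) frequency Omega (a.u.).
    bath_omegas : ndarray, shape (N-1,)
        Secondary bath frequencies, ascending (a.u.).
    bath_couplings : ndarray, shape (N-1,)
        Bilinear primary/secondary couplings c_alpha (a.u.).
    primary_shifts : ndarray, shape (F, F-1)
        Equilibrium shifts S^(i,X) = sqrt(2) d_X[i] / Omega of the primary
        coordinate in each subspace; zero for i >= X.
    basis_matrix : ndarray, shape (N, N) or None
        Orthogonal map T from (y, x_1..x_{N-1}) to normal-mode coordinates,
        R = T w; shared by all subspaces. None for hand-built models that
        never touch normal-mode coordinates.
    electronic : ElectronicParams
    er_ref : float
        Reference bath reorganization energy of the originating
        equal-reorganization bath (used by :func:`mrc_to_msh`).
    """

    omega_rc: float
    bath_omegas: np.ndarray
    bath_couplings: np.ndarray
    primary_shifts: np.ndarray
    electronic: ElectronicParams
    basis_matrix: np.ndarray | None = None
    er_ref: float = 1.0

    def __post_init__(self):
        wa = np.asarray(self.bath_omegas, dtype=float)
        ca = np.asarray(self.bath_couplings, dtype=float)
        S = np.asarray(self.primary_shifts, dtype=float)
        object.__setattr__(self, "bath_omegas", wa)
        object.__setattr__(self, "bath_couplings", ca)
        object.__setattr__(self, "primary_shifts", S)
        if self.omega_rc <= 0:
            raise InvalidInputError("primary frequency must be positive")
        if np.any(wa <= 0) or np.any(np.diff(wa) < 0):
            raise InvalidInputError("secondary frequencies must be positive and ascending")
        if ca.shape != wa.shape:
            raise InvalidInputError("couplings must match secondary frequencies")
        F = self.electronic.f_states
        if S.shape != (F, F - 1):
            raise InvalidInputError("primary shift matrix must have shape (F, F-1)")
        for X in range(F):
            if np.any(S[X, X:] != 0):
                raise InvalidInputError("primary shifts must vanish for i >= X")
        if self.basis_matrix is not None:
            T = np.asarray(self.basis_matrix, dtype=float)
            object.__setattr__(self, "basis_matrix", T)
            N = wa.size + 1
            if T.shape != (N, N):
                raise InvalidInputError("basis matrix must be N x N")
            if not np.allclose(T.T @ T, np.eye(N), rtol=0, atol=1e-12):
                raise InvalidInputError("basis matrix must be orthogonal")

    @property
    def f_states(self) -> int:
        return self.electronic.f_states

    @property
    def subspaces(self) -> int:
        return self.f_states - 1

    @property
    def n_modes(self) -> int:
        """Modes per subspace, N (primary + N-1 secondary)."""
        return self.bath_omegas.size + 1

    @property
    def nuclear_shape(self) -> tuple:
        """(F-1, N): column 0 is y_i, columns 1.. are x_{i,alpha}."""
        return (self.subspaces, self.n_modes)

    @property
    def n_dof(self) -> int:
        return self.subspaces * self.n_modes

    def k11(self) -> float:
        """Curvature of the potential along y: Omega^2 + sum c^2/omega^2."""
        return self.omega_rc**2 + float(np.sum(self.bath_couplings**2 / self.bath_omegas**2))

    def state_minimum(self, X: int) -> np.ndarray:
        """(F-1, N) phase-space minimum of V_X: y_i = -S^(i,X) with the
        secondary bath relaxed, x_alpha = c_alpha S^(i,X)/omega_alpha^2."""
        w = np.zeros(self.nuclear_shape)
        S = self.primary_shifts[X]
        w[:, 0] = -S
        w[:, 1:] = S[:, None] * (self.bath_couplings / self.bath_omegas**2)[None, :]
        return w

    def potential(self, X: int, w: np.ndarray) -> float:
        return mrc_potential(self, X, w)

    def gradient(self, X: int, w: np.ndarray) -> np.ndarray:
        return mrc_gradient(self, X, w)

    def potential_all(self, w: np.ndarray):
        """All state potentials and gradients at w = (y | x)."""
        w = np.asarray(w, dtype=float).reshape(self.nuclear_shape)
        y = w[:, 0]
        x = w[:, 1:]
        Om2 = self.omega_rc**2
        wa2 = self.bath_omegas**2
        ca = self.bath_couplings
        F = self.f_states
        V = np.empty(F)
        grad = np.empty((F,) + self.nuclear_shape)
        bath_disp = x + np.outer(y, ca / wa2)  # state independent
        bath_V = 0.5 * np.sum(wa2 * bath_disp**2)
        bath_gy = bath_disp @ ca
        for X in range(F):
            yd = y + self.primary_shifts[X]
            V[X] = self.electronic.epsilons[X] + 0.5 * Om2 * np.sum(yd**2) + bath_V
            grad[X, :, 0] = Om2 * yd + bath_gy
            grad[X, :, 1:] = wa2 * bath_disp
        return V, grad

    def pairwise_reorg(self) -> np.ndarray:
        """Pairwise reorganization energies from the relaxed PES minima."""
        F = self.f_states
        out = np.empty((F, F))
        for X in range(F):
            wX = self.state_minimum(X)
            VX = self.potential(X, wX)
            for Y in range(F):
                out[X, Y] = self.potential(Y, wX) - self.electronic.epsilons[Y]
            out[X, X] = 0.0
        return out


def primary_mode(bath: DiscretizedBath):
    """Reaction-coordinate frequency and direction of a discretized bath.

    a_j = omega_j^2 R_j^eq / kappa, kappa = sqrt(sum omega_j^4 (R_j^eq)^2),
    Omega^2 = sum omega_j^4 R_j^2 / sum omega_j^2 R_j^2. Under the
    equal-reorganization discretization (R_j ~ 1/omega_j) this reduces to
    Omega = rms(omega_j) and a_j ~ omega_j.
    """
    w, R = bath.omegas, bath.req
    weights = w**2 * R
    kappa = float(np.linalg.norm(weights))
    if kappa == 0.0:
        raise InvalidInputError("all equilibrium displacements vanish; no reaction coordinate")
    Omega = kappa / float(np.linalg.norm(w * R))
    return float(Omega), ReactionCoordinateFrame(direction=weights / kappa, kappa=kappa)


def householder_reflector(a: np.ndarray) -> np.ndarray:
    """Symmetric orthogonal P with P e_1 = a: P = I - 2|u><u|/<u|u>,
    u = e_1 - a. Returns the identity when a is within 1e-12 of e_1."""
    a = np.asarray(a, dtype=float)
    if not np.isclose(np.linalg.norm(a), 1.0, rtol=0, atol=1e-10):
        raise InvalidInputError("reflector direction must be a unit vector")
    N = a.size
    if abs(1.0 - a[0]) < _DEGENERATE_REFLECTOR_TOL and np.allclose(
        a[1:], 0.0, atol=_DEGENERATE_REFLECTOR_TOL
    ):
        return np.eye(N)
    u = -a.copy()
    u[0] += 1.0
    return np.eye(N) - 2.0 * np.outer(u, u) / (u @ u)


def _fix_eigenvector_signs(U: np.ndarray) -> np.ndarray:
    """Make the first nonzero component of each column positive (sign flips
    are immaterial physically; fixing them makes runs bit-reproducible)."""
    U = U.copy()
    for k in range(U.shape[1]):
        col = U[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
        if nz.size and col[nz[0]] < 0:
            U[:, k] = -col
    return U


def secondary_bath(bath: DiscretizedBath, frame: ReactionCoordinateFrame):
    """Secondary bath frequencies, couplings, and the full basis matrix T.

    Forms K = P Lambda P with the Householder reflector P of the frame
    direction, diagonalizes the trailing (N-1) x (N-1) block K_sub =
    U diag(omega_alpha^2) U^T, and sets c_alpha = (U^T d)_alpha with d the
    first column of K below the diagonal. Returns
    (omega_alpha, c_alpha, U, T) with T = P @ blockdiag(1, U), ordered so
    the secondary frequencies ascend.
    """
    P = householder_reflector(frame.direction)
    K = P @ (bath.omegas**2 * P).T  # P diag(w^2) P with P symmetric
    K = 0.5 * (K + K.T)
    Ksub = K[1:, 1:]
    vals, U = np.linalg.eigh(0.5 * (Ksub + Ksub.T))
    scale = max(abs(vals[-1]), 1.0)
    if np.any(vals < -1e-12 * scale):
        raise NumericalFailureError(
            f"secondary Hessian block has negative eigenvalue {vals.min():.3e}"
        )
    vals = np.clip(vals, 0.0, None)
    order = np.argsort(vals)
    vals, U = vals[order], _fix_eigenvector_signs(U[:, order])
    omega_alphas = np.sqrt(vals)
    c_alphas = U.T @ K[1:, 0]
    N = bath.n_modes
    T = np.empty((N, N))
    T[:, 0] = P[:, 0]
    T[:, 1:] = P[:, 1:] @ U
    return omega_alphas, c_alphas, U, T


def primary_shifts(vertices: PolyhedronVertices, Omega: float) -> np.ndarray:
    """Equilibrium shifts of the primary coordinate: S^(i,X) =
    sqrt(2) d_X[i] / Omega (zero for i >= X), so the relaxed RC-space
    separation carries the full pairwise reorganization energy."""
    if Omega <= 0:
        raise InvalidInputError("Omega must be positive")
    return np.sqrt(2.0) * vertices.coords / Omega


def msh_to_mrc(model: MSHModel) -> MRCModel:
    """Exact MSH -> MRC transformation (same T in every subspace)."""
    Omega, frame = primary_mode(model.bath)
    omega_alphas, c_alphas, _, T = secondary_bath(model.bath, frame)
    S = primary_shifts(model.vertices, Omega)
    return MRCModel(
        omega_rc=Omega,
        bath_omegas=omega_alphas,
        bath_couplings=c_alphas,
        primary_shifts=S,
        electronic=model.electronic,
        basis_matrix=T,
        er_ref=model.bath.er,
    )


def _mrc_hessian(model: MRCModel) -> np.ndarray:
    """Per-subspace Hessian D in the (y, x) basis (Caldeira-Leggett form)."""
    N = model.n_modes
    D = np.zeros((N, N))
    D[0, 0] = model.k11()
    D[0, 1:] = model.bath_couplings
    D[1:, 0] = model.bath_couplings
    D[1:, 1:] = np.diag(model.bath_omegas**2)
    return D


def mrc_to_msh(model: MRCModel) -> MSHModel:
    """MRC -> MSH by diagonalizing the per-subspace Hessian.

    The eigenvalues of D give the normal-mode frequencies omega_j^2; the
    polyhedron vertices are recovered from the primary shifts
    (d_X[i] = Omega S^(i,X)/sqrt(2)) and the equal-reorganization bath is
    rebuilt at the stored reference reorganization energy ``er_ref``.
    """
    D = _mrc_hessian(model)
    vals, _ = np.linalg.eigh(D)
    if np.any(vals <= 0):
        raise NumericalFailureError("reconstructed Hessian is not positive definite")
    omegas = np.sqrt(np.sort(vals))
    bath = DiscretizedBath(omegas=omegas, er=model.er_ref)
    coords = model.omega_rc * model.primary_shifts / np.sqrt(2.0)
    vertices = PolyhedronVertices(coords=coords)
    return build_msh(bath, vertices, model.electronic)


def _require_basis(model: MRCModel) -> np.ndarray:
    if model.basis_matrix is None:
        raise InvalidInputError(
            "this MRC model carries no basis matrix; build it with msh_to_mrc "
            "to map coordinates"
        )
    return model.basis_matrix


def coords_msh_to_mrc(model: MRCModel, R: np.ndarray) -> np.ndarray:
    """Map normal-mode coordinates/momenta (F-1, N) to the MRC basis.

    Returns w of shape (F-1, N): w[:, 0] = y_i, w[:, 1:] = x_{i, alpha}.
    Applies T^T per subspace; orthogonal, hence norm preserving and valid
    for momenta as well.
    """
    T = _require_basis(model)
    R = np.asarray(R, dtype=float).reshape(model.subspaces, model.n_modes)
    return R @ T  # (T^T R_i^T)^T row-wise


def coords_mrc_to_msh(model: MRCModel, w: np.ndarray) -> np.ndarray:
    """Inverse of :func:`coords_msh_to_mrc` (applies T per subspace)."""
    T = _require_basis(model)
    w = np.asarray(w, dtype=float).reshape(model.subspaces, model.n_modes)
    return w @ T.T


def mrc_potential(model: MRCModel, X: int, w: np.ndarray) -> float:
    """State-X potential at w = (y | x), Caldeira-Leggett completed-square
    form (counterterm included; exactly matches the MSH potential under the
    coordinate map)."""
    w = np.asarray(w, dtype=float).reshape(model.nuclear_shape)
    y, x = w[:, 0], w[:, 1:]
    yd = y + model.primary_shifts[X]
    wa2 = model.bath_omegas**2
    bath_disp = x + np.outer(y, model.bath_couplings / wa2)
    return float(
        model.electronic.epsilons[X]
        + 0.5 * model.omega_rc**2 * np.sum(yd**2)
        + 0.5 * np.sum(wa2 * bath_disp**2)
    )


def mrc_gradient(model: MRCModel, X: int, w: np.ndarray) -> np.ndarray:
    """Analytic gradient of V_X in the (y | x) layout."""
    w = np.asarray(w, dtype=float).reshape(model.nuclear_shape)
    y, x = w[:, 0], w[:, 1:]
    wa2 = model.bath_omegas**2
    ca = model.bath_couplings
    bath_disp = x + np.outer(y, ca / wa2)
    grad = np.empty_like(w)
    grad[:, 0] = model.omega_rc**2 * (y + model.primary_shifts[X]) + bath_disp @ ca
    grad[:, 1:] = wa2 * bath_disp
    return grad


def build_goa_model(
    Omega: float,
    secondary: DiscretizedBath,
    er: float,
    electronic: ElectronicParams | None = None,
) -> MRCModel:
    """Two-state reaction-coordinate (GOA) model built directly in the
    primary/secondary picture.

    The secondary bath is taken from an equal-reorganization discretization
    of its spectral density; the bilinear couplings follow the
    Caldeira-Leggett identification sum_alpha c_alpha^2/omega_alpha^2 =
    2*er_bath spread equally, i.e. c_alpha = omega_alpha *
    sqrt(2*er_bath/N). The two PES minima are separated by
    2 y_0 = sqrt(2 er)/Omega so the primary mode carries the full
    donor-acceptor reorganization energy ``er``.
    """
    if electronic is None:
        electronic = ElectronicParams(epsilons=np.zeros(2), gammas=np.zeros((2, 2)))
    if electronic.f_states != 2:
        raise InvalidInputError("GOA model is two-state")
    ca = secondary.omegas * np.sqrt(2.0 * secondary.er / secondary.n_modes)
    S = np.zeros((2, 1))
    S[1, 0] = np.sqrt(2.0 * er) / Omega
    return MRCModel(
        omega_rc=Omega,
        bath_omegas=secondary.omegas,
        bath_couplings=ca,
        primary_shifts=S,
        electronic=electronic,
        basis_matrix=None,
        er_ref=er,
    )


def goa_normal_modes(model: MRCModel):
    """Normal-mode (spin-boson) reduction of a two-state MRC/GOA model.

    Diagonalizes the per-subspace Hessian and projects the distance between
    the two relaxed PES minima onto the normal modes. Returns
    (omega_j, R_j^eq); the per-mode reorganization shares
    (1/2) omega_j^2 (R_j^eq)^2 realize the discrete effective spectral
    density of the primary mode, the quantity the Leggett closed form
    approximates.
    """
    if model.f_states != 2:
        raise InvalidInputError("normal-mode reduction defined for two-state models")
    D = _mrc_hessian(model)
    vals, V = np.linalg.eigh(D)
    order = np.argsort(vals)
    vals, V = vals[order], _fix_eigenvector_signs(V[:, order])
    omegas = np.sqrt(np.clip(vals, 0.0, None))
    dw = (model.state_minimum(1) - model.state_minimum(0))[0]
    req = V.T @ dw
    return omegas, req
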