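"""Multistate harmonic (MSH) model construction.

An F-state system has F(F-1)/2 pairwise reorganization energies, more than
the number of states, so a single shared one-dimensional bath cannot satisfy
them all. The MSH model extends each of the N shared normal modes to F-1
spatial dimensions: the PES minima of the F states then sit at the vertices
of a polyhedron in F-1 dimensions whose squared edge lengths are the
pairwise reorganization energies. Embedding that polyhedron is a
distance-geometry problem solved through the Gram matrix anchored at
state 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, NotEmbeddableError
from .spectral import DiscretizedBath

__all__ = [
    "ReorgMatrix",
    "ElectronicParams",
    "PolyhedronVertices",
    "MSHModel",
    "FrenkelModel",
    "embed_polyhedron",
    "build_msh",
    "msh_potential",
    "msh_gradient",
    "reaction_free_energy",
    "build_frenkel_model",
]


@dataclass(frozen=True)
class ReorgMatrix:
    """Symmetric F x F matrix of pairwise reorganization energies (a.u.)."""

    values: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 2:
            raise InvalidInputError("reorganization matrix must be square, F >= 2")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12 * max(1.0, np.abs(v).max())):
            raise InvalidInputError("reorganization matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InvalidInputError("reorganization matrix must have zero diagonal")
        if np.any(v < 0):
            raise InvalidInputError("reorganization energies must be nonnegative")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"state{i+1}" for i in range(v.shape[0]))
            )

    @property
    def f_states(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ElectronicParams:
    """Energy minima eps_X and interstate couplings Gamma_XY (a.u.).

    Couplings are constant (Condon approximation). ``ground_state`` marks a
    state whose couplings are forced to zero (it participates only in
    nuclear sampling, so its energy minimum is arbitrary).
    """

    epsilons: np.ndarray
    gammas: np.ndarray
    ground_state: int | None = None

    def __post_init__(self):
        eps = np.asarray(self.epsilons, dtype=float)
        gam = np.asarray(self.gammas, dtype=float)
        object.__setattr__(self, "epsilons", eps)
        object.__setattr__(self, "gammas", gam)
        F = eps.size
        if gam.shape != (F, F):
            raise InvalidInputError("gamma matrix shape must match epsilons")
        if not np.allclose(gam, gam.T, rtol=0, atol=1e-15 + 1e-12 * np.abs(gam).max()):
            raise InvalidInputError("gamma matrix must be symmetric")
        if np.any(np.diag(gam) != 0):
            raise InvalidInputError("gamma matrix must have zero diagonal")
        if self.ground_state is not None:
            g = self.ground_state
            if not (0 <= g < F):
                raise InvalidInputError("ground_state index out of range")
            if np.any(gam[g, :] != 0):
                raise InvalidInputError("couplings to the designated ground state must be zero")

    @property
    def f_states(self) -> int:
        return self.epsilons.size


@dataclass(frozen=True)
class PolyhedronVertices:
    """Vertex coordinates d_X of the PES-minimum polyhedron (units sqrt(energy)).

    Lower-triangular convention: vertex 1 sits at the origin and vertex X is
    nonzero only in its first X-1 coordinates.
    """

    coords: np.ndarray  # (F, F-1)

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        F = c.shape[0]
        if c.shape != (F, F - 1):
            raise InvalidInputError("vertex array must have shape (F, F-1)")
        for X in range(F):
            if np.any(c[X, X:] != 0):
                raise InvalidInputError(
                    f"vertex {X+1} must be zero in dimensions >= {X+1} "
                    "(lower-triangular convention)"
                )

    @property
    def f_states(self) -> int:
        return self.coords.shape[0]

    def squared_distances(self) -> np.ndarray:
        """Pairwise squared vertex distances; reproduces the input
        reorganization matrix for a valid embedding."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.einsum("xyk,xyk->xy", diff, diff)


def _triangle_violations(er: np.ndarray) -> list[str]:
    d = np.sqrt(er)
    F = er.shape[0]
    out = []
    for x in range(F):
        for y in range(F):
            for z in range(F):
                if x != y != z != x and d[x, z] > d[x, y] + d[y, z] + 1e-12:
                    out.append(
                        f"sqrt(Er[{x+1},{z+1}]) > sqrt(Er[{x+1},{y+1}]) + sqrt(Er[{y+1},{z+1}])"
                    )
    return out


def embed_polyhedron(
    er: ReorgMatrix, tol: float = 1e-8, on_defect: str = "raise"
) -> PolyhedronVertices:
    """Embed the pairwise reorganization energies as F vertices in F-1 dims.

    Builds the Gram matrix G_XY = (Er[1,X] + Er[1,Y] - Er[X,Y])/2 over
    X, Y >= 2 and returns its lower-triangular (Cholesky-style) factor with
    positive diagonal, anchored at state 1 at the origin.

    By default (``on_defect="raise"``) a Gram eigenvalue below
    -tol * max_eigenvalue raises :class:`NotEmbeddableError` (no silent
    nearest-PSD projection); smaller negative pivots are clipped to zero
    with a warning. ``on_defect="clip"`` instead clips every negative pivot
    with a warning reporting the defect: reorganization matrices estimated
    from anharmonic MD gap statistics can carry a genuine Gram defect, and
    pivot clipping keeps all distances exact among the states whose pivots
    stay positive (in particular the state-1/state-2 edge is always exact).
    """
    if on_defect not in ("raise", "clip"):
        raise InvalidInputError(f"unknown on_defect mode: {on_defect!r}")
    E = er.values
    F = er.f_states
    G = 0.5 * (E[0, 1:, None] + E[0, None, 1:] - E[1:, 1:])
    G = 0.5 * (G + G.T)
    eig = np.linalg.eigvalsh(G)
    scale = max(eig[-1], 0.0)
    if eig[0] < -tol * max(scale, 1e-300):
        if on_defect == "raise":
            hints = _triangle_violations(E)
            hint = ("; triangle-inequality diagnostics: " + "; ".join(hints[:3])) if hints else ""
            raise NotEmbeddableError(
                f"Gram matrix has negative eigenvalue {eig[0]:.6g} "
                f"(largest {scale:.6g}); the reorganization matrix admits no "
                f"point configuration{hint}"
            )
        warnings.warn(
            f"reorganization matrix is not exactly embeddable (Gram "
            f"eigenvalue {eig[0]:.4g} vs largest {scale:.4g}); negative "
            "pivots clipped, distances involving the affected states are "
            "approximate",
            stacklevel=2,
        )

    m = F - 1
    L = np.zeros((m, m))
    clipped = False
    for k in range(m):
        pivot = G[k, k] - L[k, :k] @ L[k, :k]
        if pivot < 0:
            clipped = True
            pivot = 0.0
        L[k, k] = np.sqrt(pivot)
        if L[k, k] > 0:
            for i in range(k + 1, m):
                L[i, k] = (G[i, k] - L[i, :k] @ L[k, :k]) / L[k, k]
    if clipped:
        warnings.warn(
            "Gram matrix is numerically rank deficient; negative pivots "
            "within tolerance clipped to zero",
            stacklevel=2,
        )
    coords = np.zeros((F, m))
    coords[1:] = L
    return PolyhedronVertices(coords=coords)


@dataclass(frozen=True)
class MSHModel:
    """F electronic states on a shared bath of N modes, each extended to
    F-1 spatial dimensions.

    The nuclear potential of state X is

        V_X(R) = eps_X + sum_{i,j} (1/2) omega_j^2 (R_{i,j} + S_j^{(i,X)})^2

    with equilibrium shifts S_j^{(i,X)} = sqrt(2/N) d_X[i] / omega_j derived
    from the polyhedron vertices d_X, zero for i >= X. Coordinates are
    mass-weighted; arrays of shape (F-1, N).
    """

    bath: DiscretizedBath
    vertices: PolyhedronVertices
    electronic: ElectronicParams
    shifts: np.ndarray = field(init=False)  # (F, F-1, N)

    def __post_init__(self):
        F = self.vertices.f_states
        if self.electronic.f_states != F:
            raise InvalidInputError("electronic parameter count must match vertex count")
        N = self.bath.n_modes
        S = np.sqrt(2.0 / N) * self.vertices.coords[:, :, None] / self.bath.omegas[None, None, :]
        object.__setattr__(self, "shifts", S)

    @property
    def f_states(self) -> int:
        return self.vertices.f_states

    @property
    def n_modes(self) -> int:
        return self.bath.n_modes

    @property
    def nuclear_shape(self) -> tuple:
        return (self.f_states - 1, self.bath.n_modes)

    @property
    def n_dof(self) -> int:
        """Total nuclear DOF (F-1)*N."""
        return (self.f_states - 1) * self.bath.n_modes

    def mode_frequencies(self) -> np.ndarray:
        """Per-DOF frequencies, broadcast to the nuclear shape."""
        return np.broadcast_to(self.bath.omegas, self.nuclear_shape)

    def state_minimum(self, X: int) -> np.ndarray:
        """Nuclear configuration minimizing V_X."""
        return -self.shifts[X]

    def potential(self, X: int, R: np.ndarray) -> float:
        return msh_potential(self, X, R)

    def gradient(self, X: int, R: np.ndarray) -> np.ndarray:
        return msh_gradient(self, X, R)

    def potential_all(self, R: np.ndarray):
        """All state potentials and gradients at R: (V (F,), grad (F, F-1, N))."""
        R = np.asarray(R, dtype=float).reshape(self.nuclear_shape)
        w2 = self.bath.omegas**2
        disp = R[None, :, :] + self.shifts  # (F, F-1, N)
        V = self.electronic.epsilons + 0.5 * np.einsum("j,xij,xij->x", w2, disp, disp)
        grad = w2 * disp
        return V, grad

    def pairwise_reorg(self) -> np.ndarray:
        """Pairwise reorganization energies recomputed from the shifts."""
        w2 = self.bath.omegas**2
        dS = self.shifts[:, None, :, :] - self.shifts[None, :, :, :]
        return 0.5 * np.einsum("j,xyij,xyij->xy", w2, dS, dS)


def build_msh(
    bath: DiscretizedBath, vertices: PolyhedronVertices, electronic: ElectronicParams
) -> MSHModel:
    """Assemble an MSH model from a discretized bath, embedded polyhedron
    vertices, and electronic parameters."""
    return MSHModel(bath=bath, vertices=vertices, electronic=electronic)


def msh_potential(model: MSHModel, X: int, R: np.ndarray) -> float:
    """V_X(R) = eps_X + sum (1/2) omega_j^2 (R_{i,j} + S_j^{(i,X)})^2."""
    R = np.asarray(R, dtype=float).reshape(model.nuclear_shape)
    disp = R + model.shifts[X]
    return float(
        model.electronic.epsilons[X]
        + 0.5 * np.sum(model.bath.omegas**2 * disp * disp)
    )


def msh_gradient(model: MSHModel, X: int, R: np.ndarray) -> np.ndarray:
    """Analytic gradient of V_X with respect to R (shape (F-1, N))."""
    R = np.asarray(R, dtype=float).reshape(model.nuclear_shape)
    return model.bath.omegas**2 * (R + model.shifts[X])


def reaction_free_energy(gap_mean: float, er: float, direction: str = "forward") -> float:
    """Reaction free energy from the equilibrium gap average on the initial
    state and the pair reorganization energy.

    ``direction="forward"`` (default): DeltaE = <U_XY>_X - E_r, with
    U_XY = V_X - V_Y averaged on the initial-state surface X.
    ``direction="reverse"`` flips the sign convention of the gap:
    DeltaE = E_r - <U_XY>_X.
    """
    if direction == "forward":
        return gap_mean - er
    if direction == "reverse":
        return er - gap_mean
    raise InvalidInputError(f"unknown direction: {direction!r}")


@dataclass(frozen=True)
class FrenkelModel:
    """Isolated-bath (Frenkel-exciton-like) comparison model.

    Each of the F sites owns an independent bath of N modes and shifts only
    its own bath when excited, so the effective excited-excited
    reorganization between sites X and Y is Er(X,g) + Er(Y,g) by
    construction: interstate bath correlations cannot be represented.
    Nuclear coordinates have shape (F, N) -> total DOF F*N.
    """

    baths: tuple
    electronic: ElectronicParams

    def __post_init__(self):
        if len(self.baths) != self.electronic.f_states:
            raise InvalidInputError("need one bath per site")
        n = {b.n_modes for b in self.baths}
        if len(n) != 1:
            raise InvalidInputError("all site baths must have the same mode count")

    @property
    def f_states(self) -> int:
        return self.electronic.f_states

    @property
    def nuclear_shape(self) -> tuple:
        return (self.f_states, self.baths[0].n_modes)

    @property
    def n_dof(self) -> int:
        return self.f_states * self.baths[0].n_modes

    def mode_frequencies(self) -> np.ndarray:
        return np.stack([b.omegas for b in self.baths])

    def _omega2(self) -> np.ndarray:
        return self.mode_frequencies() ** 2

    def _shift(self, X: int) -> np.ndarray:
        S = np.zeros(self.nuclear_shape)
        S[X] = self.baths[X].req
        return S

    def state_minimum(self, X: int) -> np.ndarray:
        return -self._shift(X)

    def potential(self, X: int, R: np.ndarray) -> float:
        R = np.asarray(R, dtype=float).reshape(self.nuclear_shape)
        disp = R + self._shift(X)
        return float(self.electronic.epsilons[X] + 0.5 * np.sum(self._omega2() * disp * disp))

    def gradient(self, X: int, R: np.ndarray) -> np.ndarray:
        R = np.asarray(R, dtype=float).reshape(self.nuclear_shape)
        return self._omega2() * (R + self._shift(X))

    def potential_all(self, R: np.ndarray):
        R = np.asarray(R, dtype=float).reshape(self.nuclear_shape)
        F = self.f_states
        V = np.empty(F)
        grad = np.empty((F,) + self.nuclear_shape)
        for X in range(F):
            disp = R + self._shift(X)
            V[X] = self.electronic.epsilons[X] + 0.5 * np.sum(self._omega2() * disp * disp)
            grad[X] = self._omega2() * disp
        return V, grad

    def pairwise_reorg(self) -> np.ndarray:
        """Er(X,Y) realized by the independent baths: Er(X,g)+Er(Y,g)."""
        ers = np.array([b.er for b in self.baths])
        out = ers[:, None] + ers[None, :]
        np.fill_diagonal(out, 0.0)
        return out


def build_frenkel_model(per_site_baths, electronic: ElectronicParams) -> FrenkelModel:
    """Assemble the isolated-bath comparison model (one bath per site)."""
    return FrenkelModel(baths=tuple(per_site_baths), electronic=electronic)
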