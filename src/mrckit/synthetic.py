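"""Synthetic inputs and packaged fixtures.

Everything downstream of all-atom simulation is testable without downloads:
embeddable reorganization matrices come from random point clouds (embeddable
by construction), gap TCFs are synthesized consistently with a prescribed
spectral density, and the four-state molecular-triad parameter tables are
packaged verbatim with a clearly labeled synthetic stand-in bath.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .exceptions import InvalidInputError
from .msh import ElectronicParams, MSHModel, ReorgMatrix, build_msh, embed_polyhedron
from .spectral import DiscretizedBath, GapTCF, SpectralDensity, debye_density, discretize
from .units import CM1_TO_HARTREE, EV_TO_HARTREE, KCALMOL_TO_HARTREE

__all__ = [
    "random_point_cloud",
    "random_reorg_matrix",
    "synthetic_gap_tcf",
    "random_msh_fixture",
    "available_fixtures",
    "fixture_params",
    "triad_fixture",
    "packaged_fixtures",
]


def random_point_cloud(f_states: int, scale: float, seed: int) -> np.ndarray:
    """F zero-mean Gaussian points in F-1 dimensions (units sqrt(energy))."""
    if f_states < 2:
        raise InvalidInputError("need at least two states")
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((f_states, f_states - 1))


def random_reorg_matrix(f_states: int, scale: float, seed: int) -> ReorgMatrix:
    """Squared pairwise distances of a random point cloud: an embeddable
    reorganization matrix with zero Gram defect by construction."""
    pts = random_point_cloud(f_states, scale, seed)
    diff = pts[:, None, :] - pts[None, :, :]
    values = np.einsum("xyk,xyk->xy", diff, diff)
    np.fill_diagonal(values, 0.0)
    return ReorgMatrix(values=0.5 * (values + values.T))


def synthetic_gap_tcf(
    J: SpectralDensity, beta: float, t_grid: np.ndarray, n_quad: int = 4000
) -> GapTCF:
    """Gap TCF consistent with J under the package conventions:

        C(t) = (4/(pi*beta)) int_0^inf domega (J(omega)/omega) cos(omega t),

    so the forward cosine transform recovers J and beta*C(0)/2 recovers the
    reorganization energy carried by J.
    """
    t = np.asarray(t_grid, dtype=float)
    if J.kind == "tabulated":
        w = J.table[:, 0]
        w = w[w > 0]
    else:
        wc = J.params["omega_c"]
        w = np.linspace(wc * 1e-6, 50.0 * wc, n_quad)
    integrand = J(w) / w
    wt = np.gradient(w)
    C = (4.0 / (np.pi * beta)) * (np.cos(np.outer(t, w)) @ (wt * integrand))
    # pin C(0) to the closed-form reorganization integral of J so that
    # beta*C(0)/2 recovers E_r exactly (removes quadrature tail truncation)
    from .spectral import reorg_from_density

    c0_exact = 2.0 * reorg_from_density(J) / beta
    if C[0] > 0:
        C = C * (c0_exact / C[0])
    return GapTCF(times=t, values=C, beta=beta)


def _random_electronic(f_states: int, seed: int, ground_state: int | None) -> ElectronicParams:
    rng = np.random.default_rng(seed)
    eps = 0.3 * EV_TO_HARTREE * rng.standard_normal(f_states)
    gam = 0.02 * EV_TO_HARTREE * rng.standard_normal((f_states, f_states))
    gam = 0.5 * (gam + gam.T)
    np.fill_diagonal(gam, 0.0)
    if ground_state is not None:
        gam[ground_state, :] = 0.0
        gam[:, ground_state] = 0.0
        eps[ground_state] = 0.0
    return ElectronicParams(epsilons=eps, gammas=gam, ground_state=ground_state)


def random_msh_fixture(
    f_states: int,
    n_modes: int,
    seed: int,
    scale: float | None = None,
    omega_c: float = 200.0 * CM1_TO_HARTREE,
    omega_max: float | None = 1500.0 * CM1_TO_HARTREE,
    ground_state: int | None = None,
) -> MSHModel:
    """Seeded synthetic MSH model: random embeddable reorganization matrix,
    Debye bath discretized at the matrix scale, random electronic
    parameters. The default vertex-cloud scale puts pairwise reorganization
    energies at the ~10 kcal/mol magnitude typical of charge transfer in a
    polar solvent; the bath support is truncated at 1500 cm^-1, the
    vibrational range of condensed-phase molecular spectral densities (an
    untruncated Debye tail would place equal-share modes at ~5e4 cm^-1,
    which no molecular bath exhibits)."""
    if scale is None:
        scale = np.sqrt(10.0 * KCALMOL_TO_HARTREE / (2.0 * max(f_states - 1, 1)))
    er = random_reorg_matrix(f_states, scale, seed)
    lam = float(np.mean(er.values[np.triu_indices(f_states, 1)]))
    lam = max(lam, 1e-6)
    bath = discretize(debye_density(lam, omega_c), n_modes, er_total=lam, omega_max=omega_max)
    vertices = embed_polyhedron(er)
    electronic = _random_electronic(f_states, seed + 1, ground_state)
    return build_msh(bath, vertices, electronic)


_FIXTURE_NAMES = ("triad_conf3", "triad_conf5")


def available_fixtures() -> tuple:
    return _FIXTURE_NAMES


def fixture_params(name: str) -> dict:
    """Raw packaged fixture document (printed values, with units)."""
    if name not in _FIXTURE_NAMES:
        raise InvalidInputError(f"unknown fixture {name!r}; available: {_FIXTURE_NAMES}")
    with resources.files("mrckit.data").joinpath(f"{name}.json").open() as fh:
        return json.load(fh)


def _pairs_to_matrix(pairs: dict, f_states: int, factor: float) -> np.ndarray:
    out = np.zeros((f_states, f_states))
    for key, val in pairs.items():
        x, y = int(key[0]) - 1, int(key[1]) - 1
        out[x, y] = out[y, x] = val * factor
    return out


def triad_fixture(
    name: str = "triad_conf3",
    n_modes: int | None = None,
) -> MSHModel:
    """Four-state molecular-triad MSH model from the packaged parameter
    table (energies converted to a.u. at load) with its synthetic Debye
    stand-in bath."""
    doc = fixture_params(name)
    F = len(doc["states"])
    eps = np.asarray(doc["epsilons"]["values"]) * EV_TO_HARTREE
    gam = _pairs_to_matrix(doc["gammas"]["pairs"], F, EV_TO_HARTREE)
    er = ReorgMatrix(
        values=_pairs_to_matrix(doc["reorg"]["pairs"], F, KCALMOL_TO_HARTREE),
        labels=tuple(doc["states"]),
    )
    electronic = ElectronicParams(epsilons=eps, gammas=gam, ground_state=doc["ground_state"])
    b = doc["bath"]
    N = n_modes if n_modes is not None else b["n_modes"]
    lam = float(np.mean(er.values[np.triu_indices(F, 1)]))
    bath = discretize(
        debye_density(lam, b["omega_c_cm1"] * CM1_TO_HARTREE),
        N,
        er_total=lam,
        omega_max=b["omega_max_cm1"] * CM1_TO_HARTREE,
    )
    return build_msh(bath, embed_polyhedron(er, on_defect="clip"), electronic)


def packaged_fixtures() -> dict:
    """All packaged named models."""
    return {name: triad_fixture(name) for name in _FIXTURE_NAMES}
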