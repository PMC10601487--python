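"""Model serialization (versioned JSON documents) and trajectory output.

A model document is a single structured text file:

* ``"format": "mrckit-model-1"`` with ``"kind": "msh"`` blocks
  {states, reorg_matrix, epsilons, gammas, ground_state, bath{omegas, er},
  vertices}, all numbers in atomic units, or
* ``"kind": "mrc"`` blocks {omega_rc, bath_omegas, bath_couplings,
  primary_shifts, basis_matrix (optional), er_ref, epsilons, gammas}.

JSON floats round-trip at full double precision (shortest-roundtrip repr).
Trajectory ensembles go to columnar delimited text (small) or ``.npz``
(large, runtime only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError
from .mrc import MRCModel
from .msh import ElectronicParams, MSHModel, PolyhedronVertices, build_msh
from .spectral import DiscretizedBath

__all__ = ["read_model", "write_model", "model_to_doc", "model_from_doc", "write_trace"]

FORMAT_VERSION = "mrckit-model-1"


def model_to_doc(model, store_basis: bool = True) -> dict:
    """Serialize an MSH or MRC model to a plain dict (JSON-ready)."""
    el = model.electronic
    doc = {
        "format": FORMAT_VERSION,
        "units": "au",
        "epsilons": el.epsilons.tolist(),
        "gammas": el.gammas.tolist(),
        "ground_state": el.ground_state,
    }
    if isinstance(model, MSHModel):
        doc["kind"] = "msh"
        doc["bath"] = {
            "omegas": model.bath.omegas.tolist(),
            "er": model.bath.er,
            "n_modes": model.bath.n_modes,
        }
        doc["vertices"] = model.vertices.coords.tolist()
        doc["reorg_matrix"] = model.vertices.squared_distances().tolist()
    elif isinstance(model, MRCModel):
        doc["kind"] = "mrc"
        doc["omega_rc"] = model.omega_rc
        doc["bath_omegas"] = model.bath_omegas.tolist()
        doc["bath_couplings"] = model.bath_couplings.tolist()
        doc["primary_shifts"] = model.primary_shifts.tolist()
        doc["er_ref"] = model.er_ref
        doc["basis_matrix"] = (
            model.basis_matrix.tolist() if (store_basis and model.basis_matrix is not None) else None
        )
    else:
        raise InvalidInputError(f"cannot serialize {type(model).__name__}")
    return doc


def _check_positive(values, name):
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(arr <= 0)
    if bad.size:
        raise InvalidInputError(f"{name}[{bad[0]}] = {arr[bad[0]]} must be positive")
    return arr


def model_from_doc(doc: dict):
    """Rebuild a model from its document; kind auto-detected."""
    version = doc.get("format")
    if version != FORMAT_VERSION:
        raise InvalidInputError(
            f"unsupported model document version {version!r} (expected {FORMAT_VERSION!r})"
        )
    missing = [k for k in ("epsilons", "gammas", "kind") if k not in doc]
    if missing:
        raise InvalidInputError(f"model document missing fields: {missing}")
    electronic = ElectronicParams(
        epsilons=np.asarray(doc["epsilons"], float),
        gammas=np.asarray(doc["gammas"], float),
        ground_state=doc.get("ground_state"),
    )
    if doc["kind"] == "msh":
        bath = DiscretizedBath(
            omegas=_check_positive(doc["bath"]["omegas"], "bath.omegas"),
            er=float(doc["bath"]["er"]),
        )
        vertices = PolyhedronVertices(coords=np.asarray(doc["vertices"], float))
        return build_msh(bath, vertices, electronic)
    if doc["kind"] == "mrc":
        basis = doc.get("basis_matrix")
        return MRCModel(
            omega_rc=float(doc["omega_rc"]),
            bath_omegas=_check_positive(doc["bath_omegas"], "bath_omegas"),
            bath_couplings=np.asarray(doc["bath_couplings"], float),
            primary_shifts=np.asarray(doc["primary_shifts"], float),
            electronic=electronic,
            basis_matrix=None if basis is None else np.asarray(basis, float),
            er_ref=float(doc.get("er_ref", 1.0)),
        )
    raise InvalidInputError(f"unknown model kind {doc['kind']!r}")


def write_model(model, path, store_basis: bool = True) -> None:
    Path(path).write_text(json.dumps(model_to_doc(model, store_basis=store_basis)) + "\n")


def read_model(path):
    """Read an MSH or MRC model document; raises a validation error naming
    the offending field for malformed input."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InvalidInputError(f"{path}: not valid JSON ({exc})") from exc
    return model_from_doc(doc)


def write_trace(trace, path, coherences: bool = False) -> None:
    """Columnar text output: time_fs, populations, optional Re/Im
    coherences, and mean RC components when present."""
    F = trace.sigma.shape[1]
    cols = [trace.times] + [trace.populations[:, X] for X in range(F)]
    header = ["time_fs"] + [f"sigma_{X+1}{X+1}" for X in range(F)]
    if coherences:
        for X in range(F):
            for Y in range(X + 1, F):
                cols += [trace.sigma[:, X, Y].real, trace.sigma[:, X, Y].imag]
                header += [f"re_sigma_{X+1}{Y+1}", f"im_sigma_{X+1}{Y+1}"]
    if trace.rc_mean is not None:
        for i in range(trace.rc_mean.shape[1]):
            cols.append(trace.rc_mean[:, i])
            header.append(f"y_{i+1}")
    np.savetxt(
        path,
        np.column_stack(cols),
        header=" ".join(header) + f"  (n_traj={trace.n_traj})",
        fmt="%.12g",
    )
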