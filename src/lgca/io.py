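"""Serialisation: environment fields from CSV, trajectories to HDF5/CSV.

Environment-field CSVs have one row per node in flat row-major node order:
a single column for scalar signal concentrations, ``d`` columns for vector
fields.  Kymograph CSVs are time × node total density with 17 significant
digits so a reload is lossless.  HDF5 trajectory files carry the occupation
array plus density and flux summaries and provenance metadata (seed, config
hash, geometry).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError, StructuralError
from .lattice import LatticeGeometry, LatticeState
from .operators import Trajectory

__all__ = [
    "read_scalar_field",
    "read_vector_field",
    "export_kymograph",
    "export_trajectory_h5",
    "load_trajectory_h5",
]

_FMT = "%.17g"


def read_scalar_field(path: str | Path, geometry: LatticeGeometry) -> np.ndarray:
    """Scalar per-node field (e.g. signal concentration) from one-column CSV."""
    values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=1)
    if values.ndim != 1 or values.size != geometry.n_nodes:
        raise StructuralError(
            f"scalar field file {path} has {values.size} values, "
            f"expected {geometry.n_nodes} (one row per node)"
        )
    return values.reshape(geometry.shape)


def read_vector_field(path: str | Path, geometry: LatticeGeometry) -> np.ndarray:
    """Vector per-node field E from a d-column CSV in flat node order."""
    values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    if values.shape != (geometry.n_nodes, geometry.dimension):
        raise StructuralError(
            f"vector field file {path} has shape {values.shape}, expected "
            f"({geometry.n_nodes}, {geometry.dimension})"
        )
    return values.reshape(geometry.shape + (geometry.dimension,))


def export_kymograph(trajectory: Trajectory, path: str | Path) -> None:
    """Write the time × node total-density kymograph as CSV.

    For 2D lattices nodes are flattened in row-major order, one column per
    node; rows are time steps (steps + 1 rows).
    """
    if trajectory.occupancy.shape[0] == 0:
        raise ConfigurationError("empty trajectory")
    density = trajectory.density().reshape(trajectory.occupancy.shape[0], -1)
    np.savetxt(path, density, delimiter=",", fmt=_FMT)


def export_trajectory_h5(
    trajectory: Trajectory,
    path: str | Path,
    config_hash: str | None = None,
    extra_attrs: dict | None = None,
) -> None:
    """Write occupations, density and flux datasets plus provenance metadata."""
    g = trajectory.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("occupancy", data=trajectory.occupancy, compression=None)
        f.create_dataset("density", data=trajectory.density())
        f.create_dataset("flux", data=trajectory.flux())
        f.attrs["geometry"] = json.dumps(
            {
                "dimension": g.dimension,
                "shape": list(g.shape),
                "a": g.a,
                "phenotypes": g.phenotypes,
                "boundary": g.boundary,
            }
        )
        if trajectory.seed is not None:
            f.attrs["seed"] = trajectory.seed
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash
        for key, value in (extra_attrs or {}).items():
            f.attrs[key] = value


def load_trajectory_h5(path: str | Path) -> Trajectory:
    """Reload a trajectory written by :func:`export_trajectory_h5`."""
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["geometry"])
        geometry = LatticeGeometry(
            dimension=meta["dimension"],
            shape=tuple(meta["shape"]),
            a=meta["a"],
            phenotypes=meta["phenotypes"],
            boundary=meta["boundary"],
        )
        occ = f["occupancy"][...]
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    return Trajectory(geometry=geometry, occupancy=occ, seed=seed)
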