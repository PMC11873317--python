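"""Reading and writing path ensembles and problem configurations.

Ensemble formats:

* HDF5 — datasets ``values`` (N x T float64) and ``times`` (T float64);
* CSV — first row is the time vector, each subsequent row one path.

Readers validate that the time grid is equidistant.  Problem definitions
can be loaded from YAML (name, params, grid, initial spec, n_paths, seed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import yaml

from .sde import (InitialDistribution, PathEnsemble, SDEProblem, TimeGrid,
                  make_benchmark_problem)

__all__ = [
    "read_ensemble",
    "write_ensemble",
    "problem_from_config",
    "load_problem_yaml",
]


def write_ensemble(ensemble: PathEnsemble, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=ensemble.array, dtype="float64")
            f.create_dataset("times", data=ensemble.grid.times, dtype="float64")
    elif path.suffix == ".csv":
        out = np.vstack([ensemble.grid.times, ensemble.array])
        np.savetxt(path, out, delimiter=",")
    else:
        raise ValueError(f"unsupported ensemble format {path.suffix!r}")


def read_ensemble(path: Union[str, Path]) -> PathEnsemble:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = np.asarray(f["values"], dtype=np.float64)
            times = np.asarray(f["times"], dtype=np.float64)
    elif path.suffix == ".csv":
        raw = np.loadtxt(path, delimiter=",", ndmin=2)
        times, values = raw[0], raw[1:]
    else:
        raise ValueError(f"unsupported ensemble format {path.suffix!r}")
    return PathEnsemble(values=values, grid=TimeGrid(times))


def _initial_from_spec(spec: dict) -> InitialDistribution:
    kind = spec["kind"]
    if kind == "normal":
        return InitialDistribution.normal(spec["mean"], spec["sd"])
    if kind == "exponential":
        return InitialDistribution.exponential(spec["rate"])
    if kind == "point":
        return InitialDistribution.point(spec["value"])
    raise ValueError(f"unknown initial distribution kind {kind!r}")


def problem_from_config(cfg: dict) -> SDEProblem:
    """Build a benchmark problem from a parsed configuration mapping.

    Keys: ``name``; optional ``params`` mapping, ``grid`` (t0, t1, n),
    ``initial`` (kind + parameters).
    """
    grid = None
    if "grid" in cfg:
        g = cfg["grid"]
        grid = TimeGrid.regular(g["t0"], g["t1"], g["n"])
    initial = _initial_from_spec(cfg["initial"]) if "initial" in cfg else None
    return make_benchmark_problem(cfg["name"], cfg.get("params"), grid, initial)


def load_problem_yaml(path: Union[str, Path]) -> tuple[SDEProblem, dict]:
    """Load a problem plus the raw config (n_paths, seed, ...) from YAML."""
    cfg = yaml.safe_load(Path(path).read_text())
    return problem_from_config(cfg), cfg
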