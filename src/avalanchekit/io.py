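"""Plain-text readers and writers.

Series and tables are tab-delimited text with a header line; structured
metadata (parameters, seeds, fit reports) is JSON.  Floats are written
with 17 significant digits so every round trip is value-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import ModelParams
from .gillespie import EnsembleResult, Trajectory
from .avalanche import AvalancheRecord
from .phase import PhaseGrid

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_ensemble", "read_ensemble",
    "write_avalanches", "read_avalanches",
    "write_phase_grid", "read_phase_grid",
    "read_series",
]

_FMT = "%.17g"


def _params_dict(p: ModelParams) -> dict:
    return {"mu": p.mu, "nu": p.nu, "delta": p.delta}


def _params_from(d: dict) -> ModelParams:
    return ModelParams(mu=d["mu"], nu=d["nu"], delta=d["delta"])


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write event table (u, x, y, N) plus a `.json` sidecar."""
    path = Path(path)
    data = np.column_stack([traj.times, traj.x, traj.y, traj.n])
    np.savetxt(path, data, fmt=[_FMT, "%d", "%d", "%d"], delimiter="\t",
               header="u\tx\ty\tN", comments="")
    sidecar = {
        "params": _params_dict(traj.params),
        "seed": traj.seed,
        "terminated_by": traj.terminated_by,
        "horizon": traj.horizon,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Trajectory(
        times=data[:, 0],
        x=data[:, 1].astype(np.int64),
        y=data[:, 2].astype(np.int64),
        params=_params_from(meta["params"]),
        seed=int(meta["seed"]),
        terminated_by=meta["terminated_by"],
        horizon=float(meta["horizon"]),
    )


def write_ensemble(res: EnsembleResult, path: str | Path) -> None:
    doc = {
        "params": _params_dict(res.params),
        "cap": res.cap,
        "base_seed": res.base_seed,
        "init_rule": res.init_rule,
        "realizations": res.realizations,
        "mean_T": res.mean_T,
        "extinction_times": res.extinction_times.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ensemble(path: str | Path) -> EnsembleResult:
    doc = json.loads(Path(path).read_text())
    return EnsembleResult(
        extinction_times=np.asarray(doc["extinction_times"], dtype=float),
        params=_params_from(doc["params"]),
        cap=float(doc["cap"]),
        base_seed=int(doc["base_seed"]),
        init_rule=doc["init_rule"],
    )


def write_avalanches(records: list[AvalancheRecord], path: str | Path) -> None:
    rows = [(r.start_u, r.end_u, r.duration_t, r.size_S, r.peak_value) for r in records]
    data = np.asarray(rows, dtype=float).reshape(-1, 5)
    np.savetxt(path, data, fmt=[_FMT] * 4 + ["%d"], delimiter="\t",
               header="start_u\tend_u\tduration_t\tsize_S\tpeak_value", comments="")


def read_avalanches(path: str | Path) -> list[AvalancheRecord]:
    if len(Path(path).read_text().splitlines()) <= 1:
        return []
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.size == 0:
        return []
    return [
        AvalancheRecord(start_u=row[0], end_u=row[1], size_S=row[3], peak_value=int(row[4]))
        for row in data
    ]


def write_phase_grid(grid: PhaseGrid, path: str | Path) -> None:
    """JSON metadata + embedded matrices (text-only, round-trip exact)."""
    doc = {
        "excitation_axis": grid.excitation_axis.tolist(),
        "nu_axis": grid.nu_axis.tolist(),
        "mean_T": grid.mean_T.tolist(),
        "realizations": grid.realizations.tolist(),
        "delta": grid.delta,
        "cap": grid.cap,
        "base_seed": grid.base_seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_phase_grid(path: str | Path) -> PhaseGrid:
    doc = json.loads(Path(path).read_text())
    return PhaseGrid(
        excitation_axis=np.asarray(doc["excitation_axis"], dtype=float),
        nu_axis=np.asarray(doc["nu_axis"], dtype=float),
        mean_T=np.asarray(doc["mean_T"], dtype=float),
        realizations=np.asarray(doc["realizations"], dtype=np.int64),
        delta=float(doc["delta"]),
        cap=float(doc["cap"]),
        base_seed=int(doc["base_seed"]),
    )


def read_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a uniformly sampled two-column (u, N) text series.

    Accepts tab-, comma- or whitespace-delimited text with or without a
    header line; supports re-analysis of user-supplied count series.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] or ("," in text) else None
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError:
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("series file must have two columns (u, N)")
    return data[:, 0], data[:, 1]
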