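"""Reading and writing systems and trajectories.

System files are JSON or YAML mappings with keys ``labels``, ``matrix``
(row-major), ``growth_rates`` and an explicit ``orientation`` field
("row=affected,column=acting") so that a transposed matrix can never be
loaded silently.  A CSV variant carries the same orientation statement
in a leading comment line.  Numbers are serialized at full double
precision, so round-trips are bit-exact.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EcoGameSystem, LVGamesError, MATRIX_ORIENTATION, Trajectory

__all__ = ["system_to_dict", "system_from_dict", "save_system", "load_system",
           "save_trajectory", "load_trajectory"]


def _fmt(x: float) -> float:
    return float(x)


def system_to_dict(sys: EcoGameSystem) -> dict:
    return {
        "format": "lvgames-system",
        "orientation": MATRIX_ORIENTATION,
        "labels": list(sys.labels),
        "matrix": [[_fmt(v) for v in row] for row in sys.matrix],
        "growth_rates": [_fmt(v) for v in sys.rates],
    }


def system_from_dict(d: dict) -> EcoGameSystem:
    orientation = d.get("orientation", MATRIX_ORIENTATION)
    if orientation != MATRIX_ORIENTATION:
        raise LVGamesError(
            f"unsupported matrix orientation {orientation!r}; expected {MATRIX_ORIENTATION!r}")
    try:
        return EcoGameSystem.from_arrays(d["matrix"], d["growth_rates"],
                                         tuple(d.get("labels", ())))
    except KeyError as exc:
        raise LVGamesError(f"system file missing key {exc}") from None


def save_system(sys: EcoGameSystem, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(system_to_dict(sys), sort_keys=False))
    elif path.suffix == ".csv":
        _save_system_csv(sys, path)
    else:
        path.write_text(json.dumps(system_to_dict(sys), indent=2) + "\n")


def load_system(path) -> EcoGameSystem:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".csv":
        return _load_system_csv(text)
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return system_from_dict(data)


def _save_system_csv(sys: EcoGameSystem, path: Path) -> None:
    lines = [f"# lvgames-system; orientation: {MATRIX_ORIENTATION}"]
    lines.append(",".join(["label", *sys.labels, "growth_rate"]))
    for i, lab in enumerate(sys.labels):
        row = [repr(float(v)) for v in sys.matrix[i]]
        lines.append(",".join([lab, *row, repr(float(sys.rates[i]))]))
    path.write_text("\n".join(lines) + "\n")


def _load_system_csv(text: str) -> EcoGameSystem:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or "orientation" not in lines[0]:
        raise LVGamesError("system CSV must begin with an orientation comment line")
    if MATRIX_ORIENTATION not in lines[0]:
        raise LVGamesError(f"unsupported orientation in CSV header: {lines[0]!r}")
    header = lines[1].split(",")
    labels = tuple(header[1:-1])
    matrix, rates, row_labels = [], [], []
    for ln in lines[2:]:
        parts = ln.split(",")
        row_labels.append(parts[0])
        matrix.append([float(v) for v in parts[1:-1]])
        rates.append(float(parts[-1]))
    if tuple(row_labels) != labels:
        raise LVGamesError("system CSV row labels must match column labels")
    return EcoGameSystem.from_arrays(matrix, rates, labels)


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (t plus one column per type; lossless floats)."""
    path = Path(path)
    if traj.dynamics_kind == "coupled":
        labels = list(traj.system.labels) if traj.system else \
            [f"x{i + 1}" for i in range(traj.values.shape[1] - 1)]
        cols = [f"x_{lab}" for lab in labels] + ["N"]
    else:
        m = traj.values.shape[1]
        labels = list(traj.system.labels) if traj.system else [f"T{i + 1}" for i in range(m)]
        cols = labels
    df = pd.DataFrame(traj.values, columns=cols)
    df.insert(0, "t", traj.times)
    with open(path, "w") as fh:
        fh.write(f"# dynamics_kind: {traj.dynamics_kind}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# dynamics_kind:"):
            raise LVGamesError("trajectory CSV must start with a dynamics_kind comment")
        kind = first.split(":", 1)[1].strip()
        df = pd.read_csv(fh, float_precision="round_trip")
    times = df["t"].to_numpy()
    values = df.drop(columns="t").to_numpy()
    return Trajectory(times, values, kind)
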