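"""Configuration handling and file formats.

Everything the package writes is plain text: RFC-4180 CSV with ``#``-prefixed
header metadata lines (package version, seed, config hash) and JSON sidecars
for grid/axis metadata.  Deterministic stages re-run with identical
configuration reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import CommunityParams, make_params
from .spatial import SpatialState
from .wellmixed import PhaseDiagram, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "load_params_json",
    "config_hash",
    "write_trajectory",
    "read_trajectory",
    "write_phase_diagram",
    "read_phase_diagram",
    "write_snapshot",
    "read_snapshot",
]

_TRAJ_COLUMNS = ["time", "u_A", "u_B", "c_A", "c_B"]


@dataclass
class RunConfig:
    """Effective configuration of one CLI run, serialized for provenance."""

    subcommand: str
    params_file: str | None = None
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.overrides.items():
            if key.endswith(("tol", "tolerance")) and float(value) <= 0:
                raise ValueError(f"override {key!r} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig | dict) -> str:
    """Short stable hash of a configuration for file headers."""
    payload = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **flags) -> RunConfig:
    """Build a :class:`RunConfig` from a JSON file, flags, or both.

    Flag values win over file values (a warning is emitted on conflict);
    unknown keys in the file are rejected by name.
    """
    import warnings

    data: dict = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in flags.items():
        if value is None:
            continue
        if key in data and data[key] != value:
            warnings.warn(
                f"flag overrides config file for {key!r}: {data[key]!r} -> {value!r}",
                stacklevel=2,
            )
        data[key] = value
    return RunConfig(**data)


def load_params_json(path: str | Path) -> CommunityParams:
    """Read a flat JSON parameter file through :func:`make_params`."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("parameter file must hold a flat JSON object")
    return make_params(raw)


def _header_lines(kind: str, meta: dict) -> str:
    head = {"format": kind, "version": __version__, **meta}
    return "".join(f"# {k} = {v}\n" for k, v in head.items())


def write_trajectory(
    traj: Trajectory, path: str | Path, meta: dict | None = None
) -> Path:
    """Trajectory as CSV with columns time,u_A,u_B,c_A,c_B."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([traj.times, traj.states]), columns=_TRAJ_COLUMNS
    )
    with path.open("w", newline="") as fh:
        fh.write(_header_lines("trajectory", meta or {}))
        df.to_csv(fh, index=False)
    return path


def read_trajectory(path: str | Path, params: CommunityParams | None = None) -> Trajectory:
    df = pd.read_csv(path, comment="#")
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file lacks columns {sorted(missing)}")
    return Trajectory(
        times=df["time"].to_numpy(),
        states=df[_TRAJ_COLUMNS[1:]].to_numpy(),
        params=params or CommunityParams(),
        meta={"source": str(path)},
    )


def write_phase_diagram(pd_grid: PhaseDiagram, path: str | Path) -> tuple[Path, Path]:
    """Phase grid as CSV plus a JSON axis sidecar (``<path>.axes.json``)."""
    path = Path(path)
    df = pd.DataFrame(
        pd_grid.values,
        index=pd.Index(pd_grid.axis1_values, name=pd_grid.axis1_name),
        columns=pd.Index(pd_grid.axis2_values, name=pd_grid.axis2_name),
    )
    with path.open("w", newline="") as fh:
        fh.write(_header_lines("phase_diagram", {"mode": pd_grid.mode}))
        df.to_csv(fh)
    sidecar = path.with_suffix(path.suffix + ".axes.json")
    sidecar.write_text(json.dumps({
        "axis1_name": pd_grid.axis1_name,
        "axis1_values": list(map(float, pd_grid.axis1_values)),
        "axis2_name": pd_grid.axis2_name,
        "axis2_values": list(map(float, pd_grid.axis2_values)),
        "mode": pd_grid.mode,
        "base_params": dataclasses.asdict(pd_grid.base_params),
    }, indent=2))
    return path, sidecar


def read_phase_diagram(path: str | Path) -> PhaseDiagram:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".axes.json").read_text())
    df = pd.read_csv(path, comment="#", index_col=0)
    values = df.to_numpy()
    if sidecar["mode"] == "rho_c":
        values = values.astype(float)
    return PhaseDiagram(
        axis1_name=sidecar["axis1_name"],
        axis1_values=np.asarray(sidecar["axis1_values"]),
        axis2_name=sidecar["axis2_name"],
        axis2_values=np.asarray(sidecar["axis2_values"]),
        mode=sidecar["mode"],
        values=values,
        base_params=CommunityParams(**sidecar["base_params"]),
    )


def write_snapshot(state: SpatialState, path: str | Path, time: float = 0.0) -> Path:
    """Spatial snapshot as CSV.

    1D grids use columns x,u_A,u_B,c_A,c_B; 2D grids are written long-form
    with columns y,x,u_A,u_B,c_A,c_B.  Grid metadata (shape, spacing, time)
    goes in the ``#`` header.
    """
    path = Path(path)
    meta = {"shape": "x".join(map(str, state.shape)), "h": state.h, "time": time}
    if state.ndim == 1:
        x = np.arange(state.shape[0]) * state.h
        df = pd.DataFrame({
            "x": x, "u_A": state.u_A, "u_B": state.u_B,
            "c_A": state.c_A, "c_B": state.c_B,
        })
    else:
        yy, xx = np.mgrid[0:state.shape[0], 0:state.shape[1]]
        df = pd.DataFrame({
            "y": yy.ravel() * state.h, "x": xx.ravel() * state.h,
            "u_A": state.u_A.ravel(), "u_B": state.u_B.ravel(),
            "c_A": state.c_A.ravel(), "c_B": state.c_B.ravel(),
        })
    with path.open("w", newline="") as fh:
        fh.write(_header_lines("snapshot", meta))
        df.to_csv(fh, index=False)
    return path


def read_snapshot(path: str | Path) -> SpatialState:
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            header[key.strip()] = value.strip()
    shape = tuple(int(v) for v in header["shape"].split("x"))
    h = float(header["h"])
    df = pd.read_csv(path, comment="#")
    fields = [df[name].to_numpy().reshape(shape) for name in ("u_A", "u_B", "c_A", "c_B")]
    return SpatialState(*fields, h=h)
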