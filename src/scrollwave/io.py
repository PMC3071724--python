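"""Configuration files, state persistence and export formats.

* Scenario configs: a TOML dialect (read with :mod:`tomllib`, written by a
  small serializer here) mapping one-to-one onto
  :class:`scrollwave.protocols.ScenarioConfig`.
* Tissue state: HDF5 with the layout ``/V``, ``/gates/<name>``,
  ``/conc/<name>`` and ``/meta`` attributes (grid, time, config hash).
  Checkpoints store float64 (bit-faithful restart); snapshots store float32.
* Volumes: legacy-ASCII VTK structured points, readable by standard VTK tools.
* Runs: a JSON manifest with the resolved config hash and output inventory.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import kernels
from .cell import GATE_NAMES
from .geometry import GridSpec, Inhomogeneity, TransmuralLayout
from .protocols import ScenarioConfig
from .solver import Stimulus, TissueState

__all__ = ["load_config", "save_config", "config_hash", "write_state", "read_state",
           "write_frames", "read_frames", "export_vtk", "RunManifest"]

_CONC_NAMES = ("Na_i", "K_i", "Ca_i", "Ca_SR")


class SnapshotError(RuntimeError):
    """A state file is corrupt, partial, or inconsistent with its metadata."""


# ---------------------------------------------------------------------------
# TOML scenario configs
# ---------------------------------------------------------------------------

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _emit_table(name: str, d: dict, out: list, array_of_tables: bool = False):
    head = f"[[{name}]]" if array_of_tables else f"[{name}]"
    out.append(head)
    for k, v in d.items():
        if v is None:
            continue
        out.append(f"{k} = {_toml_value(v)}")
    out.append("")


def save_config(scenario: ScenarioConfig, path) -> Path:
    """Serialize a scenario to the TOML dialect (round-trips via load_config)."""
    out: list[str] = []
    _emit_table("scenario", {
        "name": scenario.name, "variant": scenario.variant,
        "cell_type": scenario.cell_type, "initial": scenario.initial,
        "s2_time": scenario.s2_time, "duration": scenario.duration,
    }, out)
    if scenario.param_scales:
        _emit_table("scenario.param_scales", scenario.param_scales, out)
    _emit_table("grid", {"nx": scenario.nx, "ny": scenario.ny, "nz": scenario.nz,
                         "dx": scenario.dx, "dz": scenario.dz}, out)
    _emit_table("fibers", {"dtheta_total_deg": scenario.dtheta_total_deg}, out)
    _emit_table("diffusivity", {"D_par": scenario.D_par, "D_perp": scenario.D_perp,
                                "D_trans": scenario.D_trans}, out)
    _emit_table("numerics", {"dt": scenario.dt, "method": scenario.method,
                             "cross_terms": scenario.cross_terms,
                             "physics": scenario.physics,
                             "allow_unstable": scenario.allow_unstable}, out)
    _emit_table("output", {"probes": [list(p) for p in scenario.probes],
                           "probe_interval": scenario.probe_interval,
                           "frame_interval": scenario.frame_interval,
                           "record": scenario.record,
                           "record_slice": scenario.record_slice}, out)
    if scenario.transmural is not None:
        t = scenario.transmural
        _emit_table("transmural", {"w_endo": t.w_endo, "w_mid": t.w_mid,
                                   "w_epi": t.w_epi}, out)
    for inhom in scenario.inhomogeneities:
        _emit_table("inhomogeneity", {
            "kind": inhom.kind, "center": list(inhom.center), "radius": inhom.radius,
            "D_obs": inhom.D_obs, "V_obs": inhom.V_obs,
            "target": inhom.target, "scale": inhom.scale}, out, array_of_tables=True)
    for st in scenario.stimuli:
        _emit_table("stimulus", {"box": [list(b) for b in st.box],
                                 "amplitude": st.amplitude, "start": st.start,
                                 "duration": st.duration}, out, array_of_tables=True)
    path = Path(path)
    path.write_text("\n".join(out))
    return path


def load_config(path) -> ScenarioConfig:
    """Parse and validate a TOML scenario file into a resolved ScenarioConfig.

    A file whose ``[scenario]`` table only names a registry entry resolves to
    that scenario's full defaults; any other table overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with path.open("rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as e:
        raise ValueError(f"TOML parse error in {path}: {e}") from e

    sc = dict(raw.get("scenario", {}))
    name = sc.pop("name", "custom")
    kwargs: dict = {}
    from .protocols import _REGISTRY, build_scenario
    if name in _REGISTRY:
        base = build_scenario(name)
        kwargs = {f.name: getattr(base, f.name)
                  for f in dataclasses.fields(ScenarioConfig)}
    kwargs["name"] = name
    scales = sc.pop("param_scales", None)
    if scales:
        kwargs["param_scales"] = dict(scales)
    for k, v in sc.items():
        _set_field(kwargs, k, v, "scenario")
    for k, v in raw.get("grid", {}).items():
        _set_field(kwargs, k, v, "grid")
    for k, v in raw.get("fibers", {}).items():
        _set_field(kwargs, k, v, "fibers")
    for k, v in raw.get("diffusivity", {}).items():
        _set_field(kwargs, k, v, "diffusivity")
    for k, v in raw.get("numerics", {}).items():
        _set_field(kwargs, k, v, "numerics")
    out_tab = dict(raw.get("output", {}))
    if "probes" in out_tab:
        out_tab["probes"] = [tuple(int(x) for x in p) for p in out_tab["probes"]]
    for k, v in out_tab.items():
        _set_field(kwargs, k, v, "output")
    if "transmural" in raw:
        kwargs["transmural"] = TransmuralLayout(**raw["transmural"])
    if "inhomogeneity" in raw:
        kwargs["inhomogeneities"] = [
            Inhomogeneity(**{**d, "center": tuple(d["center"])})
            for d in raw["inhomogeneity"]]
    if "stimulus" in raw:
        kwargs["stimuli"] = [
            Stimulus(box=tuple(tuple(int(x) for x in b) for b in d.pop("box")), **d)
            for d in raw["stimulus"]]
    cfg = ScenarioConfig(**kwargs)
    _validate(cfg)
    return cfg


def _set_field(kwargs: dict, key: str, value, table: str):
    if key not in ScenarioConfig.__dataclass_fields__:
        raise ValueError(f"unknown config key '{table}.{key}'")
    kwargs[key] = value


def _validate(cfg: ScenarioConfig):
    grid = cfg.grid()   # raises ConfigError on bad counts/spacings
    if cfg.transmural is not None:
        from .geometry import assign_transmural
        assign_transmural(grid, cfg.transmural)   # checks widths vs thickness
    for p in cfg.probes:
        if not (0 <= p[0] < grid.nx and 0 <= p[1] < grid.ny and 0 <= p[2] < grid.nz):
            raise ValueError(f"output.probes entry {p} lies outside the grid")
    if cfg.dt <= 0:
        raise ValueError("numerics.dt must be positive")
    cfg.cell_params()   # validates variant name and scale keys


def config_hash(scenario: ScenarioConfig) -> str:
    """Stable hash of the resolved scenario (key order independent)."""

    def norm(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: norm(v) for k, v in sorted(dataclasses.asdict(obj).items())}
        if isinstance(obj, dict):
            return {k: norm(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [norm(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    blob = json.dumps(norm(scenario), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# HDF5 state and frame storage
# ---------------------------------------------------------------------------

def write_state(path, state: TissueState, grid: GridSpec, precision: str = "double",
                meta: dict | None = None) -> Path:
    """Write a tissue state (``/V``, ``/gates/*``, ``/conc/*``, ``/meta``).

    ``precision='double'`` is a checkpoint (bit-faithful restart);
    ``'single'`` is a compact snapshot.
    """
    dtype = np.float64 if precision == "double" else np.float32
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("V", data=state.S[0].astype(dtype))
        gates = f.create_group("gates")
        for gi, name in enumerate(GATE_NAMES):
            gates.create_dataset(name, data=state.S[1 + gi].astype(dtype))
        conc = f.create_group("conc")
        for ci, name in enumerate(_CONC_NAMES):
            conc.create_dataset(name, data=state.S[13 + ci].astype(dtype))
        m = f.create_group("meta")
        m.attrs["t"] = state.t
        m.attrs["shape"] = grid.shape
        m.attrs["dx"] = grid.dx
        m.attrs["dz"] = grid.dz
        m.attrs["precision"] = precision
        m.attrs["complete"] = True
        for k, v in (meta or {}).items():
            m.attrs[k] = v
    return path


def read_state(path, grid: GridSpec | None = None) -> tuple[TissueState, dict]:
    """Read a state written by :func:`write_state`; verifies shape metadata."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "meta" not in f or not f["meta"].attrs.get("complete", False):
                raise SnapshotError(f"{path}: missing or incomplete metadata")
            meta = dict(f["meta"].attrs)
            shape = tuple(int(x) for x in meta["shape"])
            if grid is not None and shape != grid.shape:
                raise SnapshotError(
                    f"{path}: stored grid {shape} does not match expected {grid.shape}")
            S = np.empty((kernels.N_STATE,) + shape)
            S[0] = f["V"][()]
            for gi, name in enumerate(GATE_NAMES):
                S[1 + gi] = f["gates"][name][()]
            for ci, name in enumerate(_CONC_NAMES):
                S[13 + ci] = f["conc"][name][()]
    except (KeyError, OSError) as e:
        raise SnapshotError(f"{path}: corrupt or partial state file ({e})") from e
    return TissueState(S, float(meta["t"])), meta


def write_frames(path, frame_t, frames, grid: GridSpec, meta: dict | None = None) -> Path:
    """Store a recorded V-frame sequence (float32) with its time axis."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=np.asarray(frame_t))
        f.create_dataset("frames", data=np.asarray(frames, dtype=np.float32),
                         compression="gzip", compression_opts=1)
        m = f.create_group("meta")
        m.attrs["dx"] = grid.dx
        m.attrs["dz"] = grid.dz
        for k, v in (meta or {}).items():
            m.attrs[k] = v
    return path


def read_frames(path):
    with h5py.File(path, "r") as f:
        t = f["t"][()]
        frames = f["frames"][()]
        meta = dict(f["meta"].attrs)
    return t, [frames[i] for i in range(frames.shape[0])], meta


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

def export_vtk(path, grid: GridSpec, fields: dict) -> Path:
    """Write scalar voxel fields as a legacy-ASCII VTK structured-points file."""
    path = Path(path)
    first = next(iter(fields.values()))
    nx, ny, nz = first.shape
    lines = ["# vtk DataFile Version 3.0", "scrollwave volume export", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx} {ny} {nz}",
             "ORIGIN 0 0 0",
             f"SPACING {grid.dx} {grid.dy} {grid.dz}",
             f"POINT_DATA {nx * ny * nz}"]
    for name, arr in fields.items():
        if arr.shape != (nx, ny, nz):
            raise ValueError(f"field {name} shape {arr.shape} inconsistent")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr, dtype=np.float32).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Inventory of one completed run."""

    scenario_name: str
    config_hash: str
    code_version: str
    started: str
    finished: str = ""
    outputs: list = field(default_factory=list)
    log_path: str = ""

    @classmethod
    def start(cls, scenario: ScenarioConfig) -> "RunManifest":
        from . import __version__
        return cls(scenario_name=scenario.name, config_hash=config_hash(scenario),
                   code_version=__version__,
                   started=datetime.datetime.now().isoformat(timespec="seconds"))

    def finish(self, outputs) -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        self.outputs = [str(o) for o in outputs]
        missing = [o for o in self.outputs if not Path(o).exists()]
        if missing:
            raise SnapshotError(f"manifest lists missing outputs: {missing}")
        return self

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
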