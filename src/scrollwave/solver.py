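"""Monodomain time integration on the 3-D grid.

Advances ``dV/dt = div(D grad V) - I_ion + I_stim`` (per-capacitance units,
pA/pF) with explicit Euler time marching, zero-flux outer boundaries, voltage
clamping inside conduction obstacles, and box stimuli.  The per-voxel ionic
update is delegated to the compiled kernels; an ``exact`` backend driven by the
reference cell module is available for verification on small problems.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass

import numpy as np

from . import cell as _cell
from . import kernels
from .cell import CellParameters, CellState, NumericalBlowupError
from .geometry import DiffusivityField, GridSpec, ParamMap

__all__ = ["TissueState", "Stimulus", "Recordings", "StabilityReport",
           "diffusion_term", "check_stability", "step_tissue", "run_simulation"]


@dataclass
class TissueState:
    """Full tissue state: one 17-component vector per voxel plus the clock."""

    S: np.ndarray          # (17, nx, ny, nz) float64, layout kernels.STATE_FIELDS
    t: float = 0.0

    @classmethod
    def uniform(cls, grid: GridSpec, state: CellState, t: float = 0.0) -> "TissueState":
        S = np.empty((kernels.N_STATE,) + grid.shape)
        for i, f in enumerate(kernels.STATE_FIELDS):
            S[i] = float(np.asarray(getattr(state, f)))
        return cls(S, t)

    @property
    def V(self) -> np.ndarray:
        return self.S[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.S.shape[1:]

    def copy(self) -> "TissueState":
        return TissueState(self.S.copy(), self.t)

    def cell_state(self) -> CellState:
        """View the tissue as an array-valued :class:`CellState`."""
        return CellState(**{f: self.S[i] for i, f in enumerate(kernels.STATE_FIELDS)})

    def check_finite(self):
        if not np.all(np.isfinite(self.S)):
            comp, *idx = np.argwhere(~np.isfinite(self.S))[0]
            raise NumericalBlowupError(kernels.STATE_FIELDS[comp], t=self.t,
                                       index=tuple(int(v) for v in idx))


@dataclass
class Stimulus:
    """Box stimulus in voxel indices; amplitude in pA/pF (negative depolarizes)."""

    box: tuple  # ((i0, i1), (j0, j1), (k0, k1)), half-open ranges
    amplitude: float = -52.0
    start: float = 0.0
    duration: float = 1.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration

    def paint(self, istim: np.ndarray):
        (i0, i1), (j0, j1), (k0, k1) = self.box
        istim[i0:i1, j0:j1, k0:k1] += self.amplitude


@dataclass
class StabilityReport:
    dt: float
    dt_max: float
    ok: bool

    def __str__(self):
        verdict = "stable" if self.ok else "UNSTABLE"
        return f"dt = {self.dt} ms vs explicit-diffusion bound {self.dt_max:.4f} ms: {verdict}"


def check_stability(dt: float, grid: GridSpec, Dfield: DiffusivityField) -> StabilityReport:
    """Explicit-diffusion step bound dt <= 0.5 / max(Dxx/dx^2 + Dyy/dy^2 + Dzz/dz^2).

    For an isotropic tensor this reduces to the textbook dx^2/(2 n_dim D).
    """
    rate = Dfield.Dxx / grid.dx ** 2 + Dfield.Dyy / grid.dy ** 2
    if grid.nz > 1:
        rate = rate + Dfield.Dzz / grid.dz ** 2
    dt_max = 0.5 / float(rate.max())
    return StabilityReport(dt=dt, dt_max=dt_max, ok=dt <= dt_max)


def diffusion_term(V: np.ndarray, Dfield: DiffusivityField, grid: GridSpec,
                   cross_terms: bool = True, out: np.ndarray | None = None) -> np.ndarray:
    """div(D grad V) in mV/ms on the grid, zero-flux outer boundaries."""
    if V.shape != grid.shape:
        raise ValueError(f"V shape {V.shape} does not match grid {grid.shape}")
    if out is None:
        out = np.empty_like(V)
    kernels.diffusion_kernel(V, Dfield.Dxx, Dfield.Dyy, Dfield.Dzz, Dfield.Dxy,
                             grid.dx, grid.dy, grid.dz, cross_terms, out)
    return out


def _paint_stimuli(istim: np.ndarray, stimuli, t: float) -> bool:
    istim[:] = 0.0
    any_active = False
    for s in stimuli:
        if s.active(t):
            s.paint(istim)
            any_active = True
    return any_active


def step_tissue(state: TissueState, Dfield: DiffusivityField, param_map: ParamMap,
                grid: GridSpec, tables: kernels.ModelTables,
                stimuli: tuple = (), clamp_mask: np.ndarray | None = None,
                v_clamp: float = -86.2, cross_terms: bool = True,
                backend: str = "table", _work: dict | None = None) -> TissueState:
    """Advance the tissue by one time step ``tables.dt`` (out-of-place)."""
    dt = tables.dt
    recycle = _work is not None
    if _work is None:
        _work = {}
    lap = _work.get("lap")
    if lap is None:
        lap = _work["lap"] = np.empty(grid.shape)
        _work["istim"] = np.zeros(grid.shape)
        _work["istim_dirty"] = True
        _work["Snew"] = np.empty_like(state.S)
        _work["endo"] = np.ascontiguousarray(param_map.endo_mask)
        _work["noclamp"] = np.zeros(grid.shape, dtype=bool)
    istim = _work["istim"]
    any_active = any(s.active(state.t) for s in stimuli)
    if any_active or _work.get("istim_dirty", True):
        _paint_stimuli(istim, stimuli, state.t)
        _work["istim_dirty"] = any_active
    if clamp_mask is None:
        clamp_mask = _work["noclamp"]

    diffusion_term(state.V, Dfield, grid, cross_terms, out=lap)

    if backend == "table":
        Snew = _work["Snew"]
        endo = _work.get("endo")
        if endo is None:
            endo = param_map.endo_mask
        kernels.step_tissue_kernel(state.S, Snew, endo, param_map.G,
                                   istim, lap, clamp_mask, v_clamp, dt,
                                   tables.tab, tables.xk1, tables.cc)
        # recycle the input buffer only if it was our own previous output, so
        # a caller-owned initial state is never overwritten
        if recycle:
            _work["Snew"] = state.S if state.S is _work.get("last_out") \
                else np.empty_like(state.S)
            _work["last_out"] = Snew
        new = TissueState(Snew, state.t + dt)
    elif backend == "exact":
        new = _step_exact(state, param_map, istim, lap, clamp_mask, v_clamp, dt,
                          tables.method)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return new


def _step_exact(state: TissueState, param_map: ParamMap, istim, lap, clamp_mask,
                v_clamp, dt, method) -> TissueState:
    """Reference NumPy step: vectorized cell.step_cell per cell type."""
    Snew = np.empty_like(state.S)
    ct = param_map.cell_type
    for ct_idx, ct_name in enumerate(_cell.CELL_TYPES):
        sel = ct == ct_idx
        if not sel.any():
            continue
        sub = CellState(**{f: state.S[i][sel] for i, f in enumerate(kernels.STATE_FIELDS)})
        base = param_map.base
        params = _cell.CellParameters(
            **{**{fld.name: getattr(base, fld.name) for fld in dataclasses.fields(base)},
               "cell_type": ct_name})
        # substitute per-voxel conductance arrays (bypassing scalar validation)
        for i, n in enumerate(_cell.SCALABLE_PARAMS):
            object.__setattr__(params, n, param_map.G[i][sel])
        stepped = _cell.step_cell(sub, params, I_stim=istim[sel], dt=dt,
                                  method=method, dV_external=lap[sel])
        for i, f in enumerate(kernels.STATE_FIELDS):
            Snew[i][sel] = np.asarray(getattr(stepped, f))
    if clamp_mask.any():
        Snew[0][clamp_mask] = v_clamp
        for i in range(1, kernels.N_STATE):
            Snew[i][clamp_mask] = state.S[i][clamp_mask]
    return TissueState(Snew, state.t + dt)


@dataclass
class Recordings:
    """Probe series, stored frames and the final state of a run."""

    probe_locations: list
    probe_t: np.ndarray
    probe_V: np.ndarray              # (n_probes, n_samples)
    frame_t: np.ndarray
    frames: list                     # float32 V arrays (2-D slice or 3-D volume)
    final_state: TissueState
    wall_time_s: float = 0.0
    scenario_name: str = ""

    def probe_series(self, idx: int = 0):
        return self.probe_t, self.probe_V[idx]


def run_simulation(scenario, initial_state: TissueState | None = None,
                   backend: str = "table") -> Recordings:
    """Execute a scenario end to end and return its recordings.

    ``scenario`` is a :class:`scrollwave.protocols.ScenarioConfig`.  The run is
    deterministic for a fixed configuration.  Passing ``initial_state``
    restarts from a checkpointed state (its clock is kept).
    """
    from . import protocols  # lazy: protocols builds initial conditions with this module

    t0 = time.perf_counter()
    built = protocols.realize(scenario)
    grid, Dfield, pmap = built.grid, built.Dfield, built.param_map
    tables = built.tables
    dt = tables.dt

    rep = check_stability(dt, grid, Dfield)
    if not rep.ok and not scenario.allow_unstable:
        raise RuntimeError(f"refusing to run: {rep}")

    state = initial_state.copy() if initial_state is not None else built.initial_state
    n_steps = int(round((scenario.duration - state.t) / dt))

    probes = list(scenario.probes)
    for (i, j, k) in probes:
        if not (0 <= i < grid.nx and 0 <= j < grid.ny and 0 <= k < grid.nz):
            raise ValueError(f"probe {(i, j, k)} outside the domain")
    probe_every = max(1, int(round(scenario.probe_interval / dt)))
    frame_every = max(1, int(round(scenario.frame_interval / dt))) \
        if scenario.frame_interval else 0

    probe_t, probe_V = [], []
    frame_t, frames = [], []

    def record(st: TissueState, step: int):
        if probes and step % probe_every == 0:
            probe_t.append(st.t)
            probe_V.append([st.V[p] for p in probes])
        if frame_every and step % frame_every == 0:
            frame_t.append(st.t)
            if scenario.record == "volume":
                frames.append(st.V.astype(np.float32))
            elif scenario.record == "slice":
                frames.append(st.V[:, :, scenario.record_slice].astype(np.float32))

    work: dict = {}
    record(state, 0)
    for step in range(1, n_steps + 1):
        if scenario.physics == "diffusion_only":
            lap = work.get("lap")
            if lap is None:
                lap = work["lap"] = np.empty(grid.shape)
            diffusion_term(state.V, Dfield, grid, scenario.cross_terms, out=lap)
            state = TissueState(state.S.copy(), state.t + dt)
            state.S[0] += dt * lap
        else:
            state = step_tissue(state, Dfield, pmap, grid, tables,
                                stimuli=built.stimuli, clamp_mask=built.clamp_mask,
                                v_clamp=built.v_clamp, cross_terms=scenario.cross_terms,
                                backend=backend, _work=work)
        if step % 50 == 0 or step == n_steps:
            state.check_finite()
        record(state, step)

    return Recordings(
        probe_locations=probes,
        probe_t=np.asarray(probe_t),
        probe_V=np.asarray(probe_V).T if probe_V else np.empty((len(probes), 0)),
        frame_t=np.asarray(frame_t),
        frames=frames,
        final_state=state,
        wall_time_s=time.perf_counter() - t0,
        scenario_name=scenario.name,
    )
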