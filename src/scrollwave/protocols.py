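"""Experiment protocols: initial conditions and the named scenario registry.

Spiral initial conditions are produced by a cross-field S1-S2 protocol on a
2-D sheet: a planar S1 wave from the x = 0 edge, then a half-plane S2 delivered
inside the vulnerable window of the S1 recovery gradient, which leaves a single
free wave end that curls into a spiral.  Scroll waves are built by stacking
that 2-D spiral identically in every z-layer, giving a straight transmural
filament.

The registry names the study's scenario grid: a no-rotation baseline, a
fiber-rotation sweep, conduction and ionic cylindrical obstacles at three
positions relative to the initial core and two radii, the weak- vs
strong-meander cell variants (L-type calcium conductance at its default or
quartered), a plateau-potassium breakup variant, and transmural-heterogeneity
slabs.  All sizes here are the package's scaled-down defaults; the
``full_scale_epicardial`` preset documents a cluster-sized geometry.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import analysis, kernels
from .cell import CellParameters, CellState
from .geometry import (ConfigError, DiffusivityField, GridSpec, Inhomogeneity, ParamMap,
                       TransmuralLayout, build_diffusivity, fiber_angles,
                       transmural_param_map,
                       D_PAR_DEFAULT, D_PERP_DEFAULT, D_TRANS_DEFAULT)
from .solver import Stimulus, TissueState, step_tissue

__all__ = ["ScenarioConfig", "make_spiral_2d", "stack_scroll", "build_scenario",
           "scenario_names", "realize", "ProtocolFailure"]


class ProtocolFailure(RuntimeError):
    """An initial-condition protocol did not produce the intended state."""


#: conductance scale factors of the named cell-parameter variants
VARIANTS = {
    "default": {},
    "GCaL_quarter": {"G_CaL": 0.25},
    "GpK_x5": {"G_pK": 5.0},
}


@dataclass
class ScenarioConfig:
    """Declarative description of one simulation experiment."""

    name: str = "custom"
    # --- geometry ---
    nx: int = 128
    ny: int = 128
    nz: int = 8
    dx: float = 0.025          # cm, in-plane (dy = dx)
    dz: float = 0.025          # cm, transmural
    dtheta_total_deg: float = 0.0
    D_par: float = D_PAR_DEFAULT
    D_perp: float = D_PERP_DEFAULT
    D_trans: float = D_TRANS_DEFAULT
    inhomogeneities: list = field(default_factory=list)
    transmural: TransmuralLayout | None = None
    # --- cell model ---
    cell_type: str = "epi"
    variant: str = "default"
    param_scales: dict = field(default_factory=dict)   # extra multiplicative overrides
    # --- numerics ---
    dt: float = 0.02           # ms
    method: str = "rush_larsen"
    cross_terms: bool = True
    physics: str = "full"      # "full" or "diffusion_only"
    allow_unstable: bool = False
    # --- initial condition and stimuli ---
    initial: str = "rest"      # "rest" | "spiral" | "stimuli-only"
    s2_time: float | None = None   # ms; None = automatic vulnerable-window scan
    stimuli: list = field(default_factory=list)
    # --- schedule and outputs ---
    duration: float = 100.0    # ms
    probes: list = field(default_factory=list)        # [(i, j, k), ...]
    probe_interval: float = 1.0                       # ms
    frame_interval: float = 0.0                       # ms; 0 disables frames
    record: str = "slice"      # "slice" | "volume"
    record_slice: int = 0

    def grid(self) -> GridSpec:
        return GridSpec(self.nx, self.ny, self.nz, dx=self.dx, dz=self.dz)

    def cell_params(self) -> CellParameters:
        scales = dict(VARIANTS[self.variant]) if self.variant in VARIANTS else None
        if scales is None:
            raise ConfigError(f"unknown variant {self.variant!r}")
        for k, v in self.param_scales.items():
            scales[k] = scales.get(k, 1.0) * v
        return CellParameters.from_cell_type(self.cell_type).scaled(**scales)


@dataclass
class BuiltScenario:
    """A scenario resolved into the arrays the solver consumes."""

    grid: GridSpec
    Dfield: DiffusivityField
    param_map: ParamMap
    tables: kernels.ModelTables
    stimuli: tuple
    clamp_mask: np.ndarray
    v_clamp: float
    initial_state: TissueState
    obstacle_masks: list = field(default_factory=list)
    initial_tip: tuple | None = None


def realize(scenario: ScenarioConfig) -> BuiltScenario:
    """Resolve a scenario into grid, fields, tables and initial state."""
    grid = scenario.grid()
    fibers = fiber_angles(grid, scenario.dtheta_total_deg)
    Dfield = build_diffusivity(fibers, grid, scenario.D_par, scenario.D_perp,
                               scenario.D_trans)
    params = scenario.cell_params()
    if scenario.transmural is not None:
        scales = dict(VARIANTS[scenario.variant])
        for k, v in scenario.param_scales.items():
            scales[k] = scales.get(k, 1.0) * v
        pmap = transmural_param_map(grid, scenario.transmural)
        for name, f in scales.items():
            pmap.scale_in(np.ones(grid.shape, dtype=bool), name, f)
    else:
        pmap = ParamMap.uniform(grid, params)

    from .geometry import apply_inhomogeneity
    clamp_mask = np.zeros(grid.shape, dtype=bool)
    v_clamp = -86.2
    masks = []
    for inhom in scenario.inhomogeneities:
        Dfield, pmap, mask = apply_inhomogeneity(Dfield, pmap, inhom, grid)
        masks.append(mask)
        if inhom.kind == "conduction":
            clamp_mask |= mask
            v_clamp = inhom.V_obs

    tables = kernels.ModelTables.build(params, dt=scenario.dt, method=scenario.method)

    tip = None
    if scenario.initial == "spiral":
        grid2d = GridSpec(grid.nx, grid.ny, 1, dx=grid.dx, dz=grid.dz)
        state2d, tip = _spiral_2d_cached(grid2d, scenario)
        state = stack_scroll(state2d, grid.nz)
    else:
        state = TissueState.uniform(grid, _settled_uniform_state(params, scenario.dt,
                                                                 scenario.method))
    return BuiltScenario(grid, Dfield, pmap, tables, tuple(scenario.stimuli),
                         clamp_mask, v_clamp, state, masks, tip)


def _settled_uniform_state(params: CellParameters, dt: float, method: str,
                           settle_ms: float = 1000.0) -> CellState:
    """Quiescent single-cell state after a short unstimulated settle."""
    tab = kernels.ModelTables.build(params, dt=dt, method=method)
    vec = kernels.state_to_vector(CellState.initial())
    vec = kernels.integrate_cell_vector(vec, tab, int(round(settle_ms / dt)), dt,
                                        endo=params.cell_type == "endo", params=params)
    return kernels.vector_to_state(vec)


# ---------------------------------------------------------------------------
# spiral genesis
# ---------------------------------------------------------------------------

_SPIRAL_CACHE: dict = {}


def _spiral_key(grid2d: GridSpec, scenario: ScenarioConfig):
    return (grid2d.nx, grid2d.ny, grid2d.dx, scenario.variant,
            tuple(sorted(scenario.param_scales.items())), scenario.cell_type,
            scenario.dt, scenario.method, scenario.s2_time,
            scenario.D_par, scenario.D_perp)


def _spiral_2d_cached(grid2d: GridSpec, scenario: ScenarioConfig):
    key = _spiral_key(grid2d, scenario)
    if key not in _SPIRAL_CACHE:
        state, tip = make_spiral_2d(
            scenario.cell_params(), grid2d, s2_time=scenario.s2_time,
            dt=scenario.dt, method=scenario.method,
            D_par=scenario.D_par, D_perp=scenario.D_perp, return_tip=True)
        _SPIRAL_CACHE[key] = (state, tip)
    state, tip = _SPIRAL_CACHE[key]
    return state.copy(), tip


def _run_2d(state: TissueState, Dfield, pmap, grid, tables, stimuli, t_end,
            frames_every: float = 0.0):
    """Step a 2-D tissue forward to t_end, optionally collecting V frames."""
    work: dict = {}
    frames, frame_t = [], []
    every = int(round(frames_every / tables.dt)) if frames_every else 0
    step = 0
    n = int(round((t_end - state.t) / tables.dt))
    for _ in range(n):
        state = step_tissue(state, Dfield, pmap, grid, tables, stimuli=stimuli,
                            _work=work)
        step += 1
        if every and step % every == 0:
            frames.append(state.V[:, :, 0].astype(np.float32))
            frame_t.append(state.t)
        if step % 200 == 0:
            state.check_finite()
    return state, frames, frame_t


def _tip_counts(frames, grid: GridSpec, dt_frame: float):
    track = analysis.tip_positions(frames, dt_frame, grid.dx)
    return track


def make_spiral_2d(params: CellParameters, grid2d: GridSpec, s2_time: float | None = None,
                   dt: float = 0.02, method: str = "rush_larsen",
                   D_par: float = D_PAR_DEFAULT, D_perp: float = D_PERP_DEFAULT,
                   mirror_s2: bool = False, verify_ms: float = 200.0,
                   return_tip: bool = False):
    """Create a single 2-D spiral by the cross-field S1-S2 protocol.

    Runs a planar S1 wave from the x = 0 edge, delivers a half-plane S2 at
    ``s2_time`` (or scans the vulnerable window when ``None``), lets the free
    end curl up, and verifies that exactly one tip is present over the final
    ``verify_ms``.  Returns the spiral state with its clock reset to zero
    (and the mean verified tip position when ``return_tip``).
    """
    if grid2d.nz != 1:
        raise ValueError("make_spiral_2d needs a single-layer grid")
    grid = grid2d
    fibers = fiber_angles(grid, 0.0)
    Dfield = build_diffusivity(fibers, grid, D_par, D_perp, D_PERP_DEFAULT)
    pmap = ParamMap.uniform(grid, params)
    tables = kernels.ModelTables.build(params, dt=dt, method=method)

    rest = _settled_uniform_state(params, dt, method)
    state0 = TissueState.uniform(grid, rest)
    s1 = Stimulus(box=((0, 3), (0, grid.ny), (0, 1)), amplitude=-52.0, start=0.0,
                  duration=2.0)

    if s2_time is not None:
        candidates = [float(s2_time)]
    else:
        candidates = _vulnerable_candidates(state0, Dfield, pmap, grid, tables, s1)

    ny_half = grid.ny // 2
    y_lo, y_hi = (ny_half, grid.ny) if mirror_s2 else (0, ny_half)

    base = state0
    t_reached = 0.0
    last_err = "no candidates"
    for s2t in candidates:
        if s2t < t_reached:   # need a fresh S1 run (candidates are sorted, so rare)
            base, t_reached = state0, 0.0
        base, _, _ = _run_2d(base, Dfield, pmap, grid, tables, (s1,), s2t)
        t_reached = s2t
        trial = base.copy()
        s2 = Stimulus(box=((0, grid.nx), (y_lo, y_hi), (0, 1)), amplitude=-52.0,
                      start=s2t, duration=2.0)
        trial, _, _ = _run_2d(trial, Dfield, pmap, grid, tables, (s2,), s2t + 150.0)
        if np.all(trial.V < -70.0):
            last_err = f"S2 at {s2t:.0f} ms: wave died (tissue fully refractory or recovered)"
            continue
        frame_every = 10.0
        trial, frames, frame_t = _run_2d(trial, Dfield, pmap, grid, tables, (),
                                         s2t + 150.0 + verify_ms, frames_every=frame_every)
        track = analysis.tip_positions(frames, frame_every, grid.dx)
        counts = [len(p) for p in track.per_frame]
        if counts and np.median(counts) == 1 and min(counts) >= 1:
            pts = np.concatenate([p for p in track.per_frame if len(p)])
            tip = (float(np.median(pts[:, 0])), float(np.median(pts[:, 1])))
            trial.t = 0.0
            return (trial, tip) if return_tip else trial
        last_err = (f"S2 at {s2t:.0f} ms: tip counts {counts} (expected a single spiral)")
    raise ProtocolFailure(
        f"S1-S2 protocol failed: {last_err}; scan the S2 window (tried {candidates})")


def _vulnerable_candidates(state0, Dfield, pmap, grid, tables, s1):
    """S2 times bracketing the recovery of the S1 wave at the domain middle."""
    probe = (grid.nx // 2, grid.ny // 2, 0)
    state = state0.copy()
    work: dict = {}
    t_rec = None
    was_depolarized = False
    n_max = int(round(1000.0 / tables.dt))
    for step in range(n_max):
        state = step_tissue(state, Dfield, pmap, grid, tables, stimuli=(s1,), _work=work)
        v = state.V[probe]
        if v > -20.0:
            was_depolarized = True
        if was_depolarized and v < -72.0:
            t_rec = state.t
            break
    if t_rec is None:
        raise ProtocolFailure("S1 wave never activated/recovered at the probe; "
                              "domain too small or stimulus too weak")
    # the vulnerable window usually sits just before full mid-domain recovery
    return [t_rec + off for off in (-30.0, -20.0, -10.0, 0.0, -40.0, 10.0, 20.0, 30.0)]


def stack_scroll(state2d: TissueState, nz: int) -> TissueState:
    """Stack a 2-D state identically along z: a scroll with a straight filament."""
    if nz < 1:
        raise ValueError("nz must be >= 1")
    if state2d.S.shape[3] != 1:
        raise ValueError("stack_scroll expects a single-layer state")
    S = np.repeat(state2d.S, nz, axis=3)
    return TissueState(S, state2d.t)


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

def _obstacle_position(which: str, grid: GridSpec, tip: tuple | None = None):
    """Obstacle center: domain center, or 25% / 85% of the way from the
    initial core toward the far corner of the sheet."""
    Lx, Ly, _ = grid.extent
    if which == "center":
        return (Lx / 2.0, Ly / 2.0)
    t = np.array(tip if tip is not None else (Lx / 2.0, Ly / 2.0))
    corner = np.array((Lx, Ly))
    frac = 0.25 if which == "corner_near" else 0.85
    pos = t + frac * (corner - t)
    return (float(pos[0]), float(pos[1]))


#: scaled-down obstacle radii (cm); the large/small contrast mirrors the
#: radius-dependence of anchoring with obstacles that fit the reduced sheet
R_SMALL = 0.25
R_LARGE = 1.0

# Scaled-down study conditions (see docs/methods.md): a 6.4 cm sheet is the
# smallest that sustains reentry in this model; at its 0.05 cm spacing the
# strongest resolvable in-plane anisotropy is a 2:1 diffusivity ratio, and
# 2-D sheets run isotropic at D_par.
D_PAR = D_PAR_DEFAULT
_COMMON_3D = dict(nx=128, ny=128, nz=8, dx=0.05, dz=0.025, dt=0.05,
                  D_par=D_PAR, D_perp=D_PAR / 2.0, D_trans=D_PAR / 4.0,
                  initial="spiral", duration=1000.0,
                  probes=[(32, 32, 0)], probe_interval=1.0,
                  frame_interval=10.0, record="volume")
_COMMON_2D = dict(nx=128, ny=128, nz=1, dx=0.05, dz=0.025, dt=0.05,
                  D_par=D_PAR, D_perp=D_PAR, D_trans=D_PAR,
                  initial="spiral", duration=1000.0,
                  probes=[(32, 32, 0)], probe_interval=1.0,
                  frame_interval=10.0, record="slice")


def _registry() -> dict:
    reg: dict[str, dict] = {}
    reg["baseline_noFR"] = dict(_COMMON_3D, dtheta_total_deg=0.0)
    for ang in (30, 60, 90, 120):
        reg[f"fr_sweep_{ang}"] = dict(_COMMON_3D, dtheta_total_deg=float(ang))
    reg["weak_meander_2d"] = dict(_COMMON_2D)
    reg["strong_meander_2d"] = dict(_COMMON_2D, variant="GCaL_quarter")
    reg["strong_meander_FR60"] = dict(_COMMON_3D, dtheta_total_deg=60.0,
                                      variant="GCaL_quarter")
    reg["breakup_GpK_x5"] = dict(_COMMON_2D, variant="GpK_x5")

    for pos in ("center", "corner_far", "corner_near"):
        for rname, r in (("small", R_SMALL), ("large", R_LARGE)):
            reg[f"conduction_{pos}_{rname}"] = dict(
                _COMMON_3D, dtheta_total_deg=60.0,
                inhomogeneities=[("conduction", pos, r)])
        reg[f"ionic_{pos}"] = dict(
            _COMMON_3D, dtheta_total_deg=60.0,
            inhomogeneities=[("ionic", pos, R_LARGE)])

    reg["conduction_center_strongmeander"] = dict(
        _COMMON_3D, dtheta_total_deg=60.0, variant="GCaL_quarter",
        inhomogeneities=[("conduction", "center", R_LARGE)])

    trans = TransmuralLayout(w_endo=0.5, w_mid=0.5, w_epi=0.2)
    common_tm = dict(_COMMON_3D, nz=49, dz=0.025, dtheta_total_deg=120.0,
                     transmural=trans, duration=500.0)  # 1.2 cm three-layer wall
    reg["transmural_baseline"] = dict(common_tm)
    reg["transmural_conduction_center"] = dict(
        common_tm, inhomogeneities=[("conduction", "center", R_LARGE)])
    reg["transmural_ionic_center"] = dict(
        common_tm, inhomogeneities=[("ionic", "center", R_LARGE)])

    # documentation preset of a cluster-scale domain (not used by tests)
    reg["full_scale_epicardial"] = dict(
        nx=512, ny=512, nz=10, dx=0.02, dz=0.02, dt=0.02, initial="spiral",
        duration=4000.0, dtheta_total_deg=60.0, probes=[(128, 128, 0)],
        frame_interval=10.0, record="volume")
    return reg


_REGISTRY = _registry()


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def build_scenario(name: str, overrides: dict | None = None) -> ScenarioConfig:
    """Resolve a registry scenario by name; ``overrides`` merge shallowly."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown scenario {name!r}; known: {', '.join(scenario_names())}")
    spec = copy.deepcopy(_REGISTRY[name])
    spec["name"] = name
    if overrides:
        valid = set(ScenarioConfig.__dataclass_fields__)
        for k in overrides:
            if k not in valid:
                raise ConfigError(f"unknown scenario override {k!r}")
        spec.update(copy.deepcopy(overrides))
    inhoms = spec.pop("inhomogeneities", [])
    cfg = ScenarioConfig(**spec)
    grid = cfg.grid()
    resolved = []
    for item in inhoms:
        if isinstance(item, Inhomogeneity):
            resolved.append(item)
        else:
            kind, pos, radius = item
            center = _obstacle_position(pos, grid)
            resolved.append(Inhomogeneity(kind=kind, center=center, radius=radius))
    cfg.inhomogeneities = resolved
    return cfg
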