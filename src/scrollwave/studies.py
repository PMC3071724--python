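"""Self-contained study drivers: each runs one verification or scaled-down
experiment end to end and returns its headline numbers.

These are the computations behind the package's reproducibility checks:
conduction-velocity anisotropy, the analytic diffusion oracle, the resting
fixed point, tracker and spectral recovery on synthetic truth, and the
scaled-down spiral/scroll regime studies.  Sizes and durations default to the
package's single-CPU study conditions.
"""

from __future__ import annotations

import numpy as np

from . import analysis, fixtures, kernels, protocols
from .cell import CellParameters, CellState, dv_dt, find_rest, ionic_currents
from .geometry import (GridSpec, Inhomogeneity, ParamMap, apply_inhomogeneity,
                       build_diffusivity, fiber_angles)
from .protocols import ScenarioConfig, VARIANTS
from .solver import Recordings, Stimulus, TissueState, run_simulation, step_tissue

__all__ = ["cv_anisotropy", "current_count", "diffusion_oracle", "rest_fixed_point",
           "tracker_recovery", "spectral_recovery", "regime_contrast_2d",
           "scroll_filaments_3d", "anchoring_contrast"]


def _planar_cv(D_along: float, D_cross: float, dx: float, dt: float, n: int,
               params: CellParameters, duration: float = 150.0) -> float:
    """CV of a planar wave down a thin strip whose x-axis has diffusivity D_along."""
    grid = GridSpec(n, 3, 1, dx=dx)
    tables = kernels.ModelTables.build(params, dt=dt)
    Df = build_diffusivity(fiber_angles(grid, 0.0), grid,
                           D_par=max(D_along, D_cross), D_perp=min(D_along, D_cross))
    Df.Dxx[:] = D_along
    Df.Dyy[:] = D_cross
    pmap = ParamMap.uniform(grid, params)
    rest = protocols._settled_uniform_state(params, dt, "rush_larsen")
    state = TissueState.uniform(grid, rest)
    ncol = max(3, int(round(0.06 / dx)))
    stim = Stimulus(box=((0, ncol), (0, 3), (0, 1)), amplitude=-52.0, start=0.0,
                    duration=2.0)
    probes = [(n // 3, 1, 0), (2 * n // 3, 1, 0)]
    ts, vs = [], []
    work: dict = {}
    for _ in range(int(round(duration / dt))):
        state = step_tissue(state, Df, pmap, grid, tables, stimuli=(stim,), _work=work)
        ts.append(state.t)
        vs.append([state.V[p] for p in probes])
    rec = Recordings(probes, np.asarray(ts), np.asarray(vs).T, np.array([]), [], state)
    return analysis.measure_cv(rec, grid, axis="x")


def cv_anisotropy(dx: float = 0.0075, dt: float = 0.005, n: int = 256,
                  D_par: float = 1.54e-3, ratio: float = 9.0) -> dict:
    """Planar CV along vs across fibers on a fine strip (default D ratio 9)."""
    params = CellParameters.from_cell_type("epi")
    cv_par = _planar_cv(D_par, D_par / ratio, dx, dt, n, params)
    cv_perp = _planar_cv(D_par / ratio, D_par, dx, dt, n, params)
    return {"cv_par_cm_per_ms": cv_par, "cv_perp_cm_per_ms": cv_perp,
            "ratio": cv_par / cv_perp, "n": n}


def current_count() -> dict:
    """The cell model's current breakdown: 12 components summing to I_ion."""
    state = CellState.initial()
    cur = ionic_currents(state, CellParameters.from_cell_type("epi"))
    comps = [cur.as_dict()[k] for k in cur.as_dict() if k != "I_ion"]
    return {"n_currents": len(comps),
            "sum_closure_residual": float(abs(cur.I_ion - sum(comps)))}


def diffusion_oracle(n: int = 81, dx: float = 0.02, sigma0: float = 0.12,
                     duration: float = 30.0, D: float = 1.0e-3) -> dict:
    """Pure-diffusion run vs the analytic spreading Gaussian, plus the error
    reduction when dx is halved (second-order stencil: factor ~4)."""

    def rel_err(nn, hx, dt):
        grid = GridSpec(nn, nn, 1, dx=hx)
        f0, ev = fixtures.analytic_diffusion_field(D, 1e-12, grid, sigma0=sigma0)
        sc = ScenarioConfig(nx=nn, ny=nn, nz=1, dx=hx, dt=dt, duration=duration,
                            physics="diffusion_only", initial="rest",
                            D_par=D, D_perp=D, D_trans=D)
        st = TissueState(np.zeros((kernels.N_STATE, nn, nn, 1)))
        st.S[0] = f0
        rec = run_simulation(sc, initial_state=st)
        want = ev(duration)
        return float(np.linalg.norm(rec.final_state.V - want) / np.linalg.norm(want))

    e_coarse = rel_err(n, dx, dt=0.005)
    e_fine = rel_err(2 * n - 1, dx / 2, dt=0.005)
    return {"rel_l2_error_pct": 100.0 * e_coarse,
            "convergence_factor": e_coarse / e_fine, "n": n}


def rest_fixed_point(dt: float = 0.02) -> dict:
    """Equilibrated single cell and invariance of a uniform resting tissue."""
    params = CellParameters.from_cell_type("epi")
    rest = find_rest(params)
    dvdt = abs(dv_dt(rest, params))
    grid = GridSpec(8, 8, 2, dx=0.02, dz=0.02)
    Df = build_diffusivity(fiber_angles(grid, 0.0), grid)
    pmap = ParamMap.uniform(grid, params)
    tables = kernels.ModelTables.build(params, dt=dt)
    state = TissueState.uniform(grid, rest)
    work: dict = {}
    s = state
    n_steps = int(round(100.0 / dt))
    for _ in range(n_steps):
        s = step_tissue(s, Df, pmap, grid, tables, _work=work)
    drift = float(np.abs(s.V - state.V).max())
    return {"rest_abs_dvdt_mv_per_ms": float(dvdt),
            "tissue_drift_mv_per_step": drift / n_steps, "n": grid.nx * grid.ny * grid.nz}


def tracker_recovery() -> dict:
    """Tip/filament recovery on synthetic spirals, helices and stacked scrolls."""
    grid2d = GridSpec(96, 96, 1, dx=0.025)
    omega, wavelen = 2.0 * np.pi / 150.0, 1.5
    core = (1.2, 1.15)
    frames, _ = fixtures.synthetic_spiral_frames(core, omega, wavelen, grid2d, 12, 10.0)
    track = analysis.tip_positions(frames, 10.0, grid2d.dx)
    tip_err = max(float(np.linalg.norm(p - np.asarray(core), axis=1).min())
                  for p in track.per_frame)

    grid3d = GridSpec(64, 64, 8, dx=0.025, dz=0.025)
    z = np.arange(8) * grid3d.dz
    helix = np.column_stack([0.8 + 0.15 * np.cos(np.pi * z / (8 * grid3d.dz)),
                             0.8 + 0.15 * np.sin(np.pi * z / (8 * grid3d.dz)), z])
    vols, truth = fixtures.synthetic_scroll_volume([helix], grid3d, 4, 10.0,
                                                   omega=omega, wavelength=wavelen)
    # linking radius sized to the helix pitch (adjacent-layer cores ~2.3 voxels apart)
    fs = analysis.extract_filaments(vols, 10.0, grid3d.dx, grid3d.dz,
                                    linking_radius=4 * grid3d.dx)
    got = fs.filaments[0][0].points
    dmat = np.linalg.norm(got[:, None, :] - truth[0][None, :, :], axis=2)
    hausdorff = max(dmat.min(axis=0).max(), dmat.min(axis=1).max())

    straight = np.column_stack([np.full(8, 0.8), np.full(8, 0.8), z])
    vols2, _ = fixtures.synthetic_scroll_volume([straight], grid3d, 3, 10.0,
                                                omega=omega, wavelength=wavelen)
    fs2 = analysis.extract_filaments(vols2, 10.0, grid3d.dx, grid3d.dz)
    straight_counts = fs2.counts()
    xy_spread = float(np.abs(fs2.filaments[0][0].points[:, :2] - [0.8, 0.8]).max())
    return {"tip_error_voxels": tip_err / grid2d.dx,
            "helix_hausdorff_voxels": float(hausdorff) / grid3d.dx,
            "stacked_filament_count": int(straight_counts.max()),
            "stacked_xy_spread_voxels": xy_spread / grid3d.dx,
            "n": len(frames)}


def spectral_recovery(seed: int = 7) -> dict:
    """Frequency recovery, quasiperiodic indexing and classification."""
    f1, f2 = 3.5, 5.2
    _, x = fixtures.synthetic_multitone([f1, f2, f1 + f2, 2 * f1],
                                        [1.0, 0.8, 0.3, 0.2], 16384.0, 1.0)
    spec = analysis.power_spectrum(x, 1.0, transient=0.0)
    got = sorted(p for p, _ in spec.peaks[:2])
    peak_err_bins = max(abs(got[0] - f1), abs(got[1] - f2)) / spec.df
    label_two = analysis.classify_dynamics(spec)
    by_freq = dict(zip([p for p, _ in spec.peaks], spec.indices or []))
    comb = min(by_freq, key=lambda fp: abs(fp - (f1 + f2)))
    comb_ok = by_freq[comb] == (1, 1)

    _, tone = fixtures.synthetic_multitone([6.0], [1.0], 8192.0, 1.0)
    label_tone = analysis.classify_dynamics(analysis.power_spectrum(tone, 1.0, transient=0.0))
    _, noise = fixtures.synthetic_multitone([], [], 8192.0, 1.0, noise_sd=1.0, seed=seed)
    label_noise = analysis.classify_dynamics(analysis.power_spectrum(noise, 1.0, transient=0.0))
    return {"peak_error_bins": float(peak_err_bins),
            "combination_indexed_11": bool(comb_ok),
            "label_two_tone": label_two, "label_tone": label_tone,
            "label_noise": label_noise, "n": x.size}


# ---------------------------------------------------------------------------
# scaled-down regime studies
# ---------------------------------------------------------------------------

#: 2-D regime-contrast sheet: 128 x 128 voxels at coarse spacing (6.4 cm),
#: the smallest sheet that can hold the hypermeandering default spiral
SHEET_N = 128
SHEET_DX = 0.05
SHEET_DT = 0.05

_SEED_CACHE: dict = {}


def _spiral_sheet(variant: str, n: int = SHEET_N, dx: float = SHEET_DX,
                  dt: float = SHEET_DT) -> tuple:
    """A single-spiral 2-D initial state for the given cell variant (cached)."""
    key = (variant, n, dx, dt)
    if key not in _SEED_CACHE:
        grid = GridSpec(n, n, 1, dx=dx)
        params = CellParameters.from_cell_type("epi").scaled(**VARIANTS[variant])
        state, tip = protocols.make_spiral_2d(
            params, grid, dt=dt, D_par=1.54e-3, D_perp=1.54e-3,
            verify_ms=200.0, return_tip=True)
        _SEED_CACHE[key] = (state, tip)
    state, tip = _SEED_CACHE[key]
    return state.copy(), tip


def _evolve_sheet(state: TissueState, variant: str, duration: float,
                  n: int = SHEET_N, dx: float = SHEET_DX, dt: float = SHEET_DT,
                  obstacle: Inhomogeneity | None = None,
                  frame_interval: float = 10.0):
    """Evolve a 2-D sheet, returning frame times and V frames."""
    grid = GridSpec(n, n, 1, dx=dx)
    params = CellParameters.from_cell_type("epi").scaled(**VARIANTS[variant])
    tables = kernels.ModelTables.build(params, dt=dt)
    Df = build_diffusivity(fiber_angles(grid, 0.0), grid, D_par=1.54e-3, D_perp=1.54e-3)
    pmap = ParamMap.uniform(grid, params)
    clamp, v_clamp = None, -86.2
    if obstacle is not None:
        Df, pmap, clamp = apply_inhomogeneity(Df, pmap, obstacle, grid)
        v_clamp = obstacle.V_obs
    work: dict = {}
    frames, ft = [], []
    every = int(round(frame_interval / dt))
    st = state
    n_steps = int(round(duration / dt))
    for step in range(1, n_steps + 1):
        st = step_tissue(st, Df, pmap, grid, tables, clamp_mask=clamp,
                         v_clamp=v_clamp, _work=work)
        if step % every == 0:
            frames.append(st.V[:, :, 0].astype(np.float32))
            ft.append(st.t)
        if step % 400 == 0:
            st.check_finite()
    return np.asarray(ft), frames, st


def _lifetime(frames, ft, thresh: float = -30.0) -> float:
    alive = [t for t, f in zip(ft, frames) if (f > thresh).any()]
    return max(alive) if alive else 0.0


def sheet_cv(n: int = 192) -> float:
    """Planar CV (cm/ms) at the sheet's isotropic study conditions."""
    params = CellParameters.from_cell_type("epi")
    return _planar_cv(1.54e-3, 1.54e-3, SHEET_DX, SHEET_DT, n, params, duration=220.0)


def _rotation_period(frames, ft, probe) -> float:
    """Dominant rotation period (ms) from the autocorrelation of a probe series."""
    v = np.array([f[probe] for f in frames], dtype=float)
    v = v - v.mean()
    ac = np.correlate(v, v, mode="full")[v.size - 1:]
    # first local maximum after the zero-lag peak
    dt_frame = float(ft[1] - ft[0])
    for lag in range(2, ac.size - 1):
        if ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > 0:
            return lag * dt_frame
    return float("nan")


def regime_contrast_2d(duration: float = 1100.0, n: int = SHEET_N,
                       dx: float = SHEET_DX, transient: float = 200.0) -> dict:
    """Weak (default) vs strong (quartered G_CaL) meander on matched sheets.

    Returns spiral lifetimes and meander extents measured on the shared
    window where both spirals are alive.
    """
    out: dict = {"n": n, "duration_ms": duration}
    tracks = {}
    for variant, tag in (("default", "weak"), ("GCaL_quarter", "strong")):
        seed, _ = _spiral_sheet(variant, n=n, dx=dx)
        ft, frames, _ = _evolve_sheet(seed, variant, duration, n=n, dx=dx)
        track = analysis.tip_positions(frames, float(ft[1] - ft[0]), dx, times=ft)
        counts = track.counts()
        alive_t = track.t[counts > 0]
        out[f"{tag}_lifetime_ms"] = float(alive_t.max()) if alive_t.size else 0.0
        out[f"{tag}_rotation_period_ms"] = _rotation_period(frames, ft, (n // 4, n // 4))
        tracks[tag] = track
    window = min(out["weak_lifetime_ms"], out["strong_lifetime_ms"])
    for tag in ("weak", "strong"):
        tr = tracks[tag]
        keep = tr.t <= window
        sub = analysis.TipTrack(tr.t[keep], [p for p, k in zip(tr.per_frame, keep) if k],
                                [c for c, k in zip(tr.chirality, keep) if k],
                                tr.gaps[keep], tr.dx)
        try:
            out[f"{tag}_meander_extent_cm"] = analysis.meander_extent(
                sub, transient=min(transient, 0.5 * window), min_points=5)
        except ValueError:
            out[f"{tag}_meander_extent_cm"] = float("nan")
    return out


def scroll_filaments_3d(duration: float = 300.0, n: int = SHEET_N, nz: int = 8,
                        dx: float = SHEET_DX, dz: float = 0.025, dt: float = SHEET_DT,
                        dtheta: float = 60.0, variant: str = "GCaL_quarter",
                        frame_interval: float = 10.0) -> dict:
    """Scroll wave with fiber rotation: filament counts over time.

    Stacks the strong-meander 2-D spiral into a 2 mm wall, with the strongest
    in-plane anisotropy resolvable at the sheet spacing (D ratio 2) and
    transmural diffusivity D_par/4.  Reports the filament count over time,
    whose maximum exceeds 1 when fiber rotation transiently breaks the
    filament.
    """
    params = CellParameters.from_cell_type("epi").scaled(**VARIANTS[variant])
    seed2d, _ = _spiral_sheet(variant, n=n, dx=dx, dt=dt)
    state = protocols.stack_scroll(seed2d, nz)

    grid = GridSpec(n, n, nz, dx=dx, dz=dz)
    D_par = 1.54e-3
    Df = build_diffusivity(fiber_angles(grid, dtheta), grid, D_par=D_par,
                           D_perp=D_par / 2.0, D_trans=D_par / 4.0)
    pmap = ParamMap.uniform(grid, params)
    tables = kernels.ModelTables.build(params, dt=dt)
    work: dict = {}
    vols, ft = [], []
    every = int(round(frame_interval / dt))
    for step in range(1, int(round(duration / dt)) + 1):
        state = step_tissue(state, Df, pmap, grid, tables, _work=work)
        if step % every == 0:
            vols.append(state.V.astype(np.float32))
            ft.append(state.t)
        if step % 400 == 0:
            state.check_finite()
    fs = analysis.extract_filaments(vols, frame_interval, dx, dz, times=np.asarray(ft))
    counts = fs.counts()
    return {"max_filament_count": int(counts.max()) if counts.size else 0,
            "filament_counts": counts.tolist(), "n": n * n * nz,
            "duration_ms": duration}


def anchoring_contrast(duration: float = 1000.0, n: int = SHEET_N, dx: float = SHEET_DX,
                       R_small: float = 0.25, R_large: float = 1.0,
                       variant: str = "default") -> dict:
    """Pre-formed spiral evolving around a central conduction obstacle.

    Compares small vs large obstacle radius: the tendency to anchor grows
    with radius.  Reports final-window tip distances to the obstacle surface
    and wave lifetimes.
    """
    seed, tip = _spiral_sheet(variant, n=n, dx=dx)
    grid = GridSpec(n, n, 1, dx=dx)
    center = (grid.extent[0] / 2.0, grid.extent[1] / 2.0)
    params = CellParameters.from_cell_type("epi").scaled(**VARIANTS[variant])
    rest_v = float(protocols._settled_uniform_state(params, SHEET_DT, "rush_larsen").V)
    out: dict = {"n": n, "R_small_cm": R_small, "R_large_cm": R_large,
                 "obstacle_center": center}
    for tag, R in (("small", R_small), ("large", R_large)):
        obst = Inhomogeneity("conduction", center=center, radius=R, V_obs=rest_v)
        ft, frames, _ = _evolve_sheet(seed.copy(), variant, duration, n=n, dx=dx,
                                      obstacle=obst)
        track = analysis.tip_positions(frames, float(ft[1] - ft[0]), dx, times=ft)
        out[f"{tag}_lifetime_ms"] = _lifetime(frames, ft)
        pts = track.all_points(t_min=duration - 250.0)
        if len(pts):
            d_axis = np.hypot(pts[:, 1] - center[0], pts[:, 2] - center[1])
            out[f"{tag}_final_tip_dist_cm"] = float(np.median(d_axis))
            out[f"{tag}_final_tip_surface_dist_cm"] = float(np.median(np.abs(d_axis - R)))
        else:
            out[f"{tag}_final_tip_dist_cm"] = float("inf")
            out[f"{tag}_final_tip_surface_dist_cm"] = float("inf")
    return out
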