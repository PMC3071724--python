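"""Monodomain solver: diffusion operator, stability, stepping, full runs."""

import numpy as np
import pytest

from scrollwave import protocols
from scrollwave.cell import CellParameters
from scrollwave.geometry import GridSpec, ParamMap, build_diffusivity, fiber_angles
from scrollwave.kernels import ModelTables
from scrollwave.protocols import ScenarioConfig
from scrollwave.solver import (Recordings, Stimulus, TissueState, check_stability,
                               diffusion_term, run_simulation, step_tissue)


def brute_force_divergence(V, Dxx, Dyy, Dzz, Dxy, dx, dy, dz):
    """Independent flux-form stencil (boundary fluxes vanish), index by index."""
    nx, ny, nz = V.shape
    out = np.zeros_like(V)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                if i + 1 < nx:
                    acc += 0.5 * (Dxx[i, j, k] + Dxx[i + 1, j, k]) * (V[i + 1, j, k] - V[i, j, k]) / dx ** 2
                if i > 0:
                    acc -= 0.5 * (Dxx[i - 1, j, k] + Dxx[i, j, k]) * (V[i, j, k] - V[i - 1, j, k]) / dx ** 2
                if j + 1 < ny:
                    acc += 0.5 * (Dyy[i, j, k] + Dyy[i, j + 1, k]) * (V[i, j + 1, k] - V[i, j, k]) / dy ** 2
                if j > 0:
                    acc -= 0.5 * (Dyy[i, j - 1, k] + Dyy[i, j, k]) * (V[i, j, k] - V[i, j - 1, k]) / dy ** 2
                if nz > 1:
                    if k + 1 < nz:
                        acc += 0.5 * (Dzz[i, j, k] + Dzz[i, j, k + 1]) * (V[i, j, k + 1] - V[i, j, k]) / dz ** 2
                    if k > 0:
                        acc -= 0.5 * (Dzz[i, j, k - 1] + Dzz[i, j, k]) * (V[i, j, k] - V[i, j, k - 1]) / dz ** 2
                out[i, j, k] = acc
    return out


def make_uniform(grid, D=1.0, Dz=None):
    f = fiber_angles(grid, 0.0)
    return build_diffusivity(f, grid, D, D, Dz if Dz is not None else D)


class TestDiffusionTerm:
    def test_uniform_field_gives_zero(self):
        g = GridSpec(9, 9, 3, dx=0.1, dz=0.1)
        D = make_uniform(g, 2.0)
        V = np.full(g.shape, -80.0)
        assert np.allclose(diffusion_term(V, D, g), 0.0, atol=1e-12)

    def test_linear_field_gives_zero_interior(self):
        g = GridSpec(9, 9, 1, dx=0.1)
        D = make_uniform(g, 2.0)
        x = g.axis_coords(0)[:, None, None]
        V = np.broadcast_to(3.0 * x, g.shape).copy()
        out = diffusion_term(V, D, g)
        assert np.allclose(out[1:-1, :, :], 0.0, atol=1e-10)

    def test_quadratic_field_gives_2D_interior(self):
        g = GridSpec(9, 9, 9, dx=0.1, dz=0.1)
        Dval = 1.7
        D = make_uniform(g, Dval)
        x = g.axis_coords(0)[:, None, None]
        V = np.broadcast_to(x ** 2, g.shape).copy()
        out = diffusion_term(V, D, g)
        assert np.allclose(out[1:-1, 1:-1, 1:-1], 2.0 * Dval, rtol=1e-10)

    def test_matches_brute_force_stencil_with_rotation(self, rng):
        g = GridSpec(7, 6, 4, dx=0.05, dz=0.04)
        D = build_diffusivity(fiber_angles(g, 75.0), g, 9e-4, 1e-4, 2e-4)
        V = rng.normal(-60.0, 20.0, g.shape)
        got = diffusion_term(V, D, g, cross_terms=False)
        want = brute_force_divergence(V, D.Dxx, D.Dyy, D.Dzz, D.Dxy, g.dx, g.dy, g.dz)
        assert np.allclose(got, want, atol=1e-10)

    def test_cross_terms_consistent_for_bilinear_field(self):
        # V = x*y with constant full tensor: div(D grad V) = 2 D_xy exactly
        g = GridSpec(12, 12, 1, dx=0.1)
        D = build_diffusivity(fiber_angles(g, 30.0), g, 9.0, 1.0, 1.0)
        x = g.axis_coords(0)[:, None, None]
        y = g.axis_coords(1)[None, :, None]
        V = np.broadcast_to(x * y, g.shape).copy()
        out = diffusion_term(V, D, g, cross_terms=True)
        dxy = D.Dxy[0, 0, 0]
        assert np.allclose(out[1:-1, 1:-1, :], 2.0 * dxy, rtol=1e-10)

    def test_conservation_with_cross_terms(self, rng):
        g = GridSpec(16, 16, 5, dx=0.05, dz=0.05)
        D = build_diffusivity(fiber_angles(g, 100.0), g, 9e-4, 1e-4, 1e-4)
        V = rng.normal(0.0, 30.0, g.shape)
        total0 = V.sum()
        dt = 0.5
        for _ in range(1000):
            V = V + dt * diffusion_term(V, D, g, cross_terms=True)
        assert abs(V.sum() - total0) <= 1e-8 * abs(total0) + 1e-8

    def test_shape_mismatch_rejected(self):
        g = GridSpec(9, 9, 1)
        D = make_uniform(g)
        with pytest.raises(ValueError):
            diffusion_term(np.zeros((5, 5, 1)), D, g)


class TestStability:
    def test_zero_dt_trivially_stable(self):
        g = GridSpec(4, 4, 1, dx=0.02)
        assert check_stability(0.0, g, make_uniform(g, 1.54e-3)).ok

    def test_doubling_diffusivity_halves_bound(self):
        g = GridSpec(4, 4, 4, dx=0.02, dz=0.02)
        b1 = check_stability(0.02, g, make_uniform(g, 1e-3)).dt_max
        b2 = check_stability(0.02, g, make_uniform(g, 2e-3)).dt_max
        assert b1 == pytest.approx(2.0 * b2)

    def test_bound_matches_hand_computation_3d(self):
        dx, Dmax = 0.02, 1.54e-3
        g = GridSpec(4, 4, 4, dx=dx, dz=dx)
        rep = check_stability(0.02, g, make_uniform(g, Dmax))
        assert rep.dt_max == pytest.approx(dx ** 2 / (6.0 * Dmax))   # 3-D isotropic

    def test_unstable_dt_blocks_run(self):
        sc = ScenarioConfig(nx=8, ny=8, nz=1, dx=0.01, dt=1.0, duration=2.0,
                            initial="rest")
        with pytest.raises(RuntimeError, match="UNSTABLE"):
            run_simulation(sc)


@pytest.fixture(scope="module")
def small_rest():
    """A small uniform resting tissue with its solver ingredients."""
    params = CellParameters.from_cell_type("epi")
    grid = GridSpec(6, 5, 2, dx=0.02, dz=0.02)
    Df = build_diffusivity(fiber_angles(grid, 0.0), grid, 1.54e-3, 1.54e-3 / 9, 1.54e-3 / 9)
    pmap = ParamMap.uniform(grid, params)
    tables = ModelTables.build(params, dt=0.02)
    rest = protocols._settled_uniform_state(params, 0.02, "rush_larsen", settle_ms=3000.0)
    state = TissueState.uniform(grid, rest)
    return dict(params=params, grid=grid, Df=Df, pmap=pmap, tables=tables, state=state)


class TestStepTissue:
    def test_uniform_rest_is_fixed_point(self, small_rest):
        s = small_rest
        st = s["state"].copy()
        for _ in range(10):
            st = step_tissue(st, s["Df"], s["pmap"], s["grid"], s["tables"])
        assert np.abs(st.V - s["state"].V).max() < 1e-5
        assert np.abs(st.S - s["state"].S).max() < 1e-5

    def test_single_voxel_reduces_to_cell_step(self, small_rest):
        from scrollwave.cell import CellState, step_cell
        from scrollwave.kernels import STATE_FIELDS
        params = small_rest["params"]
        grid = GridSpec(1, 1, 1)
        Df = make_uniform(grid, 1.54e-3)
        pmap = ParamMap.uniform(grid, params)
        tables = ModelTables.build(params, dt=0.02)
        cs = CellState(**{f: float(small_rest["state"].S[i][0, 0, 0])
                          for i, f in enumerate(STATE_FIELDS)})
        tissue = TissueState.uniform(grid, cs)
        stim = Stimulus(box=((0, 1), (0, 1), (0, 1)), amplitude=-52.0, start=0.0,
                        duration=1.0)
        ref = cs
        for _ in range(100):
            tissue = step_tissue(tissue, Df, pmap, grid, tables, stimuli=(stim,),
                                 backend="exact")
            ref = step_cell(ref, params, I_stim=-52.0 if tissue.t - 0.02 < 1.0 else 0.0,
                            dt=0.02)
        for i, f in enumerate(STATE_FIELDS):
            assert tissue.S[i][0, 0, 0] == pytest.approx(getattr(ref, f), rel=1e-12), f

    def test_table_and_exact_backends_agree(self, small_rest):
        s = small_rest
        stim = Stimulus(box=((0, 2), (0, 5), (0, 2)), amplitude=-52.0, start=0.0,
                        duration=1.0)
        st_tab = s["state"].copy()
        st_ex = s["state"].copy()
        for _ in range(150):   # 3 ms spanning the upstroke
            st_tab = step_tissue(st_tab, s["Df"], s["pmap"], s["grid"], s["tables"],
                                 stimuli=(stim,), backend="table")
            st_ex = step_tissue(st_ex, s["Df"], s["pmap"], s["grid"], s["tables"],
                                stimuli=(stim,), backend="exact")
        assert np.abs(st_tab.V - st_ex.V).max() < 0.05

    def test_planar_wave_activates_monotonically(self):
        params = CellParameters.from_cell_type("epi")
        grid = GridSpec(100, 3, 1, dx=0.02)
        Df = build_diffusivity(fiber_angles(grid, 0.0), grid, 1.54e-3, 1.54e-3 / 9,
                               1.54e-3 / 9)
        pmap = ParamMap.uniform(grid, params)
        tables = ModelTables.build(params, dt=0.02)
        rest = protocols._settled_uniform_state(params, 0.02, "rush_larsen")
        st = TissueState.uniform(grid, rest)
        stim = Stimulus(box=((0, 3), (0, 3), (0, 1)), amplitude=-52.0, start=0.0,
                        duration=2.0)
        act = np.full(grid.nx, np.nan)
        work = {}
        for _ in range(int(40.0 / 0.02)):
            st = step_tissue(st, Df, pmap, grid, tables, stimuli=(stim,), _work=work)
            newly = np.isnan(act) & (st.V[:, 1, 0] > -30.0)
            act[newly] = st.t
        assert np.isfinite(act[:90]).all()           # front reached x index 89
        assert np.all(np.diff(act[3:90]) > 0)        # strictly later with distance


class TestRunSimulation:
    def test_zero_duration_returns_initial(self):
        sc = ScenarioConfig(nx=6, ny=6, nz=1, duration=0.0, initial="rest",
                            probes=[(2, 2, 0)])
        rec = run_simulation(sc)
        assert rec.probe_t.size == 1 and rec.final_state.t == 0.0

    def test_determinism(self):
        sc = ScenarioConfig(nx=8, ny=8, nz=2, dx=0.02, dz=0.02, duration=5.0,
                            initial="rest", probes=[(4, 4, 0)], probe_interval=0.5,
                            stimuli=[Stimulus(box=((0, 2), (0, 8), (0, 2)),
                                              amplitude=-52.0, start=0.0, duration=1.0)])
        r1 = run_simulation(sc)
        r2 = run_simulation(sc)
        assert np.array_equal(r1.probe_V, r2.probe_V)

    def test_restart_equals_uninterrupted(self):
        stim = Stimulus(box=((0, 2), (0, 8), (0, 2)), amplitude=-52.0, start=0.0,
                        duration=1.0)
        base = dict(nx=8, ny=8, nz=2, dx=0.02, dz=0.02, initial="rest",
                    stimuli=[stim], probes=[(4, 4, 0)])
        full = run_simulation(ScenarioConfig(duration=6.0, **base))
        part = run_simulation(ScenarioConfig(duration=3.0, **base))
        resumed = run_simulation(ScenarioConfig(duration=6.0, **base),
                                 initial_state=part.final_state)
        assert np.abs(resumed.final_state.V - full.final_state.V).max() < 1e-10

    def test_isotropy_limit_invariant_under_fiber_rotation(self):
        stim = Stimulus(box=((0, 2), (0, 6), (0, 3)), amplitude=-52.0, start=0.0,
                        duration=1.0)
        base = dict(nx=6, ny=6, nz=3, dx=0.02, dz=0.02, duration=3.0, initial="rest",
                    stimuli=[stim], D_par=1.54e-3, D_perp=1.54e-3, D_trans=1.54e-3)
        r0 = run_simulation(ScenarioConfig(dtheta_total_deg=0.0, **base))
        r1 = run_simulation(ScenarioConfig(dtheta_total_deg=120.0, **base))
        assert np.abs(r0.final_state.V - r1.final_state.V).max() < 1e-10

    def test_pure_diffusion_matches_analytic_gaussian(self):
        from scrollwave.fixtures import analytic_diffusion_field
        Dv = 1.0e-3
        g = GridSpec(81, 81, 1, dx=0.02)
        field0, evaluator = analytic_diffusion_field(Dv, 1e-12, g, sigma0=0.12)
        sc = ScenarioConfig(nx=81, ny=81, nz=1, dx=0.02, dt=0.02, duration=30.0,
                            physics="diffusion_only", initial="rest",
                            D_par=Dv, D_perp=Dv, D_trans=Dv)
        built_state = TissueState(np.zeros((17, 81, 81, 1)), 0.0)
        built_state.S[0] = field0
        rec = run_simulation(sc, initial_state=built_state)
        want = evaluator(30.0)
        err = np.linalg.norm(rec.final_state.V - want) / np.linalg.norm(want)
        assert err < 0.01
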