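"""Tip tracking, filaments, spectra, CV and meander on synthetic ground truth."""

import numpy as np
import pytest

from scrollwave.analysis import (PropagationError, classify_dynamics, extract_filaments,
                                 filament_stats, index_quasiperiodic, meander_extent,
                                 measure_cv, power_spectrum, tip_positions)
from scrollwave.fixtures import (synthetic_multitone, synthetic_scroll_volume,
                                 synthetic_spiral_frames)
from scrollwave.geometry import GridSpec
from scrollwave.solver import Recordings

GRID2D = GridSpec(96, 96, 1, dx=0.025)
OMEGA = 2.0 * np.pi / 150.0      # rad/ms: 150 ms rotation period
WAVELEN = 1.5                    # cm


class TestTipTracking:
    def test_uniform_frames_have_no_tips(self):
        frames = [np.full((32, 32), -80.0)] * 4
        track = tip_positions(frames, 10.0, 0.025)
        assert track.counts().sum() == 0
        assert track.gaps.all()

    def test_static_spiral_core_recovered_within_one_voxel(self):
        core = (1.2, 1.15)
        frames, truth = synthetic_spiral_frames(core, OMEGA, WAVELEN, GRID2D,
                                                n_frames=12, dt_frame=10.0)
        track = tip_positions(frames, 10.0, GRID2D.dx)
        assert not track.gaps.any()
        for pts in track.per_frame:
            d = np.linalg.norm(pts - np.asarray(core), axis=1)
            assert d.min() <= GRID2D.dx

    def test_moving_core_followed(self):
        # frame spacing well below a rotation so successive isolines nearly
        # coincide except at the singularity (the tracker's validity regime)
        # the isoline-crossing point carries an O(drift speed / rotation rate)
        # offset from the instantaneous core, so the drift must be slow
        # relative to rotation -- as it is for meandering cardiac spirals
        t = np.arange(24) * 5.0
        path = np.column_stack([1.2 + 0.2 * np.cos(2 * np.pi * t / 4800.0),
                                1.2 + 0.2 * np.sin(2 * np.pi * t / 4800.0)])
        frames, _ = synthetic_spiral_frames(None, OMEGA, WAVELEN, GRID2D,
                                            n_frames=24, dt_frame=5.0, core_path=path)
        track = tip_positions(frames, 5.0, GRID2D.dx)
        linked = track.linked()
        ok = ~np.isnan(linked[:, 0])
        assert ok.sum() >= 16
        mid = 0.5 * (path[:-1] + path[1:])   # tip is defined between frame pairs
        err = np.linalg.norm(linked[ok] - mid[ok], axis=1)
        assert np.max(err) <= 2 * GRID2D.dx

    def test_translation_equivariance(self):
        core = (1.0, 1.0)
        shift_vox = 8
        frames, _ = synthetic_spiral_frames(core, OMEGA, WAVELEN, GRID2D, 6, 10.0)
        shifted = [np.roll(f, shift_vox, axis=0) for f in frames]
        t1 = tip_positions(frames, 10.0, GRID2D.dx)
        t2 = tip_positions(shifted, 10.0, GRID2D.dx)
        # compare tips nearest the (shifted) core to sidestep roll wrap-around
        for p1, p2 in zip(t1.per_frame, t2.per_frame):
            a = p1[np.argmin(np.linalg.norm(p1 - [1.0, 1.0], axis=1))]
            b = p2[np.argmin(np.linalg.norm(p2 - [1.0 + shift_vox * GRID2D.dx, 1.0], axis=1))]
            assert b[0] - a[0] == pytest.approx(shift_vox * GRID2D.dx, abs=1e-6)
            assert b[1] - a[1] == pytest.approx(0.0, abs=1e-6)

    def test_rotation_equivariance(self):
        core = (1.2, 0.9)
        frames, _ = synthetic_spiral_frames(core, OMEGA, WAVELEN, GRID2D, 6, 10.0)
        rotated = [np.rot90(f) for f in frames]    # (x, y) -> (y, L - x)
        t1 = tip_positions(frames, 10.0, GRID2D.dx)
        t2 = tip_positions(rotated, 10.0, GRID2D.dx)
        L = (GRID2D.nx - 1) * GRID2D.dx
        # np.rot90 maps a feature at (x, y) to (L - y, x)
        for p1, p2 in zip(t1.per_frame, t2.per_frame):
            a = p1[np.argmin(np.linalg.norm(p1 - core, axis=1))]
            want = np.array([L - core[1], core[0]])
            b = p2[np.argmin(np.linalg.norm(p2 - want, axis=1))]
            assert np.linalg.norm(b - np.array([L - a[1], a[0]])) < 1e-6

    def test_chirality_flips_with_conjugate_phase(self):
        core = (1.2, 1.2)
        f_ccw, _ = synthetic_spiral_frames(core, OMEGA, WAVELEN, GRID2D, 6, 10.0,
                                           chirality=+1)
        f_cw, _ = synthetic_spiral_frames(core, OMEGA, WAVELEN, GRID2D, 6, 10.0,
                                          chirality=-1)
        c1 = np.concatenate(tip_positions(f_ccw, 10.0, GRID2D.dx).chirality)
        c2 = np.concatenate(tip_positions(f_cw, 10.0, GRID2D.dx).chirality)
        assert np.median(c1) == -np.median(c2) != 0

    def test_frame_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tip_positions([np.zeros((8, 8)), np.zeros((9, 8))], 1.0, 0.02)


GRID3D = GridSpec(64, 64, 8, dx=0.025, dz=0.025)


class TestFilaments:
    def test_straight_filament_from_vertical_polyline(self):
        poly = np.column_stack([np.full(8, 0.8), np.full(8, 0.8),
                                np.arange(8) * GRID3D.dz])
        frames, _ = synthetic_scroll_volume([poly], GRID3D, 4, 10.0,
                                            omega=OMEGA, wavelength=WAVELEN)
        fs = extract_filaments(frames, 10.0, GRID3D.dx, GRID3D.dz)
        assert np.all(fs.counts() == 1)
        f = fs.filaments[0][0]
        assert f.points.shape[0] == 8
        assert f.z_extent == (0.0, 7 * GRID3D.dz)
        assert np.abs(f.points[:, :2] - [0.8, 0.8]).max() <= GRID3D.dx

    def test_helical_filament_recovered_within_one_voxel_hausdorff(self):
        # half-turn helix: adjacent-layer cores stay within the linking radius
        z = np.arange(8) * GRID3D.dz
        poly = np.column_stack([0.8 + 0.15 * np.cos(np.pi * z / (8 * GRID3D.dz)),
                                0.8 + 0.15 * np.sin(np.pi * z / (8 * GRID3D.dz)), z])
        frames, truth = synthetic_scroll_volume([poly], GRID3D, 4, 10.0,
                                                omega=OMEGA, wavelength=WAVELEN)
        fs = extract_filaments(frames, 10.0, GRID3D.dx, GRID3D.dz,
                               linking_radius=4 * GRID3D.dx)
        assert np.all(fs.counts() == 1)
        got = fs.filaments[0][0].points
        want = truth[0]
        dmat = np.linalg.norm(got[:, None, :] - want[None, :, :], axis=2)
        hausdorff = max(dmat.min(axis=0).max(), dmat.min(axis=1).max())
        assert hausdorff <= np.hypot(GRID3D.dx, GRID3D.dz)

    def test_two_disjoint_polylines_give_two_filaments_and_breakage(self):
        zlo = np.arange(3) * GRID3D.dz
        zhi = (np.arange(3) + 5) * GRID3D.dz
        p1 = np.column_stack([np.full(3, 0.5), np.full(3, 0.5), zlo])
        p2 = np.column_stack([np.full(3, 1.1), np.full(3, 1.1), zhi])
        frames, _ = synthetic_scroll_volume([p1, p2], GRID3D, 3, 10.0,
                                            omega=OMEGA, wavelength=WAVELEN)
        fs = extract_filaments(frames, 10.0, GRID3D.dx, GRID3D.dz)
        assert np.all(fs.counts() == 2)
        stats = filament_stats(fs)
        assert stats.transmural_breakage

    def test_empty_medium_has_no_filaments(self):
        frames = [np.full(GRID3D.shape, -80.0)] * 3
        fs = extract_filaments(frames, 10.0, GRID3D.dx, GRID3D.dz)
        assert np.all(fs.counts() == 0)

    def test_attachment_fraction_matches_geometric_oracle(self):
        poly = np.column_stack([np.full(8, 0.8), np.full(8, 0.8),
                                np.arange(8) * GRID3D.dz])
        frames, _ = synthetic_scroll_volume([poly], GRID3D, 3, 10.0,
                                            omega=OMEGA, wavelength=WAVELEN)
        fs = extract_filaments(frames, 10.0, GRID3D.dx, GRID3D.dz)
        center, radius = (0.6, 0.8), 0.18
        stats = filament_stats(fs, obstacle_center=center, obstacle_radius=radius)
        # oracle: fraction of recovered points with |dist_to_axis - R| <= link radius
        pts = np.concatenate([f.points for fl in fs.filaments for f in fl])
        d = np.abs(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) - radius)
        assert stats.attachment_fraction == pytest.approx(
            float(np.mean(d <= fs.linking_radius)))

    def test_single_layer_volume_rejected(self):
        with pytest.raises(ValueError):
            extract_filaments([np.zeros((8, 8, 1))] * 3, 1.0, 0.02, 0.02)


class TestSpectra:
    def test_pure_tone_peak_within_one_bin(self):
        t, x = synthetic_multitone([6.0], [1.0], duration=8192.0, sample_interval=1.0)
        spec = power_spectrum(x, 1.0, transient=0.0)
        assert abs(spec.peaks[0][0] - 6.0) <= spec.df
        assert classify_dynamics(spec) == "periodic"

    def test_two_tone_peaks_recovered_and_indexed(self):
        f1, f2 = 3.5, 5.2
        t, x = synthetic_multitone([f1, f2, f1 + f2, 2 * f1],
                                   [1.0, 0.8, 0.3, 0.2],
                                   duration=16384.0, sample_interval=1.0)
        spec = power_spectrum(x, 1.0, transient=0.0)
        got = sorted(p for p, _ in spec.peaks[:2])
        assert got[0] == pytest.approx(f1, abs=spec.df)
        assert got[1] == pytest.approx(f2, abs=spec.df)
        spec = index_quasiperiodic(spec)
        assert spec.label == "quasiperiodic"
        assert spec.residual < spec.df
        by_freq = dict(zip([p for p, _ in spec.peaks], spec.indices))
        comb = min(by_freq, key=lambda fp: abs(fp - (f1 + f2)))
        assert by_freq[comb] in [(1, 1)]

    def test_harmonic_series_classified_periodic(self):
        f0 = 4.0
        t, x = synthetic_multitone([f0, 2 * f0, 3 * f0], [1.0, 0.5, 0.25],
                                   duration=8192.0, sample_interval=1.0)
        spec = power_spectrum(x, 1.0, transient=0.0)
        assert classify_dynamics(spec) == "periodic"

    def test_white_noise_broadband_and_chaotic(self):
        t, x = synthetic_multitone([], [], duration=8192.0, sample_interval=1.0,
                                   noise_sd=1.0, seed=7)
        spec = power_spectrum(x, 1.0, transient=0.0)
        assert spec.broadband_fraction > 0.5
        assert classify_dynamics(spec) == "chaotic"

    def test_random_peak_positions_fail_indexing(self):
        rng = np.random.default_rng(11)
        freqs = np.sort(rng.uniform(1.0, 40.0, size=6))
        t, x = synthetic_multitone(freqs, np.ones(6), duration=16384.0,
                                   sample_interval=1.0)
        spec = power_spectrum(x, 1.0, transient=0.0)
        spec = index_quasiperiodic(spec, max_index=2, tol_bins=0.2)
        assert spec.label in ("unindexed",)

    def test_parseval_within_one_percent(self):
        t, x = synthetic_multitone([3.0, 8.5], [1.0, 0.4], duration=16384.0,
                                   sample_interval=1.0, noise_sd=0.2, seed=3)
        spec = power_spectrum(x, 1.0, transient=0.0)
        total = spec.power.sum() * spec.df
        var = np.var(x[: len(x) - len(x) % 2] - np.mean(x))
        assert total == pytest.approx(var, rel=0.01)

    def test_threshold_monotonicity_of_classification(self):
        t, x = synthetic_multitone([3.5, 5.2, 8.7], [1.0, 0.8, 0.3],
                                   duration=16384.0, sample_interval=1.0)
        for thresh in (0.2, 0.4, 0.6, 0.9):
            spec = power_spectrum(x, 1.0, transient=0.0)
            assert classify_dynamics(spec, broadband_threshold=thresh) == "quasiperiodic"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.zeros(100), 1.0, transient=0.0)


class TestCvAndMeander:
    def _rec(self, t, va, vb, locs, grid):
        return Recordings(locs, t, np.vstack([va, vb]), np.array([]), [], None)

    def test_cv_from_linear_upstrokes(self):
        g = GridSpec(100, 3, 1, dx=0.02)
        t = np.linspace(0.0, 50.0, 501)
        va = np.where(t > 10.0, 20.0, -85.0) + 0.0
        vb = np.where(t > 20.0, 20.0, -85.0) + 0.0
        rec = self._rec(t, va, vb, [(10, 1, 0), (60, 1, 0)], g)
        cv = measure_cv(rec, g, axis="x")
        assert cv == pytest.approx(50 * 0.02 / 10.0, rel=0.02)

    def test_identical_activation_times_flagged(self):
        g = GridSpec(100, 3, 1, dx=0.02)
        t = np.linspace(0.0, 50.0, 501)
        v = np.where(t > 10.0, 20.0, -85.0) + 0.0
        rec = self._rec(t, v, v, [(10, 1, 0), (60, 1, 0)], g)
        with pytest.raises(PropagationError):
            measure_cv(rec, g, axis="x")

    def test_no_crossing_flagged(self):
        g = GridSpec(100, 3, 1, dx=0.02)
        t = np.linspace(0.0, 50.0, 501)
        va = np.where(t > 10.0, 20.0, -85.0) + 0.0
        rec = self._rec(t, va, np.full_like(t, -85.0), [(10, 1, 0), (60, 1, 0)], g)
        with pytest.raises(PropagationError):
            measure_cv(rec, g, axis="x")

    def test_stationary_tip_zero_extent(self):
        frames, _ = synthetic_spiral_frames((1.2, 1.2), OMEGA, WAVELEN, GRID2D, 14, 10.0)
        track = tip_positions(frames, 10.0, GRID2D.dx)
        assert meander_extent(track) <= 2 * GRID2D.dx

    def test_circular_orbit_extent_is_diameter(self):
        # core drift well below one voxel per frame keeps the isoline-crossing
        # definition clean of arm-crossing artifacts
        r = 0.3
        t = np.arange(600) * 5.0
        path = np.column_stack([1.2 + r * np.cos(2 * np.pi * t / 3000.0),
                                1.2 + r * np.sin(2 * np.pi * t / 3000.0)])
        frames, _ = synthetic_spiral_frames(None, OMEGA, WAVELEN, GRID2D, 600, 5.0,
                                            core_path=path)
        track = tip_positions(frames, 5.0, GRID2D.dx)
        assert meander_extent(track) == pytest.approx(2 * r, abs=3 * GRID2D.dx)

    def test_too_few_points_rejected(self):
        frames, _ = synthetic_spiral_frames((1.2, 1.2), OMEGA, WAVELEN, GRID2D, 3, 10.0)
        track = tip_positions(frames, 10.0, GRID2D.dx)
        with pytest.raises(ValueError):
            meander_extent(track, min_points=10)
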