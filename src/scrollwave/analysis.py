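"""Diagnostics extracted from voltage fields and probe series.

* Spiral-tip tracking: the tip at time t is where the V = V_iso isoline of a
  frame intersects the same isoline of the next frame — the classic
  isoline-crossing definition of the rotation center (phase singularity).
  Sub-voxel positions come from marching-squares contours intersected with
  exact segment geometry.
* Scroll-wave filaments: per-layer tips linked across adjacent z-layers within
  a linking radius; connected chains are reported as ordered polylines.
* Rotation dynamics: windowed periodograms of probe series, with peak
  detection, quasiperiodic indexing of peaks as integer combinations
  m*f1 + n*f2 of two basis frequencies, and a broadband-fraction chaos
  signature.
* Wave-propagation measurements: planar conduction velocity from upstroke
  crossing times, and tip-meander extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from shapely.geometry import MultiLineString
from skimage import measure as skmeasure

__all__ = ["TipTrack", "Filament", "FilamentSet", "SpectrumResult",
           "tip_positions", "extract_filaments", "filament_stats",
           "power_spectrum", "index_quasiperiodic", "classify_dynamics",
           "measure_cv", "meander_extent", "PropagationError"]

V_ISO_DEFAULT = -30.0


class PropagationError(RuntimeError):
    """A wavefront measurement failed (no crossing, degenerate timing)."""


# ---------------------------------------------------------------------------
# tip tracking
# ---------------------------------------------------------------------------

@dataclass
class TipTrack:
    """Tip intersections per frame pair, in physical (cm) coordinates."""

    t: np.ndarray                 # (n_pairs,) time of the earlier frame, ms
    per_frame: list               # per pair: (k, 2) array of (x, y) cm
    chirality: list               # per pair: (k,) array of +-1
    gaps: np.ndarray              # (n_pairs,) True where no tip was found
    dx: float = 1.0

    def all_points(self, t_min: float = -np.inf) -> np.ndarray:
        """Pool all tip points with t >= t_min into an (n, 3) (t, x, y) array."""
        rows = [np.column_stack([np.full(len(p), tt), p])
                for tt, p in zip(self.t, self.per_frame) if len(p) and tt >= t_min]
        return np.concatenate(rows) if rows else np.empty((0, 3))

    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.per_frame])

    def linked(self) -> np.ndarray:
        """Greedy nearest-neighbor single trajectory (NaN across gaps)."""
        out = np.full((len(self.t), 2), np.nan)
        prev = None
        for i, pts in enumerate(self.per_frame):
            if not len(pts):
                continue
            if prev is None:
                out[i] = pts[0]
            else:
                out[i] = pts[np.argmin(np.linalg.norm(pts - prev, axis=1))]
            prev = out[i]
        return out


def _iso_segments(field: np.ndarray, level: float):
    """Marching-squares isolines of a 2-D field, as index-space line strings."""
    contours = skmeasure.find_contours(field, level)
    return [c for c in contours if len(c) >= 2]


def _intersections(lines_a, lines_b):
    """Intersection points of two families of polylines (index coordinates)."""
    if not lines_a or not lines_b:
        return np.empty((0, 2))
    inter = MultiLineString([np.asarray(l) for l in lines_a]).intersection(
        MultiLineString([np.asarray(l) for l in lines_b]))
    pts = []
    if inter.is_empty:
        return np.empty((0, 2))
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.geom_type == "Point":
            pts.append((g.x, g.y))
        elif g.geom_type in ("LineString", "LinearRing"):
            pts.append(np.asarray(g.coords).mean(axis=0))
        elif g.geom_type == "MultiPoint":
            pts.extend((q.x, q.y) for q in g.geoms)
    return np.asarray(pts) if pts else np.empty((0, 2))


def _chirality_at(f1: np.ndarray, f2: np.ndarray, pt_idx: np.ndarray) -> float:
    """Rotation sense at a tip: sign of the z-component of grad(V_t) x grad(V_t+dt)."""
    i = int(round(min(max(pt_idx[0], 1), f1.shape[0] - 2)))
    j = int(round(min(max(pt_idx[1], 1), f1.shape[1] - 2)))
    g1 = np.array([f1[i + 1, j] - f1[i - 1, j], f1[i, j + 1] - f1[i, j - 1]])
    g2 = np.array([f2[i + 1, j] - f2[i - 1, j], f2[i, j + 1] - f2[i, j - 1]])
    return float(np.sign(g1[0] * g2[1] - g1[1] * g2[0]))


def tip_positions(frames, dt_frame: float, dx: float = 1.0,
                  v_iso: float = V_ISO_DEFAULT, times=None) -> TipTrack:
    """Track spiral tips through a sequence of 2-D voltage frames.

    A tip at frame i is an intersection of the V = v_iso isoline of frame i
    with that of frame i+1 (sub-voxel, via marching squares and exact segment
    intersection).  Frames with no intersection are flagged as gaps.
    """
    frames = [np.asarray(f) for f in frames]
    if len(frames) < 2:
        raise ValueError("tip tracking needs at least two frames")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise ValueError("frame shapes differ")
    if times is None:
        times = np.arange(len(frames)) * float(dt_frame)
    t_out, pts_out, chi_out, gaps = [], [], [], []
    segs_prev = _iso_segments(frames[0], v_iso)
    for i in range(len(frames) - 1):
        segs_next = _iso_segments(frames[i + 1], v_iso)
        pts_idx = _intersections(segs_prev, segs_next)
        chi = np.array([_chirality_at(frames[i], frames[i + 1], p) for p in pts_idx]) \
            if len(pts_idx) else np.empty(0)
        t_out.append(times[i])
        pts_out.append(pts_idx * dx)
        chi_out.append(chi)
        gaps.append(len(pts_idx) == 0)
        segs_prev = segs_next
    return TipTrack(np.asarray(t_out), pts_out, chi_out, np.asarray(gaps), dx)


# ---------------------------------------------------------------------------
# filaments
# ---------------------------------------------------------------------------

@dataclass
class Filament:
    """Ordered polyline (x, y, z) in cm of one scroll-wave filament."""

    points: np.ndarray            # (n, 3)

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def z_extent(self) -> tuple[float, float]:
        return float(self.points[:, 2].min()), float(self.points[:, 2].max())


@dataclass
class FilamentSet:
    """Per-time filament collections extracted from volume frames."""

    t: np.ndarray                 # (n_pairs,)
    filaments: list               # per time: list[Filament]
    linking_radius: float
    dx: float
    dz: float

    def counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.filaments])


def extract_filaments(volume_frames, dt_frame: float, dx: float = 1.0, dz: float = 1.0,
                      v_iso: float = V_ISO_DEFAULT, linking_radius: float | None = None,
                      times=None) -> FilamentSet:
    """Extract scroll-wave filaments from a sequence of 3-D voltage frames.

    Runs the 2-D tip tracker in every z-slice, then chains tips of adjacent
    layers whose planar distance is at most the linking radius (default 2*dx).
    Each connected chain, ordered by z, is one filament polyline.
    """
    volume_frames = [np.asarray(f) for f in volume_frames]
    if len(volume_frames) < 2:
        raise ValueError("filament extraction needs at least two volume frames")
    nz = volume_frames[0].shape[2]
    if nz < 2:
        raise ValueError("filament extraction needs nz >= 2")
    if linking_radius is None:
        linking_radius = 2.0 * dx
    if times is None:
        times = np.arange(len(volume_frames)) * float(dt_frame)

    per_layer = []
    for k in range(nz):
        frames_k = [v[:, :, k] for v in volume_frames]
        per_layer.append(tip_positions(frames_k, dt_frame, dx, v_iso, times=times))

    n_pairs = len(volume_frames) - 1
    all_filaments = []
    for i in range(n_pairs):
        layer_tips = [per_layer[k].per_frame[i] for k in range(nz)]
        filaments = _chain_layers(layer_tips, nz, dz, linking_radius)
        all_filaments.append(filaments)
    return FilamentSet(np.asarray(times[:n_pairs]), all_filaments,
                       linking_radius, dx, dz)


def _chain_layers(layer_tips, nz, dz, linking_radius):
    """Greedy transmural chaining of per-layer tips into filament polylines."""
    open_chains: list[list] = []   # each: list of (x, y, z)
    closed: list[list] = []
    for k in range(nz):
        tips = layer_tips[k]
        used = np.zeros(len(tips), dtype=bool)
        still_open = []
        for chain in open_chains:
            cx, cy, _ = chain[-1]
            best, best_d = -1, np.inf
            for idx in range(len(tips)):
                if used[idx]:
                    continue
                d = np.hypot(tips[idx][0] - cx, tips[idx][1] - cy)
                if d < best_d:
                    best, best_d = idx, d
            if best >= 0 and best_d <= linking_radius:
                chain.append((tips[best][0], tips[best][1], k * dz))
                used[best] = True
                still_open.append(chain)
            else:
                closed.append(chain)
        open_chains = still_open
        for idx in range(len(tips)):
            if not used[idx]:
                open_chains.append([(tips[idx][0], tips[idx][1], k * dz)])
    closed.extend(open_chains)
    return [Filament(np.asarray(c)) for c in closed]


@dataclass
class FilamentStats:
    count_over_time: np.ndarray
    max_count: int
    total_length: np.ndarray          # per time, cm
    transmural_breakage: bool
    attachment_fraction: float | None  # vs an obstacle, when given


def filament_stats(fs: FilamentSet, obstacle_center=None, obstacle_radius=None) -> FilamentStats:
    """Bookkeeping over a FilamentSet: counts, lengths, breakage, attachment.

    Transmural breakage is flagged when some time holds >= 2 filaments with
    disjoint z-extents (the filament no longer spans the wall as one piece).
    Attachment, measured against a cylindrical obstacle, is the fraction of
    filament points within one linking radius of the obstacle surface.
    """
    counts = fs.counts()
    lengths = np.array([sum(f.length for f in fl) for fl in fs.filaments])
    breakage = False
    for fl in fs.filaments:
        if len(fl) < 2:
            continue
        for a in range(len(fl)):
            for b in range(a + 1, len(fl)):
                (alo, ahi), (blo, bhi) = fl[a].z_extent, fl[b].z_extent
                if ahi < blo - 1e-12 or bhi < alo - 1e-12:
                    breakage = True
    attach = None
    if obstacle_center is not None and obstacle_radius is not None:
        tot, near = 0, 0
        for fl in fs.filaments:
            for f in fl:
                d_axis = np.hypot(f.points[:, 0] - obstacle_center[0],
                                  f.points[:, 1] - obstacle_center[1])
                near += int(np.sum(np.abs(d_axis - obstacle_radius) <= fs.linking_radius))
                tot += len(f.points)
        attach = near / tot if tot else 0.0
    return FilamentStats(counts, int(counts.max()) if len(counts) else 0,
                         lengths, breakage, attach)


# ---------------------------------------------------------------------------
# spectra and dynamical classification
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    """One-sided power spectrum with peaks and a dynamics classification."""

    f: np.ndarray                  # Hz
    power: np.ndarray
    peaks: list                    # [(f_Hz, power), ...] sorted by power, descending
    df: float                      # frequency-bin width, Hz
    broadband_fraction: float
    f1: float | None = None
    f2: float | None = None
    indices: list | None = None    # [(m, n), ...] aligned with peaks
    residual: float | None = None
    label: str | None = None


def power_spectrum(series, sample_interval: float, transient: float = 500.0,
                   peak_rel_height: float = 0.01, min_samples: int = 1024) -> SpectrumResult:
    """Hann-windowed periodogram of a probe series.

    ``sample_interval`` and ``transient`` are in ms; frequencies are reported
    in Hz.  Peaks are local maxima above ``peak_rel_height`` of the maximum
    power; the broadband fraction is the share of total power lying outside
    +-3 bins of every detected peak.
    """
    x = np.asarray(series, dtype=float)
    n_skip = int(round(transient / sample_interval))
    x = x[n_skip:]
    if x.size < min_samples:
        raise ValueError(f"series too short after transient removal: {x.size} < {min_samples}")
    x = x - x.mean()
    fs = 1000.0 / sample_interval
    f, power = sps.periodogram(x, fs=fs, window="hann", detrend=False)
    f, power = f[1:], power[1:]
    df = f[1] - f[0]

    idx, _ = sps.find_peaks(power, height=peak_rel_height * power.max())
    order = np.argsort(power[idx])[::-1]
    idx = idx[order][:12]
    peaks = []
    for i in idx:
        fp = f[i]
        if 0 < i < power.size - 1 and power[i - 1] > 0 and power[i + 1] > 0:
            # sub-bin refinement: parabola through log-power at the peak
            la, lb, lc = np.log(power[i - 1]), np.log(power[i]), np.log(power[i + 1])
            denom = la - 2 * lb + lc
            if denom < 0:
                fp = fp + 0.5 * (la - lc) / denom * df
        peaks.append((float(fp), float(power[i])))

    mask = np.ones(power.size, dtype=bool)
    for i in idx:
        mask[max(0, i - 3):i + 4] = False
    broadband = float(power[mask].sum() / power.sum()) if power.sum() > 0 else 0.0
    return SpectrumResult(f, power, peaks, float(df), broadband)


def index_quasiperiodic(spec: SpectrumResult, max_index: int = 5,
                        tol_bins: float = 1.5) -> SpectrumResult:
    """Index spectral peaks as m*f1 + n*f2 over two basis frequencies.

    Searches bases among peak pairs, assigns each peak the integer pair
    (|m|, |n| <= max_index) minimizing its mismatch, and keeps the basis with
    the smallest total residual.  With fewer than two peaks, or when every
    peak is a harmonic of a single base, the result is marked periodic.
    Declares failure (label 'unindexed') when the residual exceeds
    ``tol_bins`` frequency bins per peak.
    """
    out = spec
    pk = [p for p, _ in spec.peaks]
    if len(pk) < 2:
        out.label = "periodic" if len(pk) == 1 else None
        if pk:
            out.f1, out.indices, out.residual = pk[0], [(1, 0)], 0.0
        return out
    tol = tol_bins * spec.df
    best = None
    coeffs = range(-max_index, max_index + 1)
    for a in range(len(pk)):
        for b in range(len(pk)):
            if a == b:
                continue
            f1, f2 = pk[a], pk[b]
            if f2 <= f1:
                continue
            pair_rank = a + b   # peaks are power-sorted: prefer dominant pairs
            assign, total, complexity = [], 0.0, 0
            for fp in pk:
                errs = [(abs(fp - (m * f1 + n * f2)), abs(m) + abs(n), (m, n))
                        for m in coeffs for n in coeffs
                        if (m, n) != (0, 0) and m * f1 + n * f2 > 0]
                e, c, mn = min(errs)
                assign.append(mn)
                total += e
                complexity += c
            # equivalent lattices share near-zero residual: prefer the basis
            # built from the dominant peaks with low-order indices (both
            # penalties stay far below the acceptance tolerance)
            score = total + spec.df * (1e-3 * complexity + 0.05 * pair_rank)
            if best is None or score < best[0]:
                best = (score, total, f1, f2, assign)
    _, total, f1, f2, assign = best
    out.residual = total / len(pk)
    if out.residual > tol:
        out.label = "unindexed"
        return out
    if all(n == 0 for _, n in assign):
        out.f1, out.f2, out.indices, out.label = f1, None, assign, "periodic"
        return out
    # a basis whose second frequency is (close to) an integer multiple of the
    # first indexes a harmonic series, not genuine two-frequency dynamics
    ratio = f2 / f1
    if abs(ratio - round(ratio)) * f1 <= tol:
        out.f1, out.f2, out.label = f1, None, "periodic"
        out.indices = [(int(round(fp / f1)), 0) for fp in pk]
        return out
    out.f1, out.f2, out.indices, out.label = f1, f2, assign, "quasiperiodic"
    return out


def classify_dynamics(spec: SpectrumResult, broadband_threshold: float = 0.3,
                      max_index: int = 5, tol_bins: float = 1.5) -> str:
    """Label a spectrum 'periodic', 'quasiperiodic' or 'chaotic'.

    Chaotic: broadband fraction above threshold, or indexing failure with at
    least four peaks.  Quasiperiodic: successful two-frequency indexing.
    Periodic: a single-frequency (harmonic) basis.
    """
    if spec.broadband_fraction > broadband_threshold:
        spec.label = "chaotic"
        return spec.label
    spec = index_quasiperiodic(spec, max_index=max_index, tol_bins=tol_bins)
    if spec.label == "unindexed":
        spec.label = "chaotic" if len(spec.peaks) >= 4 else "periodic"
    elif spec.label is None:
        spec.label = "periodic"
    return spec.label


# ---------------------------------------------------------------------------
# conduction velocity and meander
# ---------------------------------------------------------------------------

def _crossing_time(t: np.ndarray, v: np.ndarray, thresh: float) -> float:
    above = v >= thresh
    if not above.any() or above[0]:
        raise PropagationError("no upstroke crossing at a probe")
    i = int(np.argmax(above))
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    return float(t0 + (thresh - v0) / (v1 - v0) * (t1 - t0))


def measure_cv(recordings, grid, axis: str = "x", v_thresh: float = -30.0,
               probe_a: int = 0, probe_b: int = 1) -> float:
    """Planar-wave conduction velocity (cm/ms) between two probes.

    Uses linear interpolation of the first upstroke crossing of ``v_thresh``
    at each probe; the probe pair must be separated along ``axis``.
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    pa = recordings.probe_locations[probe_a]
    pb = recordings.probe_locations[probe_b]
    spacing = (grid.dx, grid.dy, grid.dz)[ax]
    dist = abs(pb[ax] - pa[ax]) * spacing
    ta = _crossing_time(recordings.probe_t, recordings.probe_V[probe_a], v_thresh)
    tb = _crossing_time(recordings.probe_t, recordings.probe_V[probe_b], v_thresh)
    if tb == ta:
        raise PropagationError("identical activation times: conduction velocity undefined")
    return dist / abs(tb - ta)


def meander_extent(track: TipTrack, transient: float = 0.0, min_points: int = 10) -> float:
    """Linear extent (cm) of the tip trajectory: max over x and y of max-min.

    Follows the nearest-neighbor-linked main trajectory, which is robust to
    the occasional spurious isoline crossing far from the core.
    """
    linked = track.linked()
    keep = (track.t >= transient) & ~np.isnan(linked[:, 0])
    pts = linked[keep]
    if len(pts) < min_points:
        raise ValueError(f"only {len(pts)} tip points after transient; need {min_points}")
    ranges = pts.max(axis=0) - pts.min(axis=0)
    return float(ranges.max())
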