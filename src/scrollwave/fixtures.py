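"""Synthetic ground-truth inputs for verifying every analysis stage.

These generators emulate the *geometry* and *spectral structure* of simulation
output — rotating spiral fields with known cores, scroll volumes built around
prescribed filaments, analytic diffusion solutions, multitone and noise
series — without any ionic kinetics.  Each is reproducible from its arguments
(random kinds require an explicit seed), so tests recover known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridSpec

__all__ = ["FixtureSpec", "analytic_diffusion_field", "synthetic_spiral_frames",
           "synthetic_scroll_volume", "synthetic_multitone", "make_fixture"]


# ---------------------------------------------------------------------------
# analytic diffusion
# ---------------------------------------------------------------------------

def analytic_diffusion_field(D: float, t: float, grid: GridSpec, sigma0: float,
                             center=None, amplitude: float = 100.0, n_images: int = 3):
    """Heat-kernel solution for a Gaussian initial condition, with reflecting
    boundaries approximated by image sources.

    Returns ``(field, evaluator)`` where ``evaluator(t)`` gives the analytic
    field at any time > 0 on the grid.  The solution is separable:
    sigma^2(t) = sigma0^2 + 2 D t per axis, and each axis carries mirror
    image sources enforcing zero flux at the reflecting walls.  The walls sit
    half a grid spacing outside the first and last voxel centers — the
    finite-volume box the solver's flux-form boundary treatment represents.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if center is None:
        center = tuple(e / 2.0 for e in grid.extent)

    axes = [grid.axis_coords(a) for a in range(3)]
    lengths = grid.extent
    spacings = (grid.dx, grid.dy, grid.dz)

    def axis_profile(x, L, h, x0, sig2):
        if L == 0.0:   # degenerate axis (single layer): no spread
            return np.ones_like(x)
        W = L + h                      # wall-to-wall width
        u, u0 = x + h / 2.0, x0 + h / 2.0
        prof = np.zeros_like(x)
        for n in range(-n_images, n_images + 1):
            for s in (+1, -1):
                prof += np.exp(-((u - (2 * n * W + s * u0)) ** 2) / (2.0 * sig2))
        return prof

    def evaluator(tt: float) -> np.ndarray:
        sig2 = sigma0 ** 2 + 2.0 * D * tt
        amp = amplitude * (sigma0 ** 2 / sig2) ** (sum(L > 0 for L in lengths) / 2.0)
        profs = [axis_profile(axes[a], lengths[a], spacings[a], center[a], sig2)
                 for a in range(3)]
        return amp * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]

    return evaluator(t), evaluator


# ---------------------------------------------------------------------------
# rotating spiral / scroll fields
# ---------------------------------------------------------------------------

V_REST_SYNTH = -80.0
V_AMP_SYNTH = 50.0


def _spiral_phase(grid: GridSpec, cores, wavelength: float, chirality: int = +1):
    """Complex field whose argument is the spiral phase; one phase singularity
    per core (an Archimedean-spiral isophase pattern)."""
    x = grid.axis_coords(0)[:, None]
    y = grid.axis_coords(1)[None, :]
    W = np.ones((grid.nx, grid.ny), dtype=complex)
    k_r = 2.0 * np.pi / wavelength
    for (cx, cy) in cores:
        dxp, dyp = x - cx, y - cy
        r = np.hypot(dxp, dyp)
        theta = np.arctan2(dyp, dxp)
        W = W * np.exp(1j * (chirality * theta - k_r * r))
    return W


def synthetic_spiral_frames(core, omega: float, wavelength: float, grid2d: GridSpec,
                            n_frames: int, dt_frame: float, chirality: int = +1,
                            core_path=None):
    """Rigidly rotating spiral voltage frames with known tip location.

    ``core`` is the (x, y) rotation center in cm (or give ``core_path`` as an
    (n_frames, 2) trajectory); ``omega`` in rad/ms; voltage spans a
    physiological range so the default -30 mV isoline exists.  Returns
    ``(frames, true_tips)`` with ``true_tips`` of shape (n_frames, 2).
    """
    if wavelength <= 2.0 * grid2d.dx:
        raise ValueError("wavelength must exceed two grid spacings")
    if core_path is None:
        core_path = np.tile(np.asarray(core, dtype=float), (n_frames, 1))
    core_path = np.asarray(core_path, dtype=float)
    frames = []
    for i in range(n_frames):
        W = _spiral_phase(grid2d, [core_path[i]], wavelength, chirality)
        phase = omega * (i * dt_frame) + np.angle(W)
        frames.append(V_REST_SYNTH + V_AMP_SYNTH * (1.0 + np.cos(phase)))
    return frames, core_path


def synthetic_scroll_volume(filaments, grid: GridSpec, n_frames: int, dt_frame: float,
                            omega: float = 2.0 * np.pi / 150.0, wavelength: float = 2.0,
                            chirality: int = +1):
    """Volume frames built around prescribed filament polylines.

    ``filaments`` is a list of (n, 3) arrays of (x, y, z) points, one point per
    z-layer each filament traverses (z snapped to the nearest layer).  Layers a
    filament crosses carry a spiral with its core at the filament's (x, y)
    there; untouched layers stay at the synthetic resting value.  Returns
    ``(frames, truth)`` with truth the list of snapped polylines.
    """
    filaments = [np.asarray(f, dtype=float) for f in filaments]
    Lx, Ly, _ = grid.extent
    truth = []
    layer_cores: list[list] = [[] for _ in range(grid.nz)]
    for poly in filaments:
        if (poly[:, 0].min() < 0 or poly[:, 0].max() > Lx
                or poly[:, 1].min() < 0 or poly[:, 1].max() > Ly):
            raise ValueError("filament polyline leaves the domain")
        snapped = poly.copy()
        for row in snapped:
            k = int(round(row[2] / grid.dz)) if grid.dz > 0 else 0
            if not 0 <= k < grid.nz:
                raise ValueError("filament polyline leaves the domain along z")
            row[2] = k * grid.dz
            layer_cores[k].append((row[0], row[1]))
        truth.append(snapped)

    frames = []
    base = np.full(grid.shape, V_REST_SYNTH)
    for i in range(n_frames):
        vol = base.copy()
        for k in range(grid.nz):
            if not layer_cores[k]:
                continue
            grid2d = GridSpec(grid.nx, grid.ny, 1, dx=grid.dx, dz=grid.dz)
            W = _spiral_phase(grid2d, layer_cores[k], wavelength, chirality)
            phase = omega * (i * dt_frame) + np.angle(W)
            vol[:, :, k] = V_REST_SYNTH + V_AMP_SYNTH * (1.0 + np.cos(phase))
        frames.append(vol)
    return frames, truth


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def synthetic_multitone(freqs, amps, duration: float, sample_interval: float,
                        noise_sd: float = 0.0, seed: int | None = None, phases=None):
    """Sum of cosines plus seeded Gaussian noise.

    ``freqs`` in Hz, ``duration`` and ``sample_interval`` in ms.  Returns
    ``(t_ms, series)``.  A nonzero ``noise_sd`` requires an explicit seed.
    """
    freqs = np.asarray(freqs, dtype=float)
    nyquist = 0.5 * 1000.0 / sample_interval
    if np.any(freqs >= nyquist):
        raise ValueError(f"frequencies must lie below the Nyquist limit {nyquist:.1f} Hz")
    t = np.arange(0.0, duration, sample_interval)
    if phases is None:
        phases = np.zeros_like(freqs)
    x = np.zeros_like(t)
    for f0, a, ph in zip(freqs, np.asarray(amps, dtype=float), phases):
        x += a * np.cos(2.0 * np.pi * f0 * t / 1000.0 + ph)
    if noise_sd:
        if seed is None:
            raise ValueError("noisy fixtures require an explicit seed")
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return t, x


# ---------------------------------------------------------------------------
# declarative front end
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Declarative fixture: a kind plus its keyword parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    KINDS = ("gaussian_diffusion", "spiral_frames", "scroll_volume", "multitone", "noise")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {self.KINDS}")
        if self.kind == "noise" and "seed" not in self.params:
            raise ValueError("noise fixtures require an explicit seed")


def make_fixture(spec: FixtureSpec):
    """Build the fixture named by ``spec``; see the individual generators."""
    p = dict(spec.params)
    if spec.kind == "gaussian_diffusion":
        grid = p.pop("grid") if "grid" in p else GridSpec(
            p.pop("nx", 33), p.pop("ny", 33), p.pop("nz", 1), dx=p.pop("dx", 0.02))
        return analytic_diffusion_field(grid=grid, **p)
    if spec.kind == "spiral_frames":
        grid = p.pop("grid") if "grid" in p else GridSpec(
            p.pop("nx", 96), p.pop("ny", 96), 1, dx=p.pop("dx", 0.025))
        return synthetic_spiral_frames(grid2d=grid, **p)
    if spec.kind == "scroll_volume":
        grid = p.pop("grid") if "grid" in p else GridSpec(
            p.pop("nx", 64), p.pop("ny", 64), p.pop("nz", 8), dx=p.pop("dx", 0.025))
        return synthetic_scroll_volume(grid=grid, **p)
    if spec.kind == "multitone":
        return synthetic_multitone(**p)
    if spec.kind == "noise":
        seed = p.pop("seed")
        duration = p.pop("duration", 4096.0)
        si = p.pop("sample_interval", 1.0)
        sd = p.pop("noise_sd", 1.0)
        return synthetic_multitone([], [], duration, si, noise_sd=sd, seed=seed)
    raise AssertionError
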