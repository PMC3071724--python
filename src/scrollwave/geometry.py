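"""Spatial problem setup: grid, fiber field, diffusion tensor, obstacles, layers.

The tissue slab is a regular grid of voxel *centers* at ``index * spacing``
(node-centered; physical extent ``(n-1) * spacing``).  Muscle fibers lie in
x-y planes; their angle to the +x axis rotates linearly with the transmural
coordinate z (total rotation ``dtheta_total``).  Conduction anisotropy enters
through a symmetric per-voxel diffusion tensor with in-plane components

    D_xx = D_par cos^2(theta) + D_perp sin^2(theta)
    D_yy = D_par sin^2(theta) + D_perp cos^2(theta)
    D_xy = (D_par - D_perp) sin(theta) cos(theta)
    D_zz = D_trans

Cylindrical inhomogeneities (axis along z, spanning the wall) are either
*conduction* obstacles — diffusivity set near zero inside and the voltage
clamped to an isopotential value — or *ionic* obstacles, which rescale one
named conductance inside while leaving conduction intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cell import CELL_TYPES, CellParameters, SCALABLE_PARAMS

__all__ = [
    "GridSpec", "FiberField", "DiffusivityField", "Inhomogeneity",
    "TransmuralLayout", "ParamMap", "fiber_angles", "build_diffusivity",
    "apply_inhomogeneity", "assign_transmural",
]

#: default along-fiber diffusivity (cm^2/ms); cross-fiber and transmural are
#: D_par/9 so the along/across conduction-velocity ratio is ~3
D_PAR_DEFAULT = 1.54e-3
D_PERP_DEFAULT = D_PAR_DEFAULT / 9.0
D_TRANS_DEFAULT = D_PAR_DEFAULT / 9.0
D_OBSTACLE_DEFAULT = 1.0e-6


class ConfigError(ValueError):
    """Invalid geometry or scenario configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel counts and spacings (cm).  dx = dy in-plane, dz transmural."""

    nx: int
    ny: int
    nz: int = 1
    dx: float = 0.02
    dz: float = 0.02

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigError("voxel counts must be >= 1")
        if self.dx <= 0 or self.dz <= 0:
            raise ConfigError("grid spacings must be positive")

    @property
    def dy(self) -> float:
        return self.dx

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extents (cm): (n-1) * spacing per axis."""
        return ((self.nx - 1) * self.dx, (self.ny - 1) * self.dx, (self.nz - 1) * self.dz)

    @property
    def thickness(self) -> float:
        return (self.nz - 1) * self.dz

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        d = (self.dx, self.dy, self.dz)[axis]
        return np.arange(n) * d


@dataclass(frozen=True)
class FiberField:
    """Per-layer fiber angle; affine in the layer index."""

    theta: np.ndarray            # radians, shape (nz,)
    dtheta_total_deg: float      # total transmural rotation, degrees

    @property
    def rotation_rate(self) -> float:
        """Rotation rate alpha (radians/cm) for the grid it was built on."""
        return self._alpha

    _alpha: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))


def fiber_angles(grid: GridSpec, dtheta_total_deg: float) -> FiberField:
    """Linear transmural fiber-rotation profile: theta_k = dtheta * k/(nz-1).

    The bottom layer is the angle origin (theta_0 = 0, fibers along +x).
    A single-layer grid carries the single angle 0.
    """
    nz = grid.nz
    total = np.deg2rad(dtheta_total_deg)
    if nz == 1:
        theta = np.zeros(1)
        alpha = 0.0
    else:
        theta = total * np.arange(nz) / (nz - 1)
        alpha = total / grid.thickness
    return FiberField(theta=theta, dtheta_total_deg=dtheta_total_deg, _alpha=alpha)


@dataclass
class DiffusivityField:
    """Per-voxel symmetric diffusion tensor (cm^2/ms), D_xy stored once."""

    Dxx: np.ndarray
    Dyy: np.ndarray
    Dxy: np.ndarray
    Dzz: np.ndarray
    D_par: float
    D_perp: float
    D_trans: float

    def copy(self) -> "DiffusivityField":
        return DiffusivityField(self.Dxx.copy(), self.Dyy.copy(), self.Dxy.copy(),
                                self.Dzz.copy(), self.D_par, self.D_perp, self.D_trans)

    @property
    def max_diag(self) -> float:
        return max(self.Dxx.max(), self.Dyy.max(), self.Dzz.max())


def build_diffusivity(fibers: FiberField, grid: GridSpec,
                      D_par: float = D_PAR_DEFAULT,
                      D_perp: float = D_PERP_DEFAULT,
                      D_trans: float = D_TRANS_DEFAULT) -> DiffusivityField:
    """Rotate the fiber-frame diffusivities into per-voxel tensor components."""
    if not (D_par >= D_perp > 0.0):
        raise ConfigError("diffusivities must satisfy D_par >= D_perp > 0")
    if D_trans <= 0.0:
        raise ConfigError("D_trans must be positive")
    th = fibers.theta[np.newaxis, np.newaxis, :]
    c, s = np.cos(th), np.sin(th)
    shape = grid.shape
    Dxx = np.broadcast_to(D_par * c ** 2 + D_perp * s ** 2, shape).copy()
    Dyy = np.broadcast_to(D_par * s ** 2 + D_perp * c ** 2, shape).copy()
    Dxy = np.broadcast_to((D_par - D_perp) * s * c, shape).copy()
    Dzz = np.full(shape, D_trans)
    return DiffusivityField(Dxx, Dyy, Dxy, Dzz, D_par, D_perp, D_trans)


@dataclass
class Inhomogeneity:
    """Cylindrical inhomogeneity, axis along z spanning the full thickness.

    ``kind='conduction'``: an inexcitable isopotential core — all tensor
    components set to ``D_obs`` inside and the voltage clamped to ``V_obs``.
    ``kind='ionic'``: the conductance named ``target`` is multiplied by
    ``scale`` inside; conduction is untouched.
    """

    kind: str
    center: tuple[float, float]      # (x_c, y_c) in cm
    radius: float                    # cm
    D_obs: float = D_OBSTACLE_DEFAULT
    V_obs: float = -86.2             # defaults to the epicardial resting potential
    target: str = "G_CaL"
    scale: float = 0.25

    def __post_init__(self):
        if self.kind not in ("conduction", "ionic"):
            raise ConfigError(f"unknown inhomogeneity kind {self.kind!r}")
        if self.radius <= 0:
            raise ConfigError("inhomogeneity radius must be positive")
        if self.kind == "ionic" and self.target not in SCALABLE_PARAMS:
            raise ConfigError(
                f"unknown conductance {self.target!r}; choose from {SCALABLE_PARAMS}")

    def mask(self, grid: GridSpec) -> np.ndarray:
        """Boolean membership: voxel center within distance R of the axis."""
        x = grid.axis_coords(0)[:, None]
        y = grid.axis_coords(1)[None, :]
        inside2d = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius ** 2
        return np.repeat(inside2d[:, :, None], grid.nz, axis=2)


@dataclass
class ParamMap:
    """Per-voxel cell parameters: a 12-component conductance field plus the
    cell-type label map.  All non-scalable constants are shared via ``base``."""

    G: np.ndarray            # (12, nx, ny, nz), ordered as SCALABLE_PARAMS
    cell_type: np.ndarray    # (nx, ny, nz) uint8 index into CELL_TYPES
    base: CellParameters

    @classmethod
    def uniform(cls, grid: GridSpec, params: CellParameters) -> "ParamMap":
        G = np.empty((len(SCALABLE_PARAMS),) + grid.shape)
        for i, name in enumerate(SCALABLE_PARAMS):
            G[i] = getattr(params, name)
        ct = np.full(grid.shape, CELL_TYPES.index(params.cell_type), dtype=np.uint8)
        return cls(G, ct, params)

    def copy(self) -> "ParamMap":
        return ParamMap(self.G.copy(), self.cell_type.copy(), self.base)

    def scale_in(self, mask: np.ndarray, name: str, factor: float):
        self.G[SCALABLE_PARAMS.index(name)][mask] *= factor

    @property
    def endo_mask(self) -> np.ndarray:
        return self.cell_type == CELL_TYPES.index("endo")

    def params_at(self, idx: tuple[int, int, int]) -> CellParameters:
        """Materialize the full parameter set of one voxel (for diagnostics)."""
        over = {n: float(self.G[i][idx]) for i, n in enumerate(SCALABLE_PARAMS)}
        return replace(self.base, cell_type=CELL_TYPES[int(self.cell_type[idx])], **over)


def apply_inhomogeneity(Dfield: DiffusivityField, param_map: ParamMap,
                        inhom: Inhomogeneity, grid: GridSpec):
    """Apply one cylindrical inhomogeneity in place.

    Returns ``(Dfield, param_map, mask)``; for a conduction obstacle the mask
    doubles as the voltage-clamp mask.  Voxels outside the mask are untouched.
    """
    mask = inhom.mask(grid)
    if not mask.any():
        warnings.warn("inhomogeneity cylinder lies entirely outside the domain; empty mask",
                      stacklevel=2)
        return Dfield, param_map, mask
    if inhom.kind == "conduction":
        for comp in (Dfield.Dxx, Dfield.Dyy, Dfield.Dzz):
            comp[mask] = inhom.D_obs
        Dfield.Dxy[mask] = 0.0
    else:
        param_map.scale_in(mask, inhom.target, inhom.scale)
    return Dfield, param_map, mask


@dataclass
class TransmuralLayout:
    """Slab widths (cm) of the endo, mid and epi layers along +z."""

    w_endo: float
    w_mid: float
    w_epi: float

    def __post_init__(self):
        if min(self.w_endo, self.w_mid, self.w_epi) < 0:
            raise ConfigError("slab widths must be non-negative")

    @property
    def total(self) -> float:
        return self.w_endo + self.w_mid + self.w_epi


def assign_transmural(grid: GridSpec, layout: TransmuralLayout) -> np.ndarray:
    """Label each z-layer endo/mid/epi by the slab containing its voxel center.

    Returns a (nz,) uint8 array of indices into ``CELL_TYPES``.  A center that
    sits exactly on a slab boundary belongs to the lower (smaller-z) slab.
    Widths must sum to the domain thickness within half a voxel.
    """
    if abs(layout.total - grid.thickness) > 0.5 * grid.dz + 1e-12:
        raise ConfigError(
            f"slab widths sum to {layout.total:.4f} cm but the domain thickness is "
            f"{grid.thickness:.4f} cm (w_endo + w_mid + w_epi must match)")
    z = grid.axis_coords(2)
    labels = np.empty(grid.nz, dtype=np.uint8)
    endo_i, mid_i, epi_i = (CELL_TYPES.index(t) for t in ("endo", "mid", "epi"))
    for k, zk in enumerate(z):
        if zk <= layout.w_endo:
            labels[k] = endo_i
        elif zk <= layout.w_endo + layout.w_mid:
            labels[k] = mid_i
        else:
            labels[k] = epi_i
    return labels


def transmural_param_map(grid: GridSpec, layout: TransmuralLayout,
                         overrides: dict | None = None) -> ParamMap:
    """Build a per-voxel parameter map with published layer-specific values."""
    labels = assign_transmural(grid, layout)
    base = CellParameters.from_cell_type("epi", **(overrides or {}))
    pm = ParamMap.uniform(grid, base)
    for k, lab in enumerate(labels):
        ct = CELL_TYPES[int(lab)]
        p = CellParameters.from_cell_type(ct, **(overrides or {}))
        pm.cell_type[:, :, k] = lab
        for i, name in enumerate(SCALABLE_PARAMS):
            pm.G[i, :, :, k] = getattr(p, name)
    return pm
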