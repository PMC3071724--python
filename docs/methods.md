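# Methods

## Model

`scrollwave` simulates electrical activity of human ventricular tissue with the
monodomain reaction–diffusion equation

    dV/dt = div( D(x) grad V ) − I_ion(V, s) − I_stim,

where `V` is the transmembrane potential (mV), `I_ion` the total ionic current
density per unit membrane capacitance (pA/pF, so no explicit capacitance
appears), and `D` a symmetric diffusivity tensor (cm²/ms).  Following the
convention of the underlying cell model, a depolarizing stimulus current is
negative (−52 pA/pF for 1–2 ms is the standard suprathreshold pulse).

`I_ion` is the ten Tusscher–Noble–Noble–Panfilov (TNNP, 2004) human
ventricular myocyte model: twelve currents (fast Na⁺; L-type Ca²⁺;
transient-outward, slow and rapid delayed-rectifier and inward-rectifier K⁺;
Na⁺/Ca²⁺ exchanger; Na⁺/K⁺ pump; plateau and background Ca²⁺ and K⁺/Na⁺
currents), twelve gating variables, and dynamic intracellular Na⁺, K⁺, Ca²⁺
and SR Ca²⁺ concentrations.  The complete parameter tables, including the
epicardial/mid-myocardial/endocardial differences in the transient-outward
conductance `G_to` and the slow delayed-rectifier conductance `G_Ks`, are
frozen in `src/scrollwave/data/tnnp2004.toml`; the module
`scrollwave.cell` is a direct transcription of the published equations.

Two quirks of the published formulation are handled explicitly:

* The calcium-sensing gates `f_Ca` and `g` follow the published conditional
  update (no re-opening while `V ≥ −60 mV`; ties resolve to "no update").
  The published `f_Ca` steady state slightly exceeds 1 at diastolic Ca²⁺
  (max ≈ 1.048); both gates are clipped into [0, 1] as part of the update so
  the gate invariant holds.
* The L-type Ca²⁺ driving term has a removable singularity at `V = 0`; it is
  evaluated by its analytic limit within 10⁻⁸ of zero.

## Numerics

**Time marching.** `V` and the ion concentrations advance by forward Euler.
Gating variables use the exponential (Rush–Larsen) update
`x ← x∞ + (x − x∞)·exp(−dt/τx)` by default.  This is the published scheme for
this cell model and is required in practice: the fast Na⁺ activation gate has
`τ_m` below 10⁻³ ms near rest, so forward-Euler gating is unconditionally
unstable at any usable `dt`.  A forward-Euler gate mode remains available
(`method="euler"`, usable only with `dt` well below `τ_m`).  Both modes share
one kernel: the update is `x ← x + (x∞ − x)·k(V)` with `k = dt/τ` (Euler) or
`k = 1 − exp(−dt/τ)` (Rush–Larsen).

**Lookup tables.** All voltage-dependent gate coefficients and current
prefactors are tabulated on a 0.02 mV grid over [−100, 80] mV and linearly
interpolated inside a compiled (numba) per-voxel kernel — the standard device
in cardiac tissue simulation.  Tables are generated from the same NumPy
expressions as the reference implementation, which also serves as the `exact`
solver backend; the test suite holds the two within 2·10⁻⁷ per step and
0.05 mV over a full action potential.  The inward-rectifier activation is
tabulated against `V − E_K` because `E_K` drifts with intracellular K⁺.

**Space.** Regular grid with voxel centers at `index·spacing`
(`dx = dy` in-plane, `dz` transmural).  The diffusion operator is a
conservative flux-form discretization: seven-point neighborhood for the
diagonal tensor terms, plus the in-plane cross terms `∂x(Dxy ∂y V) +
∂y(Dxy ∂x V)` as face-averaged mixed-derivative fluxes over the four diagonal
neighbors (an effective 11-point in-plane stencil; a literal 7-point stencil
cannot represent `Dxy`, so the cross terms are switchable via
`cross_terms=False` to probe their effect).  Omitting boundary fluxes
implements zero normal flux through walls half a spacing outside the outermost
voxel centers (the finite-volume reading of the grid); the scheme conserves
the domain integral of V to round-off and is second-order accurate, verified
against the analytic spreading Gaussian (relative L2 error 7·10⁻⁴ at
dx = 0.02 cm, error ratio ≈ 4.5 on halving dx).

**Stability.** The explicit step must satisfy
`dt ≤ 0.5 / max(Dxx/dx² + Dyy/dy² + Dzz/dz²)` (the isotropic textbook bound
`dx²/(2·n_dim·D)` in disguise).  `check_stability` blocks a run that violates
it unless explicitly overridden.  The default `dt` is 0.02 ms; scaled-down
scenario presets use 0.05 ms with Rush–Larsen gating, well inside both the
diffusive bound and the cell model's accuracy regime.

**Blow-up detection.** Non-finite values are scanned every 50 steps and
reported with the offending state component, voxel index and time.

## Anisotropy and fiber rotation

Muscle fibers lie in x–y planes at angle θ(z) to +x, rotating linearly across
the wall by a configurable total angle Δθ.  The tensor components are

    Dxx = D∥cos²θ + D⊥sin²θ,  Dyy = D∥sin²θ + D⊥cos²θ,
    Dxy = (D∥ − D⊥) sinθ cosθ,  Dzz = D_t,

with defaults `D∥ = 1.54·10⁻³ cm²/ms` and `D⊥ = D_t = D∥/9`, chosen so the
along/across conduction-velocity ratio is ≈ 3 (≈ √9), the anisotropy commonly
reported for ventricular myocardium.  On a fine strip (dx = 0.0075 cm) the
measured ratio is 3.2; the residual excess over 3 is the usual discretization
slowing of the narrow cross-fiber wavefront (width ≈ 0.02 cm).

This wavefront width sets a hard resolution constraint: at scaled-down
in-plane spacings (0.025–0.05 cm), cross-fiber propagation with the full 9:1
anisotropy is numerically blocked (the front spans less than one voxel).
The scaled-down presets therefore use the strongest anisotropy that
propagates robustly at their spacing — in-plane `D⊥ = D∥/2` with transmural
`D_t = D∥/4` for the 3-D slabs (dx = 0.05 cm, dz = 0.025 cm), isotropic
`D = D∥` for the 2-D sheets.  The full-resolution default remains 9:1 and is
what the conduction-velocity study measures on fine strips.

## Inhomogeneities and transmural heterogeneity

Cylindrical inhomogeneities span the wall along z; membership is tested at
voxel centers.  A *conduction* obstacle (scar) sets every tensor component to
`D_obs = 10⁻⁶ cm²/ms` inside and clamps the voltage to `V_obs` (default: the
epicardial resting potential), i.e. a solid isopotential core; cell dynamics
inside are frozen.  An *ionic* obstacle multiplies one named conductance by a
factor inside (default `G_CaL × 0.25`) and leaves conduction untouched, so
waves can enter it.  Transmural heterogeneity divides the wall into
endo/mid/epi slabs (defaults 5/5/2 mm); each z-layer takes the published
layer-specific parameters of the slab containing its center, with a center on
a slab boundary assigned to the lower slab.

## Initial conditions

Spirals are created by a cross-field S1–S2 protocol on a 2-D sheet: a planar
S1 wave from the x = 0 edge, then a half-plane S2 (lower half in y) inside the
vulnerable window of the S1 recovery gradient.  The window is found
automatically by probing the mid-domain recovery time and scanning S2 offsets
around it; genesis is verified by requiring exactly one tracked tip over the
final 200 ms, and fails loudly otherwise.  Scrolls are built by stacking the
2-D spiral state identically in every z-layer, producing a straight transmural
filament; a stacked state remains z-invariant indefinitely when both the
medium and the parameters are z-uniform and fiber rotation is absent.

## Diagnostics

**Tips.** The spiral tip at time t is the intersection of the `V = −30 mV`
isoline at t with the same isoline at t + Δt (marching-squares contours,
exact segment intersection; sub-voxel positions).  Chirality is the sign of
the vertical component of ∇V(t) × ∇V(t+Δt) at the tip.  Two properties of
this classic definition matter for interpretation: a drifting spiral's
reported tip is offset from the instantaneous core by O(drift speed /
rotation rate), and widely spaced frames of a fast-drifting pattern can
produce occasional spurious arm crossings far from the core.  Meander extent
(max over x and y of the coordinate range) therefore follows the
nearest-neighbor-linked trajectory, which is robust to isolated outliers.

**Filaments.** The 2-D tracker runs in every z-slice; tips in adjacent layers
within a linking radius (default 2·dx) are chained greedily into ordered
polylines.  Reported statistics — filament count over time, arc length,
transmural extent, breakage (≥ 2 filaments with disjoint z-ranges), and
attachment (fraction of filament points within one linking radius of an
obstacle's surface) — are pure bookkeeping, with no model inference.

**Spectra.** Hann-windowed periodograms of probe series (transient discarded,
default 500 ms; ≥ 1024 samples required).  Peaks are local maxima above 1% of
the spectral maximum, refined to sub-bin precision by parabolic interpolation
of log-power.  Quasiperiodic indexing searches bases (f₁, f₂) among peak
pairs and integer pairs |m|, |n| ≤ 5 minimizing Σ|f_peak − (m f₁ + n f₂)|;
equivalent lattice bases are disambiguated by preferring dominant peaks and
low-order indices (penalties far below the acceptance tolerance of 1.5 bins
per peak).  A harmonic series collapses to a periodic label; indexing failure
with ≥ 4 peaks, or a broadband fraction above 0.3 (power outside ±3 bins of
every peak), is labeled chaotic.  Raising the broadband threshold can only
move labels toward "quasiperiodic/periodic", never toward "chaotic".

**Conduction velocity.** Planar-wave runs on thin strips; CV is probe
separation divided by the difference of −30 mV upstroke-crossing times
(linear interpolation between samples).

## Scaled-down study conditions

The published experiments ran on cluster-scale domains (≈ 10 cm sheets).
This model's spiral wavelength (CV × rotation period ≈ 14 cm) sets a hard
floor on the physical sheet size that can sustain reentry: systematic
vulnerable-window scans showed every spiral annihilating at the boundary
within ~500 ms in sheets of 3.2–4.8 cm (any dx from 0.025 to 0.04 cm, both
cell variants, 128²–256² grids), while a 6.4 cm sheet sustains both the
default and the quartered-`G_CaL` spiral beyond one second.

The scaled-down presets are therefore 128×128 sheets at dx = 0.05 cm
(6.4 cm × 6.4 cm) and 128×128×8 slabs with dz = 0.025 cm (a 2 mm wall, the
thickness of a human epicardial layer), dt = 0.05 ms, obstacle radii 0.25 cm
(small) and 1.0 cm (large), fiber-rotation default 60° for obstacle
scenarios.  At that spacing the cross-fiber wavefront of the full 9:1
anisotropy is numerically blocked, so 2-D sheets run isotropic at `D∥` and
the 3-D slab runs the strongest resolvable in-plane ratio (2:1) with
transmural `D∥/4`; the 9:1 default remains in force everywhere resolution
permits, including the conduction-velocity study.  A
`full_scale_epicardial` preset documents a full-size geometry for cluster
use.

Two deliberate consequences of the coarse sheet spacing are worth naming:
conduction velocity is ~15% below its converged value, and the marginally
resolved core rotates with little drift (the measured default-variant meander
extent, ~0.2 cm, is the *weak*-meander baseline the regime study records;
the quartered-`G_CaL` variant meanders over ~5 cm on the same sheet).  The
contrasts asserted by the acceptance studies are qualitative orderings, which
are robust to these biases; absolute extents and frequencies at preset sizes
are not the published full-scale values.

## Synthetic fixtures: what they do and do not show

The fixture generators produce rotating Archimedean-spiral phase fields with
known cores/filaments, analytic diffusion solutions, and multitone/noise
series.  They validate the *geometric and spectral* analysis chain —
tip/filament recovery to sub-voxel accuracy, frequency recovery and
classification — and the diffusion half of the solver, independently of the
ionic model.  They do not emulate action-potential morphology, restitution or
wavefront-waveback interactions; conclusions about those rest on the ionic
model tests and the simulation-based acceptance checks.  Fixtures are
bit-reproducible from their arguments; noisy kinds require an explicit seed.

## Known limitations

* Monodomain only; no bidomain effects, no realistic anatomy or DT-MRI fiber
  fields (out of scope by design).
* Explicit Euler time stepping only; no operator splitting or adaptivity.
* The scaled-down presets trade anisotropy strength and domain size for
  single-CPU tractability, as described above; quantitative rotation
  frequencies and meander extents at preset sizes are not the published
  full-scale values, and only the qualitative contrasts are asserted.
* The tip tracker's drift bias (above) is shared by all isoline-crossing
  definitions; a phase-singularity tracker via time-delay phase maps would be
  the natural extension.
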