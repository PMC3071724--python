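"""Single-cell ionic kinetics of the TNNP human ventricular model.

Implements the ten Tusscher-Noble-Noble-Panfilov (2004) formulation: 12 ionic
currents (six major, six minor), 12 gating variables, the Na+/K+ pump and the
Na+/Ca2+ exchanger, with dynamic intracellular Na+, K+, Ca2+ and SR Ca2+
concentrations.  Units follow the published formulation: time in ms, voltage in
mV, current densities in pA/pF, conductances in nS/pF, concentrations in mM.

This module is the *reference* implementation, written with plain NumPy so
every expression is legible and broadcastable over arrays of states.  The
tissue solver uses a numerically equivalent lookup-table kernel
(:mod:`scrollwave.kernels`) that is cross-checked against this module in the
test suite.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "CellParameters",
    "CellState",
    "CurrentBreakdown",
    "GATE_NAMES",
    "CURRENT_NAMES",
    "CELL_TYPES",
    "gate_dynamics",
    "ionic_currents",
    "step_cell",
    "find_rest",
    "load_model_tables",
]

GATE_NAMES = ("m", "h", "j", "d", "f", "f_Ca", "r", "s", "x_s", "x_r1", "x_r2", "g")
CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bNa", "I_bCa",
)
CELL_TYPES = ("epi", "mid", "endo")

#: conductance-like parameters an ionic inhomogeneity may rescale
SCALABLE_PARAMS = (
    "G_Na", "G_CaL", "G_to", "G_Ks", "G_Kr", "G_K1",
    "G_pCa", "G_pK", "G_bNa", "G_bCa", "P_NaK", "k_NaCa",
)


def load_model_tables() -> dict:
    """Return the frozen TNNP-2004 parameter tables shipped with the package."""
    with resources.files("scrollwave.data").joinpath("tnnp2004.toml").open("rb") as fh:
        return tomllib.load(fh)


class InvalidStateError(ValueError):
    """A cell state violates its invariants (gate range, positivity, finiteness)."""


class NumericalBlowupError(RuntimeError):
    """A non-finite value appeared during integration."""

    def __init__(self, component: str, t: float | None = None, index=None):
        self.component = component
        self.t = t
        self.index = index
        loc = "" if index is None else f" at voxel {index}"
        when = "" if t is None else f" at t={t:.3f} ms"
        super().__init__(f"non-finite value in '{component}'{loc}{when}")


class NoRestError(RuntimeError):
    """Equilibration failed to reach the resting-state criterion."""


@dataclass
class CellParameters:
    """TNNP-2004 parameter set for one cell type.

    Conductances in nS/pF (``G_CaL`` in the published cm^3 uF^-1 s^-1 units),
    pump/exchanger maxima in pA/pF, extracellular concentrations in mM.
    """

    cell_type: str = "epi"
    # maximal conductances / fluxes
    G_Na: float = 14.838
    G_CaL: float = 0.000175
    G_to: float = 0.294
    G_Ks: float = 0.245
    G_Kr: float = 0.096
    G_K1: float = 5.405
    G_pCa: float = 0.825
    G_pK: float = 0.0146
    G_bNa: float = 0.00029
    G_bCa: float = 0.000592
    P_NaK: float = 1.362
    k_NaCa: float = 1000.0
    # extracellular milieu
    Na_o: float = 140.0
    K_o: float = 5.4
    Ca_o: float = 2.0
    # exchanger / pump / permeation constants
    gamma: float = 0.35
    K_mCa: float = 1.38
    K_mNai: float = 87.5
    k_sat: float = 0.1
    alpha: float = 2.5
    K_mK: float = 1.0
    K_mNa: float = 40.0
    p_KNa: float = 0.03
    K_pCa: float = 0.0005
    # SR calcium handling
    a_rel: float = 0.016464
    b_rel: float = 0.25
    c_rel: float = 0.008232
    V_maxup: float = 0.000425
    K_up: float = 0.00025
    V_leak: float = 8.0e-5
    tau_fCa: float = 2.0
    tau_g: float = 2.0
    # buffering
    Buf_c: float = 0.15
    K_bufc: float = 0.001
    Buf_sr: float = 10.0
    K_bufsr: float = 0.3
    # physical constants / geometry
    R: float = 8314.472
    T: float = 310.0
    F: float = 96485.3415
    Cm: float = 0.185
    V_c: float = 0.016404
    V_sr: float = 0.001094

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}; expected one of {CELL_TYPES}")
        for name in SCALABLE_PARAMS:
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")

    @classmethod
    def from_cell_type(cls, cell_type: str = "epi", **overrides) -> "CellParameters":
        """Build the published parameter set for ``cell_type`` (epi/mid/endo)."""
        tab = load_model_tables()
        kw: dict = {"cell_type": cell_type}
        kw.update(tab["conductances"])
        layer = kw.pop("by_cell_type")
        try:
            kw.update(layer[cell_type])
        except KeyError:
            raise ValueError(f"unknown cell_type {cell_type!r}") from None
        kw.update(tab["extracellular"])
        kw.update(tab["exchanger"])
        kw.update(tab["pump"])
        kw.update(tab["permeation"])
        kw.update(tab["sr_handling"])
        kw.update(tab["buffering"])
        kw.update(tab["physical"])
        kw.update(overrides)
        return cls(**kw)

    def scaled(self, **factors) -> "CellParameters":
        """Return a copy with named conductances multiplied by the given factors."""
        changes = {}
        for name, f in factors.items():
            if name not in SCALABLE_PARAMS:
                raise ValueError(f"{name!r} is not a scalable conductance; choose from {SCALABLE_PARAMS}")
            changes[name] = getattr(self, name) * f
        return dataclasses.replace(self, **changes)

    @property
    def rt_over_f(self) -> float:
        return self.R * self.T / self.F


@dataclass
class CellState:
    """Membrane potential, 12 gates and 4 dynamic concentrations.

    Every field may be a scalar or an ndarray (all broadcast-compatible), so a
    whole tissue can be carried as one ``CellState`` of 3-D arrays.
    """

    V: np.ndarray | float = -86.2
    m: np.ndarray | float = 0.0
    h: np.ndarray | float = 0.75
    j: np.ndarray | float = 0.75
    d: np.ndarray | float = 0.0
    f: np.ndarray | float = 1.0
    f_Ca: np.ndarray | float = 1.0
    r: np.ndarray | float = 0.0
    s: np.ndarray | float = 1.0
    x_s: np.ndarray | float = 0.0
    x_r1: np.ndarray | float = 0.0
    x_r2: np.ndarray | float = 1.0
    g: np.ndarray | float = 1.0
    Na_i: np.ndarray | float = 11.6
    K_i: np.ndarray | float = 138.3
    Ca_i: np.ndarray | float = 0.0002
    Ca_SR: np.ndarray | float = 0.2

    FIELDS = ("V",) + GATE_NAMES + ("Na_i", "K_i", "Ca_i", "Ca_SR")

    @classmethod
    def initial(cls) -> "CellState":
        """Published initial (quiescent) values."""
        tab = load_model_tables()["initial_state"]
        return cls(**tab)

    def copy(self) -> "CellState":
        return CellState(**{k: np.array(getattr(self, k), dtype=float, copy=True)
                            if isinstance(getattr(self, k), np.ndarray)
                            else getattr(self, k) for k in self.FIELDS})

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}

    def validate(self):
        for k in self.FIELDS:
            v = np.asarray(getattr(self, k))
            if not np.all(np.isfinite(v)):
                raise InvalidStateError(f"non-finite value in {k}")
        for k in GATE_NAMES:
            v = np.asarray(getattr(self, k))
            if np.any(v < 0) or np.any(v > 1):
                raise InvalidStateError(f"gate {k} outside [0, 1]")
        for k in ("Na_i", "K_i", "Ca_i", "Ca_SR"):
            if np.any(np.asarray(getattr(self, k)) <= 0):
                raise InvalidStateError(f"concentration {k} must be positive")


@dataclass
class CurrentBreakdown:
    """The 12 TNNP current densities (pA/pF) and their sum ``I_ion``."""

    I_Na: np.ndarray | float
    I_CaL: np.ndarray | float
    I_to: np.ndarray | float
    I_Ks: np.ndarray | float
    I_Kr: np.ndarray | float
    I_K1: np.ndarray | float
    I_NaCa: np.ndarray | float
    I_NaK: np.ndarray | float
    I_pCa: np.ndarray | float
    I_pK: np.ndarray | float
    I_bNa: np.ndarray | float
    I_bCa: np.ndarray | float
    I_ion: np.ndarray | float = field(init=False)

    def __post_init__(self):
        self.I_ion = sum(getattr(self, n) for n in CURRENT_NAMES)

    def as_dict(self) -> dict:
        out = {n: getattr(self, n) for n in CURRENT_NAMES}
        out["I_ion"] = self.I_ion
        return out


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

def _rates_m(V):
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    a = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    b = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    return m_inf, a * b


def _rates_h(V):
    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    V = np.asarray(V, dtype=float)
    low = V < -40.0
    a = np.where(low, 0.057 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b = np.where(
        low,
        2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V),
        0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    return h_inf, 1.0 / (a + b)


def _rates_j(V):
    j_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    V = np.asarray(V, dtype=float)
    low = V < -40.0
    # guard the exp overflow in the unused branch with clipped arguments
    a = np.where(
        low,
        (-2.5428e4 * np.exp(np.minimum(0.2444 * V, 50.0)) - 6.948e-6 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b = np.where(
        low,
        0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    return j_inf, 1.0 / (a + b)


def _rates_d(V):
    d_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    a = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    b = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    c = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    return d_inf, a * b + c


def _rates_f(V):
    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau = 1125.0 * np.exp(-((V + 27.0) ** 2) / 240.0) + 80.0 + 165.0 / (1.0 + np.exp((25.0 - V) / 10.0))
    return f_inf, tau


def _rates_r(V):
    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    return r_inf, tau


def _rates_s(V, cell_type: str):
    if cell_type == "endo":
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:  # epi and mid share the published epicardial s kinetics
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau = 85.0 * np.exp(-((V + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0
    return s_inf, tau


def _rates_xs(V):
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    a = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    b = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    return xs_inf, a * b


def _rates_xr1(V):
    inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    return inf, a * b


def _rates_xr2(V):
    inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    return inf, a * b


def _fca_inf(Ca_i):
    a = 1.0 / (1.0 + (Ca_i / 0.000325) ** 8)
    b = 0.1 / (1.0 + np.exp((Ca_i - 0.0005) / 0.0001))
    c = 0.2 / (1.0 + np.exp((Ca_i - 0.00075) / 0.0008))
    return (a + b + c + 0.23) / 1.46


def _g_inf(Ca_i):
    Ca_i = np.asarray(Ca_i, dtype=float)
    lo = 1.0 / (1.0 + (Ca_i / 0.00035) ** 6)
    hi = 1.0 / (1.0 + (Ca_i / 0.00035) ** 16)
    return np.where(Ca_i < 0.00035, lo, hi)


def gate_dynamics(V, cell_type: str = "epi", Ca_i=0.0002, params: CellParameters | None = None):
    """Steady state and time constant for each of the 12 gates at voltage ``V``.

    The calcium-sensing gates ``f_Ca`` and ``g`` have voltage-independent
    kinetics; their steady states are evaluated at ``Ca_i`` and their time
    constants are the published fixed values.

    Returns a dict ``{gate: (x_inf, tau_ms)}``.
    """
    if not np.all(np.isfinite(np.asarray(V, dtype=float))):
        raise InvalidStateError("non-finite voltage passed to gate_dynamics")
    p = params or CellParameters()
    tau_like = np.broadcast_to(np.asarray(V, dtype=float) * 0.0, np.shape(np.asarray(V))).copy()
    out = {
        "m": _rates_m(V),
        "h": _rates_h(V),
        "j": _rates_j(V),
        "d": _rates_d(V),
        "f": _rates_f(V),
        "f_Ca": (_fca_inf(Ca_i), tau_like + p.tau_fCa if np.ndim(V) else p.tau_fCa),
        "r": _rates_r(V),
        "s": _rates_s(V, cell_type),
        "x_s": _rates_xs(V),
        "x_r1": _rates_xr1(V),
        "x_r2": _rates_xr2(V),
        "g": (_g_inf(Ca_i), tau_like + p.tau_g if np.ndim(V) else p.tau_g),
    }
    return out


# ---------------------------------------------------------------------------
# currents
# ---------------------------------------------------------------------------

def reversal_potentials(state: CellState, p: CellParameters):
    """Nernst potentials E_Na, E_K, E_Ks, E_Ca in mV."""
    rtf = p.rt_over_f
    E_Na = rtf * np.log(p.Na_o / state.Na_i)
    E_K = rtf * np.log(p.K_o / state.K_i)
    E_Ks = rtf * np.log((p.K_o + p.p_KNa * p.Na_o) / (state.K_i + p.p_KNa * state.Na_i))
    E_Ca = 0.5 * rtf * np.log(p.Ca_o / state.Ca_i)
    return E_Na, E_K, E_Ks, E_Ca


def _xk1_inf(V, E_K):
    u = V - E_K
    a = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    b = (3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0))) / (1.0 + np.exp(-0.5 * u))
    return a / (a + b)


def _ical_driving(V, Ca_i, p: CellParameters):
    """GHK-type driving term of I_CaL (everything except G_CaL*d*f*f_Ca)."""
    vfrt = np.asarray(V, dtype=float) * p.F / (p.R * p.T)
    # remove the 0/0 at V = 0 with the analytic limit 2F(Ca_i - 0.341 Ca_o)
    small = np.abs(vfrt) < 1e-8
    vsafe = np.where(small, 1.0, vfrt)
    e2 = np.exp(2.0 * vsafe)
    full = 4.0 * vsafe * p.F * (Ca_i * e2 - 0.341 * p.Ca_o) / (e2 - 1.0)
    limit = 2.0 * p.F * (Ca_i - 0.341 * p.Ca_o)
    return np.where(small, limit, full)


def ionic_currents(state: CellState, params: CellParameters, validate: bool = True) -> CurrentBreakdown:
    """Evaluate all 12 TNNP current densities (pA/pF) at the given state."""
    if validate:
        state.validate()
    p = params
    V = state.V
    E_Na, E_K, E_Ks, E_Ca = reversal_potentials(state, p)
    vfrt = np.asarray(V, dtype=float) * p.F / (p.R * p.T)

    I_Na = p.G_Na * state.m ** 3 * state.h * state.j * (V - E_Na)
    I_CaL = p.G_CaL * state.d * state.f * state.f_Ca * _ical_driving(V, state.Ca_i, p)
    I_to = p.G_to * state.r * state.s * (V - E_K)
    I_Ks = p.G_Ks * state.x_s ** 2 * (V - E_Ks)
    I_Kr = p.G_Kr * np.sqrt(p.K_o / 5.4) * state.x_r1 * state.x_r2 * (V - E_K)
    I_K1 = p.G_K1 * np.sqrt(p.K_o / 5.4) * _xk1_inf(V, E_K) * (V - E_K)

    e_g = np.exp(p.gamma * vfrt)
    e_g1 = np.exp((p.gamma - 1.0) * vfrt)
    denom = (p.K_mNai ** 3 + p.Na_o ** 3) * (p.K_mCa + p.Ca_o) * (1.0 + p.k_sat * e_g1)
    I_NaCa = p.k_NaCa * (e_g * state.Na_i ** 3 * p.Ca_o - e_g1 * p.Na_o ** 3 * state.Ca_i * p.alpha) / denom
    I_NaK = (p.P_NaK * p.K_o * state.Na_i
             / ((p.K_o + p.K_mK) * (state.Na_i + p.K_mNa))
             / (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt)))
    I_pCa = p.G_pCa * state.Ca_i / (p.K_pCa + state.Ca_i)
    I_pK = p.G_pK * (V - E_K) / (1.0 + np.exp((25.0 - V) / 5.98))
    I_bNa = p.G_bNa * (V - E_Na)
    I_bCa = p.G_bCa * (V - E_Ca)

    return CurrentBreakdown(I_Na, I_CaL, I_to, I_Ks, I_Kr, I_K1,
                            I_NaCa, I_NaK, I_pCa, I_pK, I_bNa, I_bCa)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

_GATE_OVERSHOOT = 1e-9


def _advance_gates(state: CellState, p: CellParameters, dt: float, method: str = "rush_larsen"):
    """Return updated gate values (dict).  ``method``: 'euler' or 'rush_larsen'."""
    dyn = gate_dynamics(state.V, p.cell_type, state.Ca_i, p)
    out = {}
    for name in GATE_NAMES:
        x = getattr(state, name)
        x_inf, tau = dyn[name]
        if method == "euler":
            k = dt / tau
        elif method == "rush_larsen":
            k = 1.0 - np.exp(-dt / tau)
        else:
            raise ValueError(f"unknown gate integration method {method!r}")
        x_new = x + (x_inf - x) * k
        if name in ("f_Ca", "g"):
            # published conditional update: freeze the gate while it would
            # re-open during depolarization (V above -60 mV); ties resolve to
            # "no update".  The published f_Ca steady state slightly exceeds
            # unity at diastolic Ca_i, so these two gates are clipped into
            # [0, 1] as part of the update.
            blocked = np.logical_and(x_inf > x, np.asarray(state.V) >= -60.0)
            x_new = np.clip(np.where(blocked, x, x_new), 0.0, 1.0)
        out[name] = x_new
    return out


def _clip_gates(gates: dict):
    for name, x in gates.items():
        arr = np.asarray(x, dtype=float)
        low, high = arr.min(), arr.max()
        if low < -_GATE_OVERSHOOT or high > 1.0 + _GATE_OVERSHOOT:
            raise InvalidStateError(
                f"gate {name} left [0,1] by more than {_GATE_OVERSHOOT} "
                f"(range [{low:.3e}, {high:.3e}]); reduce dt")
        gates[name] = np.clip(arr, 0.0, 1.0) if arr.ndim else float(min(max(x, 0.0), 1.0))
    return gates


def concentration_derivatives(state: CellState, p: CellParameters, cur: CurrentBreakdown,
                              I_stim=0.0):
    """Time derivatives (mM/ms) of Na_i, K_i, Ca_i (free) and Ca_SR (free)."""
    vcf = p.Cm / (p.V_c * p.F)
    dNa = -(cur.I_Na + cur.I_bNa + 3.0 * cur.I_NaK + 3.0 * cur.I_NaCa) * vcf
    dK = -(cur.I_K1 + cur.I_to + cur.I_Kr + cur.I_Ks - 2.0 * cur.I_NaK + cur.I_pK + I_stim) * vcf

    Ca_i, Ca_SR = state.Ca_i, state.Ca_SR
    I_leak = p.V_leak * (Ca_SR - Ca_i)
    I_up = p.V_maxup / (1.0 + (p.K_up / Ca_i) ** 2)
    I_rel = (p.a_rel * Ca_SR ** 2 / (p.b_rel ** 2 + Ca_SR ** 2) + p.c_rel) * state.d * state.g

    dCa_total = (-(cur.I_CaL + cur.I_bCa + cur.I_pCa - 2.0 * cur.I_NaCa) * p.Cm
                 / (2.0 * p.V_c * p.F) + I_leak - I_up + I_rel)
    buf_c = 1.0 / (1.0 + p.Buf_c * p.K_bufc / (Ca_i + p.K_bufc) ** 2)
    dCa = buf_c * dCa_total

    dCaSR_total = p.V_c / p.V_sr * (I_up - I_rel - I_leak)
    buf_sr = 1.0 / (1.0 + p.Buf_sr * p.K_bufsr / (Ca_SR + p.K_bufsr) ** 2)
    dCaSR = buf_sr * dCaSR_total
    return dNa, dK, dCa, dCaSR


def step_cell(state: CellState, params: CellParameters, I_stim=0.0, dt: float = 0.02,
              method: str = "rush_larsen", dV_external=0.0) -> CellState:
    """Advance one cell (or an array of cells) by one explicit time step.

    The membrane equation follows the TNNP sign convention
    ``dV/dt = -(I_ion + I_stim) + dV_external``; a depolarizing stimulus is
    therefore *negative* (e.g. -52 pA/pF).  ``dV_external`` carries the
    diffusion term when the tissue solver drives this routine.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cur = ionic_currents(state, params, validate=True)
    dV = -(cur.I_ion + I_stim) + dV_external
    gates = _clip_gates(_advance_gates(state, params, dt, method))
    dNa, dK, dCa, dCaSR = concentration_derivatives(state, params, cur, I_stim)
    new = CellState(
        V=state.V + dt * dV,
        Na_i=state.Na_i + dt * dNa,
        K_i=state.K_i + dt * dK,
        Ca_i=state.Ca_i + dt * dCa,
        Ca_SR=state.Ca_SR + dt * dCaSR,
        **gates,
    )
    for name in new.FIELDS:
        if not np.all(np.isfinite(np.asarray(getattr(new, name)))):
            raise NumericalBlowupError(name)
    return new


def dv_dt(state: CellState, params: CellParameters, I_stim=0.0):
    """Instantaneous dV/dt (mV/ms) at the state, for rest diagnostics."""
    return -(ionic_currents(state, params, validate=False).I_ion + I_stim)


def find_rest(params: CellParameters, t_max: float = 20000.0, dt: float = 0.02,
              criterion: float = 1e-3) -> CellState:
    """Equilibrate a single unstimulated cell to its resting state.

    Integrates from the published initial values until ``|dV/dt|`` falls below
    ``criterion`` (mV/ms), using the fast table-driven integrator for the bulk
    of the relaxation and this module's reference stepper for the final 100 ms.
    Raises :class:`NoRestError` if the criterion is not met within ``t_max``.
    """
    from . import kernels  # local import: kernels depends on this module's tables

    state = CellState.initial()
    vec = kernels.state_to_vector(state)
    tab = kernels.ModelTables.build(params, dt=dt, method="rush_larsen")
    block = 1000.0  # ms of table-driven integration per convergence check
    t = 0.0
    while t < t_max:
        vec = kernels.integrate_cell_vector(vec, tab, int(round(block / dt)), dt,
                                            endo=params.cell_type == "endo")
        t += block
        state = kernels.vector_to_state(vec)
        if abs(dv_dt(state, params)) < 0.5 * criterion:
            break
    # polish with the reference stepper so the criterion holds under exact rates
    for _ in range(int(round(100.0 / dt))):
        state = step_cell(state, params, 0.0, dt)
    if abs(dv_dt(state, params)) >= criterion:
        raise NoRestError(
            f"cell did not reach |dV/dt| < {criterion} mV/ms within {t_max} ms")
    return state
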