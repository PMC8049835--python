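"""Vector fields for a memristive pre-Bötzinger complex pacemaker neuron.

The model couples a Butera-type somatic spiker (fast Na, delayed-rectifier K,
leak, persistent Na and tonic-drive currents) to a calcium-activated
nonspecific cationic (CAN) current gated by IP3-receptor-driven calcium release
from the endoplasmic reticulum, and to a magnetic-flux variable phi whose
flux-controlled memristor rho(phi) = alpha + 3*beta*phi**2 feeds an induced
current k1*V*rho(phi) back onto the membrane.

State variables (full system, 6-D):
    V    membrane potential (mV)
    n    delayed-rectifier K activation gate, in [0, 1]
    h    persistent-Na inactivation gate, in [0, 1]
    phi  magnetic flux (same numeric scale as V)
    Ca   cytosolic calcium (uM)
    l    fraction of non-inactivated IP3 channels, in [0, 1]

Time is measured in ms and all printed parameter values are used verbatim in
the nS/mV/ms convention (the capacitance C = 21 divides the current sum
directly, so C/g_max = 0.42 ms).

The fast subsystem freezes the super-slow gate h and replaces the CAN current
by gCANTot*(V - VNa), where gCANTot = gCAN*f([Ca]) is treated as the slow
bifurcation parameter.  The (Ca, l) subsystem is fully decoupled from the
electrical variables and paces the burst.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "FullState",
    "FastState",
    "FastParams",
    "gating_inf",
    "tau_gate",
    "f_can",
    "rho",
    "membrane_currents",
    "full_rhs",
    "fast_rhs",
    "ca_rhs",
    "jacobian",
    "fast_jacobian_analytic",
    "pack_params",
    "pack_fast_params",
    "full_rhs_nb",
    "fast_rhs_nb",
    "ca_rhs_nb",
]

FULL_VARS = ("V", "n", "h", "phi", "Ca", "l")
FAST_VARS = ("V", "n", "phi")
CA_VARS = ("Ca", "l")


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """All model constants; defaults are the reference parameter set.

    Conductances in nS, potentials in mV, time constants in ms, calcium
    quantities in uM; the ER flux constants (LIP3, PIP3, VSERCA) and the
    IP3-gate rate A are used numerically as printed with t in ms.
    """

    C: float = 21.0          # capacitance (divides the current sum)
    sigma: float = 0.185     # cytosol/ER volume ratio

    gL: float = 2.8
    gK: float = 4.0
    gNa: float = 10.0
    gNaP: float = 2.8
    gtonic_e: float = 0.3
    gCAN: float = 0.7

    VNa: float = 50.0
    VK: float = -85.0
    VL: float = -65.0
    Vsyn_e: float = 0.0

    theta_n: float = -29.0
    theta_h: float = -48.0
    theta_m: float = -34.0
    theta_mp: float = -40.0
    sigma_n: float = -4.0
    sigma_h: float = 6.0
    sigma_m: float = -5.0
    sigma_mp: float = -6.0

    tau_n_bar: float = 10.0
    tau_h_bar: float = 10000.0

    KI: float = 1.0
    Ka: float = 0.4
    KCAN: float = 0.74
    nCAN: float = 0.97
    IP3: float = 1.2
    LIP3: float = 0.37
    PIP3: float = 31000.0
    CaTot: float = 1.25
    KCa: float = 0.000025
    VSERCA: float = 400.0
    KSERCA: float = 0.2
    A: float = 0.005
    Kd: float = 0.4

    # stimulation: external DC current and electromagnetic-induction feedback
    Iextz: float = 0.0
    k1: float = 0.0
    k2: float = 3.0
    alpha: float = 1.0
    beta: float = 0.00006

    def __post_init__(self) -> None:
        for name in ("gL", "gK", "gNa", "gNaP", "gtonic_e", "gCAN"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.tau_n_bar <= 0 or self.tau_h_bar <= 0:
            raise ValueError("maximal time constants must be positive")
        if not 0 < self.sigma < 1:
            raise ValueError("volume ratio sigma must lie in (0, 1)")
        for name in ("KSERCA", "KCAN", "KI", "Ka", "Kd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"dissociation constant {name} must be > 0")
        if self.nCAN <= 0:
            raise ValueError("Hill exponent nCAN must be > 0")
        for name in ("sigma_n", "sigma_h", "sigma_m", "sigma_mp"):
            if getattr(self, name) == 0:
                raise ValueError(f"sigmoid slope {name} must be nonzero")

    def with_(self, **kw: float) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown parameter keys: {sorted(bad)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            import yaml

            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            import yaml

            d = yaml.safe_load(p.read_text())
        else:
            d = json.loads(p.read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(d)


@dataclass(frozen=True)
class FullState:
    V: float
    n: float
    h: float
    phi: float
    Ca: float
    l: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.h, self.phi, self.Ca, self.l])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FullState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class FastState:
    V: float
    n: float
    phi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.phi])


@dataclass(frozen=True)
class FastParams:
    """Fast-subsystem parameters: frozen super-slow gate and slow conductance."""

    h_frozen: float
    gCANTot: float
    base: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_frozen <= 1.0:
            raise ValueError("h_frozen must lie in [0, 1]")
        if self.gCANTot < 0:
            raise ValueError("gCANTot must be >= 0")


# --------------------------------------------------------------------------
# elementary functions
# --------------------------------------------------------------------------

def gating_inf(V: float, theta: float, sigma_slope: float) -> float:
    """Steady-state sigmoid 1/(1+exp((V-theta)/sigma)); monotone with -sigma."""
    if sigma_slope == 0:
        raise ValueError("sigmoid slope must be nonzero")
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) - theta) / sigma_slope))


def tau_gate(V: float, tau_bar: float, theta: float, sigma_slope: float) -> float:
    """Voltage-dependent time constant tau_bar/cosh((V-theta)/(2 sigma))."""
    if sigma_slope == 0:
        raise ValueError("sigmoid slope must be nonzero")
    if tau_bar <= 0:
        raise ValueError("tau_bar must be positive")
    return tau_bar / np.cosh((np.asarray(V, float) - theta) / (2.0 * sigma_slope))


def f_can(Ca: float, KCAN: float = 0.74, nCAN: float = 0.97) -> float:
    """CAN-current calcium activation, Hill form 1/(1+(KCAN/Ca)**nCAN)."""
    Ca = np.asarray(Ca, float)
    if np.any(Ca <= 0):
        raise ValueError("Ca must be positive")
    return 1.0 / (1.0 + (KCAN / Ca) ** nCAN)


def rho(phi: float, alpha: float = 1.0, beta: float = 0.00006) -> float:
    """Memductance of the flux-controlled memristor, alpha + 3*beta*phi**2."""
    phi = np.asarray(phi, float)
    return alpha + 3.0 * beta * phi * phi


def membrane_currents(state: FullState, p: ModelParams) -> dict[str, float]:
    """Each membrane current (positive = outward-balance convention)."""
    V, n, h, phi, Ca = state.V, state.n, state.h, state.phi, state.Ca
    m_inf = gating_inf(V, p.theta_m, p.sigma_m)
    mp_inf = gating_inf(V, p.theta_mp, p.sigma_mp)
    return {
        "INa": p.gNa * m_inf**3 * (1.0 - n) * (V - p.VNa),
        "IK": p.gK * n**4 * (V - p.VK),
        "IL": p.gL * (V - p.VL),
        "INaP": p.gNaP * mp_inf * h * (V - p.VNa),
        "ICAN": p.gCAN * f_can(Ca, p.KCAN, p.nCAN) * (V - p.VNa),
        "Itonic_e": p.gtonic_e * (V - p.Vsyn_e),
        "Iinduced": p.k1 * V * rho(phi, p.alpha, p.beta),
    }


# --------------------------------------------------------------------------
# numba kernels (the forms the integrators call)
# --------------------------------------------------------------------------

# packed parameter-vector layout, shared by all kernels
_PV_FIELDS = (
    "C", "sigma", "gL", "gK", "gNa", "gNaP", "gtonic_e", "gCAN",
    "VNa", "VK", "VL", "Vsyn_e",
    "theta_n", "theta_h", "theta_m", "theta_mp",
    "sigma_n", "sigma_h", "sigma_m", "sigma_mp",
    "tau_n_bar", "tau_h_bar",
    "KI", "Ka", "KCAN", "nCAN", "IP3", "LIP3", "PIP3",
    "CaTot", "KCa", "VSERCA", "KSERCA", "A", "Kd",
    "Iextz", "k1", "k2", "alpha", "beta",
)
_PV_INDEX = {name: i for i, name in enumerate(_PV_FIELDS)}


def pack_params(p: ModelParams) -> np.ndarray:
    """Flatten a ModelParams into the vector the numba kernels consume."""
    return np.array([getattr(p, name) for name in _PV_FIELDS], dtype=np.float64)


def pack_fast_params(fp: FastParams) -> np.ndarray:
    """Packed base parameters with (h_frozen, gCANTot) appended."""
    return np.concatenate([pack_params(fp.base), [fp.h_frozen, fp.gCANTot]])


@njit(cache=True)
def _electrical_rhs(V, n, h, phi, gcan_eff, pv):
    """dV, dn, dphi shared by full and fast kernels; gcan_eff = gCAN*f(Ca)."""
    m_inf = 1.0 / (1.0 + math.exp((V - pv[14]) / pv[18]))
    mp_inf = 1.0 / (1.0 + math.exp((V - pv[15]) / pv[19]))
    n_inf = 1.0 / (1.0 + math.exp((V - pv[12]) / pv[16]))
    inv_tau_n = math.cosh((V - pv[12]) / (2.0 * pv[16])) / pv[20]

    INa = pv[4] * m_inf**3 * (1.0 - n) * (V - pv[8])
    IK = pv[3] * n**4 * (V - pv[9])
    IL = pv[2] * (V - pv[10])
    INaP = pv[5] * mp_inf * h * (V - pv[8])
    ICAN = gcan_eff * (V - pv[8])
    Iton = pv[6] * (V - pv[11])
    Iind = pv[36] * V * (pv[38] + 3.0 * pv[39] * phi * phi)

    dV = (-INa - IK - IL - INaP - Iton - ICAN + pv[35] - Iind) / pv[0]
    dn = (n_inf - n) * inv_tau_n
    dphi = V - pv[37] * phi
    return dV, dn, dphi


@njit(cache=True)
def _ca_fluxes(Ca, l, pv):
    """d[Ca]/dt, dl/dt of the decoupled ER calcium subsystem."""
    G = pv[26] * Ca / ((pv[26] + pv[22]) * (Ca + pv[23]))
    gate = (G * l) ** 3
    Ca_ER = (pv[29] - Ca) / pv[1]
    J_in = (pv[27] + pv[28] * gate) * (Ca_ER - Ca)
    J_out = pv[31] * Ca * Ca / (pv[32] * pv[32] + Ca * Ca)
    dCa = pv[30] * (J_in - J_out)
    dl = pv[33] * pv[34] * (1.0 - l) - pv[33] * Ca * l
    return dCa, dl


@njit(cache=True)
def full_rhs_nb(t, y, pv):
    """6-D vector field; y = (V, n, h, phi, Ca, l), rates per ms."""
    V, n, h, phi, Ca, l = y[0], y[1], y[2], y[3], y[4], y[5]
    fca = 1.0 / (1.0 + (pv[24] / Ca) ** pv[25])
    dV, dn, dphi = _electrical_rhs(V, n, h, phi, pv[7] * fca, pv)
    h_inf = 1.0 / (1.0 + math.exp((V - pv[13]) / pv[17]))
    inv_tau_h = math.cosh((V - pv[13]) / (2.0 * pv[17])) / pv[21]
    dh = (h_inf - h) * inv_tau_h
    dCa, dl = _ca_fluxes(Ca, l, pv)
    out = np.empty(6)
    out[0] = dV
    out[1] = dn
    out[2] = dh
    out[3] = dphi
    out[4] = dCa
    out[5] = dl
    return out


@njit(cache=True)
def fast_rhs_nb(t, y, pvf):
    """3-D fast subsystem; y = (V, n, phi); pvf = packed params + (h, gCANTot)."""
    dV, dn, dphi = _electrical_rhs(y[0], y[1], pvf[40], y[2], pvf[41], pvf[:40])
    out = np.empty(3)
    out[0] = dV
    out[1] = dn
    out[2] = dphi
    return out


@njit(cache=True)
def ca_rhs_nb(t, y, pv):
    dCa, dl = _ca_fluxes(y[0], y[1], pv)
    out = np.empty(2)
    out[0] = dCa
    out[1] = dl
    return out


@njit(cache=True)
def fast_jac_nb(V, n, phi, pvf):
    """Analytic 3x3 Jacobian of the fast subsystem (numba kernel)."""
    C = pvf[0]
    gL, gK, gNa, gNaP, gton = pvf[2], pvf[3], pvf[4], pvf[5], pvf[6]
    VNa, VK = pvf[8], pvf[9]
    th_n, th_m, th_mp = pvf[12], pvf[14], pvf[15]
    s_n, s_m, s_mp = pvf[16], pvf[18], pvf[19]
    tau_n = pvf[20]
    k1, k2, alpha, beta = pvf[36], pvf[37], pvf[38], pvf[39]
    h, gT = pvf[40], pvf[41]

    m = 1.0 / (1.0 + math.exp((V - th_m) / s_m))
    dm = -m * (1.0 - m) / s_m
    mp = 1.0 / (1.0 + math.exp((V - th_mp) / s_mp))
    dmp = -mp * (1.0 - mp) / s_mp
    n_inf = 1.0 / (1.0 + math.exp((V - th_n) / s_n))
    dn_inf = -n_inf * (1.0 - n_inf) / s_n
    w = (V - th_n) / (2.0 * s_n)
    inv_tau = math.cosh(w) / tau_n
    d_inv_tau = math.sinh(w) / (2.0 * s_n * tau_n)

    dINa_dV = gNa * (1.0 - n) * (3.0 * m * m * dm * (V - VNa) + m**3)
    dINa_dn = -gNa * m**3 * (V - VNa)
    dIK_dV = gK * n**4
    dIK_dn = 4.0 * gK * n**3 * (V - VK)
    dINaP_dV = gNaP * h * (dmp * (V - VNa) + mp)
    rho_phi = alpha + 3.0 * beta * phi * phi
    dIind_dV = k1 * rho_phi
    dIind_dphi = k1 * V * 6.0 * beta * phi

    J = np.empty((3, 3))
    J[0, 0] = -(dINa_dV + dIK_dV + gL + dINaP_dV + gT + gton + dIind_dV) / C
    J[0, 1] = -(dINa_dn + dIK_dn) / C
    J[0, 2] = -dIind_dphi / C
    J[1, 0] = dn_inf * inv_tau + (n_inf - n) * d_inv_tau
    J[1, 1] = -inv_tau
    J[1, 2] = 0.0
    J[2, 0] = 1.0
    J[2, 1] = 0.0
    J[2, 2] = -k2
    return J


@njit(cache=True)
def fast_variational_rhs_nb(t, Y, pvf):
    """Fast subsystem augmented with its fundamental matrix (12-D)."""
    y = Y[:3]
    out = np.empty(12)
    out[:3] = fast_rhs_nb(t, y, pvf)
    J = fast_jac_nb(y[0], y[1], y[2], pvf)
    Phi = Y[3:].copy().reshape((3, 3))
    dPhi = J @ Phi
    out[3:] = dPhi.copy().reshape(9)
    return out


# --------------------------------------------------------------------------
# python-facing vector fields
# --------------------------------------------------------------------------

def full_rhs(state: FullState | np.ndarray, p: ModelParams) -> np.ndarray:
    """Time derivatives (per ms) of the full 6-D system."""
    y = state.as_array() if isinstance(state, FullState) else np.asarray(state, float)
    if y.shape != (6,) or not np.all(np.isfinite(y)):
        raise ValueError("state must be a finite 6-vector (V, n, h, phi, Ca, l)")
    return full_rhs_nb(0.0, y, pack_params(p))


def fast_rhs(state: FastState | np.ndarray, fp: FastParams) -> np.ndarray:
    """Time derivatives of the 3-D fast subsystem at frozen (h, gCANTot)."""
    y = state.as_array() if isinstance(state, FastState) else np.asarray(state, float)
    if y.shape != (3,) or not np.all(np.isfinite(y)):
        raise ValueError("state must be a finite 3-vector (V, n, phi)")
    return fast_rhs_nb(0.0, y, pack_fast_params(fp))


def ca_rhs(Ca: float, l: float, p: ModelParams) -> np.ndarray:
    """Derivatives of the decoupled (Ca, l) subsystem."""
    if Ca <= 0:
        raise ValueError("Ca must be positive")
    if not 0.0 <= l <= 1.0:
        raise ValueError("l must lie in [0, 1]")
    return ca_rhs_nb(0.0, np.array([Ca, l], dtype=float), pack_params(p))


# --------------------------------------------------------------------------
# Jacobians
# --------------------------------------------------------------------------

def _rhs_callable(rhs_id: str, params) -> Callable[[np.ndarray], np.ndarray]:
    if rhs_id == "full":
        pv = pack_params(params)
        return lambda y: full_rhs_nb(0.0, y, pv)
    if rhs_id == "fast":
        pvf = pack_fast_params(params)
        return lambda y: fast_rhs_nb(0.0, y, pvf)
    if rhs_id == "ca":
        pv = pack_params(params)
        return lambda y: ca_rhs_nb(0.0, y, pv)
    raise ValueError(f"unknown rhs_id {rhs_id!r}")


def jacobian(rhs_id: str, point: np.ndarray, params, mode: str = "numeric",
             step: float = 1e-6) -> np.ndarray:
    """Jacobian of one of the vector fields at ``point``.

    numeric mode: central differences with step ``step*(1+|x_i|)`` per
    coordinate.  analytic mode is available for the fast subsystem only.
    """
    point = np.asarray(point, dtype=float)
    if mode == "analytic":
        if rhs_id != "fast":
            raise ValueError("analytic Jacobian implemented for the fast subsystem only")
        return fast_jacobian_analytic(point, params)
    f = _rhs_callable(rhs_id, params)
    m = point.size
    J = np.empty((m, m))
    for i in range(m):
        hi = step * (1.0 + abs(point[i]))
        yp = point.copy()
        ym = point.copy()
        yp[i] += hi
        ym[i] -= hi
        J[:, i] = (f(yp) - f(ym)) / (2.0 * hi)
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite Jacobian entries (degenerate point)")
    return J


def fast_jacobian_analytic(point: np.ndarray, fp: FastParams) -> np.ndarray:
    """Hand-derived 3x3 Jacobian of the fast subsystem at (V, n, phi)."""
    p = fp.base
    V, n, phi = point
    h, gT = fp.h_frozen, fp.gCANTot

    m = gating_inf(V, p.theta_m, p.sigma_m)
    dm = -m * (1.0 - m) / p.sigma_m
    mp = gating_inf(V, p.theta_mp, p.sigma_mp)
    dmp = -mp * (1.0 - mp) / p.sigma_mp
    n_inf = gating_inf(V, p.theta_n, p.sigma_n)
    dn_inf = -n_inf * (1.0 - n_inf) / p.sigma_n
    w = (V - p.theta_n) / (2.0 * p.sigma_n)
    inv_tau = np.cosh(w) / p.tau_n_bar
    d_inv_tau = np.sinh(w) / (2.0 * p.sigma_n * p.tau_n_bar)

    dINa_dV = p.gNa * (1.0 - n) * (3.0 * m**2 * dm * (V - p.VNa) + m**3)
    dINa_dn = -p.gNa * m**3 * (V - p.VNa)
    dIK_dV = p.gK * n**4
    dIK_dn = 4.0 * p.gK * n**3 * (V - p.VK)
    dINaP_dV = p.gNaP * h * (dmp * (V - p.VNa) + mp)
    dIind_dV = p.k1 * rho(phi, p.alpha, p.beta)
    dIind_dphi = p.k1 * V * 6.0 * p.beta * phi

    J = np.empty((3, 3))
    J[0, 0] = -(dINa_dV + dIK_dV + p.gL + dINaP_dV + gT + p.gtonic_e + dIind_dV) / p.C
    J[0, 1] = -(dINa_dn + dIK_dn) / p.C
    J[0, 2] = -dIind_dphi / p.C
    J[1, 0] = dn_inf * inv_tau + (n_inf - n) * d_inv_tau
    J[1, 1] = -inv_tau
    J[1, 2] = 0.0
    J[2, 0] = 1.0
    J[2, 1] = 0.0
    J[2, 2] = -p.k2
    return J
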