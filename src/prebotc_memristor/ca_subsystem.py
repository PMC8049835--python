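"""The decoupled (Ca, l) slow/super-slow subsystem.

Cytosolic calcium exchanges with the ER through an IP3-receptor channel
(gated by [IP3], Ca and the availability variable l), a leak, and the SERCA
pump; the pair (Ca, l) evolves independently of the electrical variables and
acts as the pacemaker of the burst: the CAN conductance seen by the membrane
is gCANTot(t) = gCAN * f(Ca(t)).

At the reference IP3 = 1.2 uM the subsystem owns a relaxation oscillation:
the orbit hugs the left branch of the Ca-nullcline (slow refilling), jumps
to the right branch at the left knee (rapid Ca release, point P1), creeps
back, and drops down again.  The membrane spikes for as long as Ca stays
above the SNIC value of the fast subsystem; the crossing of Ca_SNIC on the
way down (point P2) ends the active phase.

The Ca-nullcline is available in closed form by solving dCa/dt = 0 for l,
and the l-nullcline is l = Kd/(Kd + Ca).  The Hill map between gCANTot and
Ca inverts exactly:  Ca = KCAN / (gCAN/gCANTot - 1)**(1/nCAN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model_core import ModelParams, f_can
from .simulate import Trajectory, integrate_ca

__all__ = [
    "CaOrbit",
    "nullclines",
    "ca_to_gcan",
    "gcan_to_ca",
    "relaxation_orbit",
    "ip3_activity_scan",
    "OSCILLATION_AMP_MIN",
]

OSCILLATION_AMP_MIN = 0.005   # uM peak-to-peak for "active" (oscillating)


@dataclass
class CaOrbit:
    t: np.ndarray                 # one period, starting at a Ca maximum
    Ca: np.ndarray
    l: np.ndarray
    period: float                 # ms
    Ca_nullcline: tuple[np.ndarray, np.ndarray]   # (Ca, l) samples
    l_nullcline: tuple[np.ndarray, np.ndarray]
    P1: dict = field(default_factory=dict)        # jump-up marker
    P2: dict = field(default_factory=dict)        # Ca_SNIC down-crossing


def _ca_null_l(Ca: np.ndarray, p: ModelParams) -> np.ndarray:
    """l on the Ca-nullcline (closed form); NaN where no root exists."""
    Ca = np.asarray(Ca, float)
    G = p.IP3 * Ca / ((p.IP3 + p.KI) * (Ca + p.Ka))
    D = (p.CaTot - (1.0 + p.sigma) * Ca) / p.sigma    # Ca_ER - Ca
    J_out = p.VSERCA * Ca**2 / (p.KSERCA**2 + Ca**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cube = (J_out / D - p.LIP3) / p.PIP3
        l = np.where(cube >= 0, np.cbrt(np.abs(cube)), np.nan) / G
    l = np.where((l >= 0) & np.isfinite(l), l, np.nan)
    return l


def nullclines(p: ModelParams, Ca_range: tuple[float, float] = (1e-3, 1.05),
               grid_n: int = 2001):
    """Sampled Ca-nullcline (root of dCa/dt in l) and analytic l-nullcline.

    Returns ((Ca, l_canull), (Ca, l_lnull), knees) where knees are the local
    extrema of l along the Ca-nullcline (the jump points of the relaxation
    orbit).
    """
    Ca = np.linspace(Ca_range[0], Ca_range[1], grid_n)
    l_ca = _ca_null_l(Ca, p)
    l_l = p.Kd / (p.Kd + Ca)
    ok = np.isfinite(l_ca)
    knees = []
    idx = np.where(ok)[0]
    dl = np.gradient(l_ca[idx], Ca[idx])
    sign_change = np.where(np.sign(dl[:-1]) * np.sign(dl[1:]) < 0)[0]
    for i in sign_change:
        j = idx[i]
        knees.append({"Ca": float(Ca[j]), "l": float(l_ca[j])})
    return (Ca, l_ca), (Ca, l_l), knees


def ca_to_gcan(Ca, p: ModelParams):
    """Effective CAN conductance gCANTot = gCAN * f([Ca])."""
    return p.gCAN * f_can(Ca, p.KCAN, p.nCAN)


def gcan_to_ca(gCANTot, p: ModelParams):
    """Exact inverse of the Hill map; requires 0 < gCANTot < gCAN."""
    g = np.asarray(gCANTot, float)
    if np.any(g <= 0) or np.any(g >= p.gCAN):
        raise ValueError("gCANTot must lie strictly between 0 and gCAN")
    return p.KCAN / (p.gCAN / g - 1.0) ** (1.0 / p.nCAN)


def relaxation_orbit(p: ModelParams, initial=(0.05, 0.9), t_end: float = 250000.0,
                     gcan_snic: float | None = None, rel_tol: float = 1e-6) -> CaOrbit:
    """Converged periodic orbit of the (Ca, l) subsystem with P1/P2 markers.

    The orbit is cut between successive Ca maxima after the transient;
    convergence requires the last two cut points to agree to ``rel_tol``
    relative.  Raises when the subsystem sits on a fixed point instead.
    """
    traj = integrate_ca(p, initial, t_end, rtol=1e-11, atol=1e-13, max_step=10.0)
    t, Ca, l = traj.t, traj["Ca"], traj["l"]
    tail = t > 0.3 * t[-1]
    if Ca[tail].max() - Ca[tail].min() < OSCILLATION_AMP_MIN:
        raise RuntimeError(
            f"no oscillation: subsystem settles near Ca={Ca[-1]:.4f}, l={l[-1]:.4f}")
    # cut the orbit on a transversal section: upward crossing of mid-range Ca
    c_mid = 0.5 * (Ca[tail].max() + Ca[tail].min())
    up = np.where((Ca[:-1] < c_mid) & (Ca[1:] >= c_mid) & tail[:-1])[0]
    if up.size < 3:
        raise RuntimeError("fewer than three section crossings; increase t_end")
    frac = (c_mid - Ca[up]) / (Ca[up + 1] - Ca[up])
    t_cross = t[up] + frac * (t[up + 1] - t[up])
    l_cross = l[up] + frac * (l[up + 1] - l[up])
    l_scale = max(l[tail].max() - l[tail].min(), 1e-12)
    if abs(l_cross[-1] - l_cross[-2]) / l_scale > rel_tol:
        raise RuntimeError("orbit not converged; increase t_end")
    a, b = up[-2] + 1, up[-1]
    period = float(t_cross[-1] - t_cross[-2])
    sl = slice(a, b + 1)
    (ca_n, l_ca), (_, l_l), knees = nullclines(p)
    orbit = CaOrbit(t[sl] - t[a], Ca[sl].copy(), l[sl].copy(), period,
                    (ca_n, l_ca), (ca_n, l_l))
    # P1: the jump-up, where dCa/dt is maximal along the cycle
    dca = np.gradient(Ca[sl], t[sl])
    i1 = int(np.argmax(dca))
    orbit.P1 = {"t": float(t[sl][i1] - t[a]), "Ca": float(Ca[sl][i1]),
                "l": float(l[sl][i1])}
    if gcan_snic is not None:
        ca_snic = float(gcan_to_ca(gcan_snic, p))
        cs, ts = Ca[sl], t[sl] - t[a]
        down = np.where((cs[:-1] >= ca_snic) & (cs[1:] < ca_snic))[0]
        if down.size:
            i2 = down[-1]
            orbit.P2 = {"t": float(ts[i2]), "Ca": ca_snic,
                        "l": float(l[sl][i2]), "Ca_SNIC": ca_snic}
    return orbit


def ip3_activity_scan(p: ModelParams, ip3_range: tuple[float, float] = (0.5, 2.0),
                      grid_n: int = 16, t_run: float = 200000.0) -> list[dict]:
    """Oscillation flag per IP3 value: peak-to-peak Ca amplitude above
    0.005 uM sustained over the last half of a long run."""
    if grid_n < 3:
        raise ValueError("grid_n must be >= 3")
    out = []
    for ip3 in np.linspace(ip3_range[0], ip3_range[1], grid_n):
        q = p.with_(IP3=float(ip3))
        traj = integrate_ca(q, (0.05, 0.9), t_run)
        t, Ca = traj.t, traj["Ca"]
        tail = t > 0.5 * t[-1]
        amp = float(Ca[tail].max() - Ca[tail].min())
        out.append({"IP3": float(ip3), "oscillatory": amp > OSCILLATION_AMP_MIN,
                    "amplitude": amp})
    return out
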