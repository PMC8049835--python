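"""Two-parameter bifurcation curves of the fast subsystem in (gCANTot, h).

Because the equilibrium curve is available in closed form for every h, the
codimension-1 curves are assembled by per-h scanning rather than bordered
codim-2 continuation: the fold curve (fc) collects the roots of
d gCANTot/dV, the Hopf curve (hc) the zero crossings of the complex pair's
real part, the fold-of-cycles curve (lc) the upper termination of the
attracting cycle branch, and the homoclinic curve (homo) its lower
termination — the latter an explicit period-ceiling approximation, flagged
as such, that merges into SNIC points on fc wherever the lower termination
lands on the fold.

The projection of a full-system trajectory into this plane is
(gCAN*f(Ca(t)), h(t)); crossing diagnostics interpolate each curve at the
trajectory's h and report signed crossings per burst cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ca_subsystem import ca_to_gcan
from .fastslow import (
    PERIOD_MAX,
    continue_cycles,
    find_folds,
    find_hopf,
    find_stable_cycle,
)
from .model_core import ModelParams
from .simulate import Trajectory

__all__ = [
    "TwoParCurve",
    "fold_curve",
    "hopf_curve",
    "lpc_curve",
    "homoclinic_contour",
    "overlay_and_crossings",
    "scurve_shift_report",
    "project_trajectory",
]


@dataclass
class TwoParCurve:
    kind: str                       # fc | hc | lc | homo
    points: np.ndarray              # (N, 2): columns gCANTot, h
    diagnostics: list[dict] = field(default_factory=list)
    approximate: bool = False

    def g_at(self, h: float, branch: int = 0) -> float:
        """Interpolate the curve's gCANTot at one h (per sub-branch)."""
        pts = self.points[self.points[:, 2] == branch] if self.points.shape[1] > 2 \
            else self.points
        if pts.shape[0] < 2:
            return float("nan")
        order = np.argsort(pts[:, 1])
        return float(np.interp(h, pts[order, 1], pts[order, 0],
                               left=np.nan, right=np.nan))


def _h_grid(h_range: tuple[float, float], n: int) -> np.ndarray:
    if not 0.0 <= h_range[0] < h_range[1] <= 1.0:
        raise ValueError("h_range must lie inside [0, 1]")
    return np.linspace(h_range[0], h_range[1], n)


def fold_curve(p: ModelParams, h_range: tuple[float, float] = (0.0, 0.35),
               n: int = 141) -> TwoParCurve:
    """Fold curve: all (g_fold, h) with physical g; branch index appended
    (0 = lower-V knee, 1, ... by V order)."""
    rows, diags = [], []
    for h in _h_grid(h_range, n):
        for k, f in enumerate(find_folds(h, p)):
            rows.append((f.gCANTot, h, k))
            diags.append({"V": f.V, "min_abs_eig": f.diagnostics["min_abs_eig"]})
    return TwoParCurve("fc", np.array(rows).reshape(-1, 3), diags)


def hopf_curve(p: ModelParams, h_range: tuple[float, float] = (0.0, 0.35),
               n: int = 141) -> TwoParCurve:
    rows, diags = [], []
    for h in _h_grid(h_range, n):
        for k, q in enumerate(find_hopf(h, p)):
            rows.append((q.gCANTot, h, k))
            diags.append({"V": q.V, "re_pair": q.diagnostics["re_pair"],
                          "omega": q.diagnostics["omega"]})
    return TwoParCurve("hc", np.array(rows).reshape(-1, 3), diags)


def _cycle_ends(h: float, p: ModelParams, which: str):
    """Lower ('homo') or upper ('lc') termination of the attracting cycle
    branch at one h, by marching the settling-based continuation."""
    folds = find_folds(h, p)
    hopfs = find_hopf(h, p)
    if not hopfs:
        return None
    pos = [f.gCANTot for f in folds if f.gCANTot > 0]
    g_lo = min(pos) if pos else 0.0
    g_hopf = max(q.gCANTot for q in hopfs)
    found = None
    # the attracting-cycle window need not reach the fold (homoclinic
    # regimes) nor stop at the Hopf (bistable window up to the LPC)
    for frac in (0.5, 0.75, 0.25, 1.1):
        g0 = g_lo + frac * max(g_hopf - g_lo, 1e-3)
        if g0 <= 0:
            continue
        found = find_stable_cycle(g0, h, p)
        if found is not None:
            break
    if found is None:
        return None
    direction = -1.0 if which == "homo" else +1.0
    stop = -0.05 if which == "homo" else g_hopf + 0.3
    cb = continue_cycles(g0, h, p, direction=direction, g_stop=stop,
                         start_point=found, dg=6e-3)
    if which == "homo" and cb.termination in ("period_blowup", "cycle_vanished"):
        return cb.g_term, {"period_last": float(cb.period[-1]),
                           "termination": cb.termination}
    if which == "lc" and cb.termination == "lpc":
        mult = cb.multipliers[-1]
        return cb.g_term, {"multipliers": mult.tolist()}
    return None


def lpc_curve(p: ModelParams, h_range: tuple[float, float] = (0.02, 0.32),
              n: int = 13) -> TwoParCurve:
    """Fold-of-cycles curve by per-h continuation (coarse by default: each
    point costs a full cycle-branch march)."""
    rows, diags = [], []
    for h in _h_grid(h_range, n):
        end = _cycle_ends(h, p, "lc")
        if end is not None:
            rows.append((end[0], h, 0))
            diags.append(end[1])
    return TwoParCurve("lc", np.array(rows).reshape(-1, 3), diags)


def homoclinic_contour(p: ModelParams, h_range: tuple[float, float] = (0.02, 0.32),
                       n: int = 13, period_max: float = PERIOD_MAX) -> TwoParCurve:
    """Approximate homoclinic/SNIC curve: lower cycle termination per h."""
    rows, diags = [], []
    for h in _h_grid(h_range, n):
        end = _cycle_ends(h, p, "homo")
        if end is not None:
            rows.append((end[0], h, 0))
            diags.append(end[1])
    return TwoParCurve("homo", np.array(rows).reshape(-1, 3), diags,
                       approximate=True)


# --------------------------------------------------------------------------
# trajectory overlay
# --------------------------------------------------------------------------

def project_trajectory(traj: Trajectory) -> np.ndarray:
    """Project a full-system trajectory to (gCANTot, h) = (gCAN f(Ca), h)."""
    g = ca_to_gcan(traj["Ca"], traj.params)
    return np.column_stack([g, traj["h"]])


def overlay_and_crossings(curves: list[TwoParCurve], traj: Trajectory) -> list[dict]:
    """Signed crossings of each curve by the projected trajectory.

    For each curve (and sub-branch), the residual g_traj(t) - g_curve(h(t))
    is monitored; sign changes are reported as (time, kind, branch,
    direction) with direction +1 for crossings toward larger gCANTot.
    """
    proj = project_trajectory(traj)
    t = traj.t
    out = []
    for curve in curves:
        branches = (np.unique(curve.points[:, 2]).astype(int)
                    if curve.points.size else [])
        for b in branches:
            pts = curve.points[curve.points[:, 2] == b]
            if pts.shape[0] < 2:
                continue
            order = np.argsort(pts[:, 1])
            hgrid, ggrid = pts[order, 1], pts[order, 0]
            gcurve = np.interp(proj[:, 1], hgrid, ggrid,
                               left=np.nan, right=np.nan)
            res = proj[:, 0] - gcurve
            ok = np.isfinite(res)
            idx = np.where(ok[:-1] & ok[1:] &
                           (np.sign(res[:-1]) * np.sign(res[1:]) < 0))[0]
            for i in idx:
                frac = -res[i] / (res[i + 1] - res[i])
                out.append({"time": float(t[i] + frac * (t[i + 1] - t[i])),
                            "kind": curve.kind, "branch": int(b),
                            "direction": int(np.sign(res[i + 1] - res[i]))})
    return sorted(out, key=lambda d: d["time"])


def scurve_shift_report(k1_values, p: ModelParams,
                        h_map: dict[float, float] | None = None,
                        h_frozen: float = 0.2834,
                        Vref_middle: float = -36.0,
                        Vref_lower: float = -55.0) -> list[dict]:
    """Fold locations and branch positions of the S-curve per k1.

    Raising the induction gain k1 leaves the fold count unchanged but shifts
    the bifurcation points: the induced current moves every branch toward
    smaller gCANTot, while the accompanying drop of the burst-average h
    raises gCANTot mostly on the middle/upper branch (where the persistent-Na
    activation is large), so with matched h values (``h_map``: k1 -> frozen
    h) the middle branch moves right relative to the lower branch.
    """
    from .fastslow import gcan_of_V

    out = []
    for k1 in k1_values:
        if k1 < 0:
            raise ValueError("k1 must be >= 0")
        h = (h_map or {}).get(k1, h_frozen)
        q = p.with_(k1=float(k1))
        folds = find_folds(h, q)
        out.append({"k1": float(k1), "h_frozen": float(h), "n_folds": len(folds),
                    "fold_g": [f.gCANTot for f in folds],
                    "fold_V": [f.V for f in folds],
                    "middle_g_at_Vref": float(gcan_of_V(Vref_middle, h, q)),
                    "lower_g_at_Vref": float(gcan_of_V(Vref_lower, h, q))})
    return out
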