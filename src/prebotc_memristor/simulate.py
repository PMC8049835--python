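"""Time integration of the full system and its subsystems.

The integrator is LSODA (adaptive, stiffness-switching) driving the
numba-compiled vector fields; solutions are returned at the accepted internal
steps, which error control makes dense during spikes and sparse during
quiescence.  Default tolerances rtol=1e-8, atol=1e-10 resolve spike peaks to
well under a solver step; the tolerance-convergence property (halving the
tolerances moves V(t) by a small fraction of a mV) is part of the test suite.

Initial conditions are not part of the modelled experiments — only the
attractor matters — so a default inside the bursting basin is used and a long
transient (20 s of model time) is discarded before any measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model_core import (
    FastParams,
    FastState,
    FullState,
    ModelParams,
    ca_rhs_nb,
    fast_rhs_nb,
    full_rhs_nb,
    pack_fast_params,
    pack_params,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "DEFAULT_INITIAL",
    "integrate_full",
    "integrate_fast",
    "integrate_ca",
    "average_h",
    "burst_cycle_starts",
]

DEFAULT_INITIAL = FullState(V=-60.0, n=0.01, h=0.45, phi=-20.0, Ca=0.03, l=0.93)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to reproduce one full-system run."""

    params: ModelParams = field(default_factory=ModelParams)
    initial: FullState = DEFAULT_INITIAL
    t_end: float = 60000.0       # ms
    transient: float = 20000.0   # ms discarded from the returned trajectory
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 1.0        # ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.transient < self.t_end:
            raise ValueError("need 0 <= transient < t_end")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Dense solution sampled at the solver's accepted steps.

    ``t`` is strictly increasing (ms, absolute time of the run including any
    discarded transient offset); ``states`` maps variable name -> array.
    """

    t: np.ndarray
    states: dict[str, np.ndarray]
    params: ModelParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.t.size
        if n < 2:
            raise ValueError("trajectory needs at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        for k, v in self.states.items():
            if v.shape != (n,):
                raise ValueError(f"state {k} misaligned with t")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in state {k}")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.states[key]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.states)

    def window(self, t0: float, t1: float) -> "Trajectory":
        m = (self.t >= t0) & (self.t <= t1)
        return Trajectory(self.t[m], {k: v[m] for k, v in self.states.items()},
                          self.params, dict(self.meta))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **self.states})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _solve(rhs, y0: np.ndarray, args: tuple, t_span: tuple[float, float],
           rtol: float, atol: float, max_step: float) -> tuple[np.ndarray, np.ndarray]:
    sol = solve_ivp(rhs, t_span, y0, args=args, method="LSODA",
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else y0
        raise RuntimeError(
            f"LSODA failed at t={sol.t[-1] if sol.t.size else t_span[0]:.3f} ms "
            f"(last state {np.array2string(last, precision=4)}): {sol.message}")
    return sol.t, sol.y


def integrate_full(cfg: SimConfig) -> Trajectory:
    """Integrate the 6-D system; the transient is dropped from the result."""
    pv = pack_params(cfg.params)
    y0 = cfg.initial.as_array()
    t, y = _solve(full_rhs_nb, y0, (pv,), (0.0, cfg.t_end),
                  cfg.rtol, cfg.atol, cfg.max_step)
    keep = t >= cfg.transient
    # keep one pre-transient sample so the window starts at/before the cutoff
    if not keep[0]:
        first = int(np.argmax(keep))
        keep[max(first - 1, 0)] = True
    states = dict(zip(("V", "n", "h", "phi", "Ca", "l"), y[:, keep]))
    meta = {"solver": "LSODA", "rtol": cfg.rtol, "atol": cfg.atol,
            "max_step": cfg.max_step, "transient": cfg.transient,
            "initial": cfg.initial, "t_end": cfg.t_end,
            "final_state": FullState.from_array(y[:, -1])}
    return Trajectory(t[keep], states, cfg.params, meta)


def integrate_fast(fp: FastParams, initial: FastState | Sequence[float],
                   t_end: float, rtol: float = 1e-8, atol: float = 1e-10,
                   max_step: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Integrate the 3-D fast subsystem at frozen (h, gCANTot)."""
    pvf = pack_fast_params(fp)
    y0 = initial.as_array() if isinstance(initial, FastState) else np.asarray(initial, float)
    t, y = _solve(fast_rhs_nb, y0, (pvf,), (t0, t0 + t_end), rtol, atol, max_step)
    states = dict(zip(("V", "n", "phi"), y))
    return Trajectory(t, states, fp.base,
                      {"solver": "LSODA", "h_frozen": fp.h_frozen,
                       "gCANTot": fp.gCANTot, "rtol": rtol, "atol": atol})


def integrate_ca(p: ModelParams, initial: Sequence[float], t_end: float,
                 rtol: float = 1e-10, atol: float = 1e-12,
                 max_step: float = 50.0) -> Trajectory:
    """Integrate the decoupled (Ca, l) subsystem."""
    pv = pack_params(p)
    y0 = np.asarray(initial, float)
    t, y = _solve(ca_rhs_nb, y0, (pv,), (0.0, t_end), rtol, atol, max_step)
    return Trajectory(t, dict(zip(("Ca", "l"), y)), p, {"solver": "LSODA"})


# --------------------------------------------------------------------------
# burst-cycle bookkeeping
# --------------------------------------------------------------------------

def _spike_times(traj: Trajectory, threshold: float = -35.0,
                 prominence: float = 5.0) -> np.ndarray:
    idx, _ = find_peaks(traj["V"], height=threshold, prominence=prominence)
    return traj.t[idx]

def burst_cycle_starts(traj: Trajectory, gap_ms: float = 300.0,
                       threshold: float = -35.0) -> np.ndarray:
    """Times of the first spike of each burst cycle.

    Bursts are delimited by the resting stages (low-potential quiescent
    spans, or depolarized rests for high-current regimes) so that mid-burst
    spike-free passages do not split a cycle; a plain inter-spike-gap rule
    is the fallback when no rest is detected.
    """
    from .isi_metrics import _plateau_spans, _quiescent_spans, detect_spikes

    tp = _spike_times(traj, threshold)
    if tp.size < 2:
        return np.empty(0)
    train = detect_spikes(traj, threshold)
    rests = _quiescent_spans(traj, train) or _plateau_spans(traj, train)
    if len(rests) >= 2:
        starts = []
        for _, b in rests:
            after = tp[tp > b]
            if after.size:
                starts.append(after[0])
        return np.unique(starts)
    gaps = np.diff(tp)
    return tp[1:][gaps > gap_ms]


def average_h(traj: Trajectory, window: tuple[float, float] | None = None,
              gap_ms: float = 300.0) -> float:
    """Time-weighted mean of h over an integer number of burst cycles.

    The averaging window is snapped to burst-cycle boundaries detected from V
    (first spike after an inter-burst gap).  Raises if the window covers
    fewer than one full cycle.
    """
    if "h" not in traj.states:
        raise ValueError("trajectory has no h component")
    starts = burst_cycle_starts(traj, gap_ms)
    if window is not None:
        starts = starts[(starts >= window[0]) & (starts <= window[1])]
    if starts.size < 2:
        raise ValueError("window covers fewer than one full burst cycle")
    a, b = starts[0], starts[-1]
    m = (traj.t >= a) & (traj.t <= b)
    return float(np.trapezoid(traj["h"][m], traj.t[m]) / (traj.t[m][-1] - traj.t[m][0]))
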