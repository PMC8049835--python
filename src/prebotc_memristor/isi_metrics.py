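"""Spike detection, interspike-interval diagrams and firing-pattern labels.

A burst cycle of the reference pattern decomposes into four phases:

    (1) low-potential quiescence (V below the quiescence ceiling, no spikes)
    (2) spiking with decreasing peak envelope (slow passage toward the focus)
    (3) small-amplitude spiking around the focus
    (4) spiking with growing envelope until the burst ends

Raising the applied current or the induction gain first removes phase (1)
(everything spikes) and then replaces phase (3) with a depolarized spike-free
plateau (quiescence at high potential).  The pattern classifier below encodes
exactly that progression; sweeps over I_extz, k1, alpha and beta locate the
two regime boundaries by label changes on a grid.

Operational constants (declared conventions, exposed as arguments): spike
threshold -35 mV with 5 mV prominence; a low-potential quiescent span must be
spike-free, stay below the -35 mV quiescence ceiling (the natural separatrix:
the lower-branch rest sits below -40 mV and the depolarized focus above
-27 mV in every regime), and last at least 100 ms (spike undershoots last
tens of ms, rest phases hundreds); small-amplitude means peak-to-trough under
15 mV; a high-potential resting plateau must be visually flat, not merely
free of prominent spikes — phase (3) oscillations can fall under any spike
prominence — so it requires a rolling 30-ms peak-to-peak amplitude under
1 mV sustained for at least 300 ms at depolarized V.  ISIs are peak-to-peak
times, reported as log10(ms) in sweep outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .simulate import SimConfig, Trajectory, integrate_full

__all__ = [
    "SpikeTrain",
    "PhaseSegmentation",
    "BurstPhases",
    "SweepResult",
    "detect_spikes",
    "compute_isi",
    "segment_phases",
    "classify_pattern",
    "sweep",
    "SPIKE_THRESHOLD",
    "QUIESCENCE_CEILING",
    "SMALL_AMP_CAP",
    "PLATEAU_MIN_MS",
    "PLATEAU_FLAT_MV",
    "QUIESCENT_MIN_MS",
]

SPIKE_THRESHOLD = -35.0    # mV, minimum peak height
SPIKE_PROMINENCE = 5.0     # mV
QUIESCENCE_CEILING = -35.0  # mV, low rest stays below this
SMALL_AMP_CAP = 15.0       # mV peak-to-trough for "small amplitude"
PLATEAU_MIN_MS = 300.0     # minimal duration of a flat depolarized rest
PLATEAU_FLAT_MV = 1.0      # rolling peak-to-peak ceiling for "flat"
PLATEAU_WINDOW_MS = 30.0   # rolling-amplitude window
QUIESCENT_MIN_MS = 100.0   # minimal duration of a low-potential quiescent span
BURST_GAP_MS = 300.0       # inter-spike gap separating bursts

PATTERNS = ("bursting_low_quiescence", "continuous_spiking",
            "bursting_high_quiescence", "quiescent")


@dataclass
class SpikeTrain:
    peak_times: np.ndarray    # ms, strictly increasing, parabola-refined
    peak_values: np.ndarray   # mV
    threshold: float

    def __len__(self) -> int:
        return self.peak_times.size


@dataclass
class BurstPhases:
    """Phase boundaries of one burst cycle; empty phases have zero duration."""

    start: dict[str, float]      # phase name -> start time (ms)
    duration: dict[str, float]   # phase name -> duration (ms)


@dataclass
class PhaseSegmentation:
    cycles: list[BurstPhases]

    def mean_duration(self, phase: str) -> float:
        d = [c.duration[phase] for c in self.cycles]
        return float(np.mean(d)) if d else 0.0


@dataclass
class SweepResult:
    param_name: str
    param_values: np.ndarray
    isis_log10: list[np.ndarray]
    labels: list[str]
    thresholds: list[tuple[float, str]] = field(default_factory=list)
    failed: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for v, isis, lab in zip(self.param_values, self.isis_log10, self.labels):
            if isis.size == 0:
                rows.append((v, np.nan, lab))
            for x in isis:
                rows.append((v, x, lab))
        pd.DataFrame(rows, columns=[self.param_name, "isi_log10", "label"]).to_csv(
            path, index=False)


# --------------------------------------------------------------------------
# spikes and ISIs
# --------------------------------------------------------------------------

def detect_spikes(traj: Trajectory, threshold: float = SPIKE_THRESHOLD,
                  min_prominence: float = SPIKE_PROMINENCE) -> SpikeTrain:
    """Local maxima of V above threshold, peak times refined by a parabola
    through the three samples around each maximum."""
    t, V = traj.t, traj["V"]
    idx, _ = find_peaks(V, height=threshold, prominence=min_prominence)
    times = np.empty(idx.size)
    values = np.empty(idx.size)
    for k, i in enumerate(idx):
        if 0 < i < t.size - 1:
            # quadratic through (t,V) at i-1, i, i+1 (nonuniform spacing)
            t0, t1, t2 = t[i - 1] - t[i], 0.0, t[i + 1] - t[i]
            v0, v1, v2 = V[i - 1], V[i], V[i + 1]
            denom = (t0 - t2) * (t0 * t2)
            if denom != 0:
                a = (t2 * (v0 - v1) - t0 * (v2 - v1)) / denom
                b = (t0 * t0 * (v2 - v1) - t2 * t2 * (v0 - v1)) / denom
                if a < 0:
                    dt = -b / (2.0 * a)
                    times[k] = t[i] + dt
                    values[k] = v1 + b * dt + a * dt * dt
                    continue
        times[k] = t[i]
        values[k] = V[i]
    return SpikeTrain(times, values, threshold)


def compute_isi(train: SpikeTrain, log10: bool = False) -> np.ndarray:
    """Successive spike-peak differences (ms), optionally log10-transformed."""
    if len(train) < 2:
        return np.empty(0)
    isi = np.diff(train.peak_times)
    return np.log10(isi) if log10 else isi


# --------------------------------------------------------------------------
# phase segmentation and pattern classification
# --------------------------------------------------------------------------

def _burst_groups(train: SpikeTrain, gap_ms: float = BURST_GAP_MS) -> list[np.ndarray]:
    """Indices of spikes grouped into bursts by inter-spike gaps."""
    if len(train) == 0:
        return []
    splits = np.where(np.diff(train.peak_times) > gap_ms)[0] + 1
    return np.split(np.arange(len(train)), splits)


def _spike_amplitudes(traj: Trajectory, train: SpikeTrain) -> np.ndarray:
    """Peak-to-following-trough amplitude of each spike."""
    t, V = traj.t, traj["V"]
    amps = np.empty(len(train))
    tp = train.peak_times
    for k in range(len(train)):
        t_next = tp[k + 1] if k + 1 < len(train) else t[-1]
        m = (t > tp[k]) & (t <= t_next)
        amps[k] = train.peak_values[k] - (V[m].min() if m.any() else V[-1])
    return amps


def _quiescent_spans(traj: Trajectory, train: SpikeTrain,
                     ceiling: float = QUIESCENCE_CEILING,
                     min_ms: float = QUIESCENT_MIN_MS) -> list[tuple[float, float]]:
    """Low-potential resting stages: inter-spike gaps (spike flanks trimmed)
    of at least ``min_ms`` whose mean V lies below ``ceiling``.

    The resting stage is the whole interval between one burst's last spike
    and the next burst's first spike, so the gap itself is the candidate;
    trimming removes the repolarization/depolarization flanks.
    """
    t, V = traj.t, traj["V"]
    edges = np.concatenate([[t[0]], train.peak_times, [t[-1]]])
    spans: list[tuple[float, float]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        pad = min(20.0, 0.1 * (b - a))
        a2, b2 = a + pad, b - pad
        if b2 - a2 < min_ms:
            continue
        m = (t >= a2) & (t <= b2)
        if m.sum() >= 2 and V[m].mean() < ceiling:
            spans.append((a2, b2))
    return spans


def _plateau_spans(traj: Trajectory, train: SpikeTrain, min_ms: float = PLATEAU_MIN_MS,
                   floor: float = QUIESCENCE_CEILING,
                   flat_mv: float = PLATEAU_FLAT_MV) -> list[tuple[float, float]]:
    """Flat depolarized rests: spike-free spans containing a segment of at
    least ``min_ms`` whose rolling 30-ms peak-to-peak stays under ``flat_mv``
    with mean V above ``floor``."""
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    t = traj.t
    edges = np.concatenate([[t[0]], train.peak_times, [t[-1]]])
    spans = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < min_ms:
            continue
        pad = min(20.0, 0.1 * (b - a))
        tg = np.arange(a + pad, b - pad, 1.0)  # 1 ms resampling
        if tg.size < min_ms:
            continue
        vg = np.interp(tg, t, traj["V"])
        w = int(PLATEAU_WINDOW_MS)
        ptp = maximum_filter1d(vg, w) - minimum_filter1d(vg, w)
        flat = ptp < flat_mv
        # longest contiguous flat run
        i = 0
        while i < flat.size:
            if flat[i]:
                j = i
                while j + 1 < flat.size and flat[j + 1]:
                    j += 1
                if tg[j] - tg[i] >= min_ms and vg[i:j + 1].mean() > floor:
                    spans.append((tg[i], tg[j]))
                i = j + 1
            else:
                i += 1
    return spans


def segment_phases(traj: Trajectory, train: SpikeTrain | None = None,
                   small_amp_cap: float = SMALL_AMP_CAP,
                   ceiling: float = QUIESCENCE_CEILING) -> PhaseSegmentation:
    """Split each full burst cycle into the four canonical phases.

    A cycle runs from the start of one quiescent span to the start of the
    next; phase (2) covers the leading spikes down to the first
    small-amplitude spike, phase (3) the small-amplitude run, phase (4) the
    regrowth until the last spike of the burst.  Patterns missing a phase
    report a zero duration for it.
    """
    if train is None:
        train = detect_spikes(traj)
    amps = _spike_amplitudes(traj, train) if len(train) else np.empty(0)
    qspans = _quiescent_spans(traj, train, ceiling, QUIESCENT_MIN_MS)
    tp = train.peak_times
    cycles: list[BurstPhases] = []
    # a cycle runs from one resting stage to the next; the burst is whatever
    # lies in between (phase-3 sub-prominence oscillation included)
    for (qa, qb), (qa2, _) in zip(qspans[:-1], qspans[1:]):
        g = np.where((tp > qb) & (tp < qa2))[0]
        if g.size < 2:
            continue
        t_first, t_last = tp[g[0]], tp[g[-1]]
        small = amps[g] < small_amp_cap
        if small.any():
            i3 = int(np.argmax(small))               # first small-amplitude spike
            i4 = g.size - 1 - int(np.argmax(small[::-1]))  # last small-amp spike
            t3 = tp[g[i3]]
            t4 = tp[g[min(i4 + 1, g.size - 1)]]
        else:
            t3 = t4 = t_last
        start = {"p1": qa, "p2": t_first, "p3": t3, "p4": t4}
        duration = {"p1": qb - qa, "p2": t3 - t_first,
                    "p3": t4 - t3, "p4": t_last - t4}
        cycles.append(BurstPhases(start, duration))
    return PhaseSegmentation(cycles)


def classify_pattern(traj: Trajectory, seg: PhaseSegmentation | None = None,
                     min_window_ms: float = 2000.0) -> str:
    """Deterministic firing-pattern label from phase presence.

    low-potential quiescent span present -> bursting_low_quiescence;
    depolarized spike-free plateau present -> bursting_high_quiescence;
    spikes but neither -> continuous_spiking; no spikes -> quiescent.
    """
    if traj.t[-1] - traj.t[0] < min_window_ms:
        raise ValueError("window too short to classify")
    train = detect_spikes(traj)
    if len(train) == 0:
        return "quiescent"
    if _quiescent_spans(traj, train, QUIESCENCE_CEILING, QUIESCENT_MIN_MS):
        return "bursting_low_quiescence"
    if _plateau_spans(traj, train):
        return "bursting_high_quiescence"
    return "continuous_spiking"


# --------------------------------------------------------------------------
# parameter sweeps
# --------------------------------------------------------------------------

def sweep(param: str, grid: np.ndarray, base: SimConfig | None = None) -> SweepResult:
    """Simulate the full system across ``grid`` values of one stimulation
    parameter and collect log10-ISI sets, pattern labels and label changes."""
    if param not in ("Iextz", "k1", "alpha", "beta"):
        raise ValueError("sweep parameter must be one of Iextz, k1, alpha, beta")
    base = base or SimConfig()
    grid = np.asarray(grid, float)
    values, isis, labels, failed = [], [], [], []
    for v in grid:
        cfg = base.with_(params=base.params.with_(**{param: float(v)}))
        try:
            traj = integrate_full(cfg)
            train = detect_spikes(traj)
            isis.append(compute_isi(train, log10=True))
            labels.append(classify_pattern(traj))
        except (RuntimeError, ValueError):
            isis.append(np.empty(0))
            labels.append("failed")
            failed.append(float(v))
        values.append(float(v))
    thresholds = []
    for i in range(1, len(values)):
        if labels[i] != labels[i - 1] and "failed" not in (labels[i], labels[i - 1]):
            thresholds.append((values[i], f"{labels[i - 1]} -> {labels[i]}"))
    return SweepResult(param, np.array(values), isis, labels, thresholds, failed)


def classify_at(param: str, value: float, base: SimConfig | None = None) -> str:
    """Pattern label of the attractor at one stimulation-parameter value."""
    base = base or SimConfig()
    cfg = base.with_(params=base.params.with_(**{param: float(value)}))
    return classify_pattern(integrate_full(cfg))


def locate_regime_boundary(param: str, lo: float, hi: float, step: float,
                           predicate, base: SimConfig | None = None) -> float | None:
    """First grid value in [lo, hi] (resolution ``step``) whose attractor
    label satisfies ``predicate``, by bisection on the grid.

    Assumes the label change is monotone across the bracket (true for the
    quiescence-loss and plateau-onset boundaries on their stated brackets).
    Returns None when the predicate never holds on the grid.
    """
    values = np.round(np.arange(lo, hi + step / 2, step), 10)
    flags: dict[int, bool] = {}

    def ok(i: int) -> bool:
        if i not in flags:
            flags[i] = bool(predicate(classify_at(param, values[i], base)))
        return flags[i]

    if ok(0):
        return float(values[0])
    if not ok(len(values) - 1):
        return None
    a, b = 0, len(values) - 1          # ok(a) False, ok(b) True
    while b - a > 1:
        m = (a + b) // 2
        if ok(m):
            b = m
        else:
            a = m
    return float(values[b])
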