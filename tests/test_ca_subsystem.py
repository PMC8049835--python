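"""Calcium-subsystem analysis: nullclines, Hill map, relaxation orbit."""

import numpy as np
import pytest

from prebotc_memristor.ca_subsystem import (
    ca_to_gcan,
    gcan_to_ca,
    ip3_activity_scan,
    nullclines,
    relaxation_orbit,
)
from prebotc_memristor.model_core import ModelParams, ca_rhs
from prebotc_memristor.simulate import SimConfig, integrate_full

P = ModelParams()


def test_l_nullcline_midpoint():
    (_, _), (ca, l_l), _ = nullclines(P)
    i = int(np.argmin(np.abs(ca - P.Kd)))
    assert l_l[i] == pytest.approx(0.5, abs=1e-3)


def test_ca_nullcline_zeroes_the_flux():
    (ca, l_ca), _, _ = nullclines(P)
    ok = np.isfinite(l_ca) & (l_ca <= 1.0)
    for c, l in list(zip(ca[ok], l_ca[ok]))[::100]:
        assert abs(ca_rhs(float(c), float(l), P)[0]) < 1e-10


def test_nullcline_knees_bracket_the_orbit():
    """Two knees exist and the relaxation orbit's Ca range spans them."""
    _, _, knees = nullclines(P)
    assert len(knees) == 2
    orbit = relaxation_orbit(P)
    ks = sorted(k["Ca"] for k in knees)
    assert orbit.Ca.min() < ks[0] < ks[1] < orbit.Ca.max()


def test_hill_map_inverse_pair():
    assert float(gcan_to_ca(0.02937, P)) == pytest.approx(0.02942, abs=5e-5)
    assert float(ca_to_gcan(P.KCAN, P)) == pytest.approx(P.gCAN / 2, rel=1e-12)
    rng = np.random.default_rng(3)
    g = rng.uniform(1e-4, P.gCAN - 1e-4, 100)
    np.testing.assert_allclose(ca_to_gcan(gcan_to_ca(g, P), P), g, rtol=1e-12)
    with pytest.raises(ValueError):
        gcan_to_ca(P.gCAN, P)
    with pytest.raises(ValueError):
        gcan_to_ca(0.0, P)


def test_relaxation_orbit_period_and_markers():
    orbit = relaxation_orbit(P, gcan_snic=0.0294)
    assert orbit.period == pytest.approx(1824.0, rel=0.01)
    assert orbit.P1 and orbit.P2
    assert 0.0 < orbit.P2["Ca"] < 0.05
    assert 0.0 <= orbit.P1["t"] < orbit.period


def test_orbit_initial_condition_invariance():
    a = relaxation_orbit(P, initial=(0.05, 0.9))
    b = relaxation_orbit(P, initial=(0.4, 0.6))
    assert a.period == pytest.approx(b.period, rel=1e-3)


def test_orbit_matches_full_system_burst_period(fig2_traj):
    """The decoupled subsystem paces the burst: its period equals the full
    system's burst-cycle period."""
    from prebotc_memristor.simulate import burst_cycle_starts

    starts = burst_cycle_starts(fig2_traj)
    burst_period = float(np.mean(np.diff(starts)))
    orbit = relaxation_orbit(P)
    assert orbit.period == pytest.approx(burst_period, rel=0.10)


def test_quiescent_span_bracketed_by_subsystem_markers():
    """In the SNIC regime (Iextz=30) the P2 -> P1 stretch of the subsystem
    orbit brackets the full model's quiescent phase from above: spiking
    stops only after a slow-passage delay past the Ca_SNIC crossing, so the
    measured rest is somewhat shorter than the marker interval."""
    from prebotc_memristor.isi_metrics import _quiescent_spans, detect_spikes

    p30 = ModelParams(Iextz=30.0, k1=0.1)
    traj = integrate_full(SimConfig(params=p30))
    orbit = relaxation_orbit(P, gcan_snic=0.0294)
    p2_to_p1 = (orbit.period - orbit.P2["t"]) + orbit.P1["t"]
    spans = _quiescent_spans(traj, detect_spikes(traj))
    q = float(np.mean([b - a for a, b in spans]))
    assert q < p2_to_p1          # delay shortens the observed rest
    assert p2_to_p1 == pytest.approx(q, rel=0.5)


def test_ip3_activity_window():
    scan = ip3_activity_scan(P, (0.5, 2.0), grid_n=7, t_run=150000.0)
    flags = {round(s["IP3"], 2): s["oscillatory"] for s in scan}
    assert flags[0.5] is False
    assert flags[1.25] is True
    assert flags[2.0] is False
    with pytest.raises(ValueError):
        ip3_activity_scan(P, (0.5, 2.0), grid_n=2)


def test_no_oscillation_error_names_fixed_point():
    with pytest.raises(RuntimeError, match="settles near"):
        relaxation_orbit(P.with_(IP3=0.5))


def test_subsystem_independence_from_full_run():
    """The (Ca, l) loop extracted from a full run equals the standalone
    orbit (same pacemaker, matched initial condition)."""
    cfg = SimConfig(params=ModelParams(Iextz=0.0, k1=0.0), t_end=30000.0,
                    transient=0.0)
    full = integrate_full(cfg)
    orbit = relaxation_orbit(cfg.params,
                             initial=(cfg.initial.Ca, cfg.initial.l))
    # compare periods: Ca peaks of the full run
    from scipy.signal import find_peaks

    pk, _ = find_peaks(full["Ca"], prominence=0.3)
    T_full = float(np.mean(np.diff(full.t[pk])))
    assert orbit.period == pytest.approx(T_full, rel=1e-3)
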