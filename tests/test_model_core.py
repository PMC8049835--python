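"""Vector-field building blocks: gating functions, currents, consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from prebotc_memristor.model_core import (
    FastParams,
    FullState,
    ModelParams,
    ca_rhs,
    f_can,
    fast_rhs,
    full_rhs,
    gating_inf,
    jacobian,
    membrane_currents,
    rho,
    tau_gate,
)

P = ModelParams()


@pytest.mark.parametrize("V, theta, slope, expected", [
    (-34.0, -34.0, -5.0, 0.5),            # half-activation at V = theta
    (-48.0, -48.0, 6.0, 0.5),
    (-44.0, -40.0, -6.0, 1.0 / (1.0 + math.exp((-44.0 + 40.0) / -6.0))),
])
def test_gating_inf_values(V, theta, slope, expected):
    assert gating_inf(V, theta, slope) == pytest.approx(expected, abs=1e-12)


@given(st.floats(-80, 20), st.floats(-80, 20))
@settings(max_examples=50, deadline=None)
def test_gating_inf_monotone(v1, v2):
    """Sigmoid increases in V for negative slope, decreases for positive."""
    lo, hi = sorted((v1, v2))
    assert gating_inf(hi, -34.0, -5.0) >= gating_inf(lo, -34.0, -5.0)
    assert gating_inf(hi, -48.0, 6.0) <= gating_inf(lo, -48.0, 6.0)


def test_gating_zero_slope_rejected():
    with pytest.raises(ValueError):
        gating_inf(-40.0, -34.0, 0.0)
    with pytest.raises(ValueError):
        tau_gate(-40.0, 10.0, -29.0, 0.0)


@pytest.mark.parametrize("V, tau_bar, theta, slope, expected", [
    (-29.0, 10.0, -29.0, -4.0, 10.0),          # maximum at V = theta
    (-48.0, 10000.0, -48.0, 6.0, 10000.0),
    (0.0, 10000.0, -48.0, 6.0, 10000.0 / math.cosh(4.0)),
])
def test_tau_gate_values(V, tau_bar, theta, slope, expected):
    assert tau_gate(V, tau_bar, theta, slope) == pytest.approx(expected, rel=1e-12)


def test_f_can_hill_midpoint_and_limits():
    assert f_can(0.74, 0.74, 0.97) == pytest.approx(0.5, abs=1e-14)
    assert f_can(1e-6, 0.74, 0.97) < 1e-4
    assert f_can(1e6, 0.74, 0.97) > 0.999
    # strictly increasing
    ca = np.linspace(0.01, 2.0, 200)
    assert np.all(np.diff(f_can(ca, 0.74, 0.97)) > 0)


def test_f_can_reproduces_snic_conductance_pair():
    """gCAN * f(0.02942) recovers the effective conductance 0.02937 at which
    the spiking cycle of the depolarized regime disappears."""
    assert 0.7 * f_can(0.02942, 0.74, 0.97) == pytest.approx(0.02937, abs=2e-6)


def test_f_can_domain_error():
    with pytest.raises(ValueError):
        f_can(0.0, 0.74, 0.97)


def test_rho_memductance():
    assert rho(0.0, 1.0, 6e-5) == 1.0
    assert rho(10.0, 1.0, 6e-5) == pytest.approx(1.018, abs=1e-12)
    phis = np.linspace(-50, 50, 101)
    assert np.allclose(rho(phis, 1.0, 6e-5), rho(-phis, 1.0, 6e-5))


def test_reversal_potential_zeros():
    s = FullState(V=P.VL, n=0.3, h=0.4, phi=0.0, Ca=0.05, l=0.9)
    assert membrane_currents(s, P)["IL"] == 0.0
    s = FullState(V=P.Vsyn_e, n=0.3, h=0.4, phi=0.0, Ca=0.05, l=0.9)
    assert membrane_currents(s, P)["Itonic_e"] == 0.0
    s = FullState(V=P.VNa, n=0.3, h=0.4, phi=0.0, Ca=0.05, l=0.9)
    cur = membrane_currents(s, P)
    assert cur["INa"] == cur["INaP"] == cur["ICAN"] == 0.0


def test_current_balance_at_root_found_equilibrium():
    """At a V-equilibrium located by a root finder (gates at steady state),
    the currents balance the applied and induced terms to 1e-10."""
    p = ModelParams(Iextz=3.0, k1=0.2)
    h, Ca = 0.3, 0.05

    def dv(V):
        s = FullState(V=V, n=float(gating_inf(V, p.theta_n, p.sigma_n)),
                      h=h, phi=V / p.k2, Ca=Ca, l=0.9)
        return float(full_rhs(s, p)[0])

    Vs = np.linspace(-75.0, -10.0, 400)
    vals = np.array([dv(v) for v in Vs])
    i = int(np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0][0])
    V_eq = brentq(dv, Vs[i], Vs[i + 1], xtol=1e-14)
    s = FullState(V=V_eq, n=float(gating_inf(V_eq, p.theta_n, p.sigma_n)),
                  h=h, phi=V_eq / p.k2, Ca=Ca, l=0.9)
    cur = membrane_currents(s, p)
    total = (cur["INa"] + cur["IK"] + cur["IL"] + cur["INaP"]
             + cur["ICAN"] + cur["Itonic_e"])
    assert total == pytest.approx(p.Iextz - cur["Iinduced"], abs=1e-10)


def test_full_rhs_partial_equilibria():
    p = ModelParams(k2=3.0)
    V = -50.0
    s = FullState(V=V, n=float(gating_inf(V, p.theta_n, p.sigma_n)),
                  h=0.4, phi=-20.0, Ca=0.4, l=p.Kd / (p.Kd + 0.4))
    dy = full_rhs(s, p)
    assert dy[1] == pytest.approx(0.0, abs=1e-14)       # n at steady state
    assert dy[5] == pytest.approx(0.0, abs=1e-14)       # l on its nullcline
    s2 = FullState(V=-60.0, n=0.1, h=0.4, phi=-20.0, Ca=0.05, l=0.9)
    assert full_rhs(s2, p)[3] == pytest.approx(0.0, abs=1e-14)  # dphi at V=k2*phi


def test_full_rhs_rejects_bad_state():
    with pytest.raises(ValueError):
        full_rhs(np.array([np.nan, 0.1, 0.4, 0.0, 0.05, 0.9]), P)


@given(st.floats(-70, 0), st.floats(0.01, 0.99), st.floats(0.01, 0.99),
       st.floats(-25, 5), st.floats(0.01, 1.0), st.floats(0.01, 0.99))
@settings(max_examples=200, deadline=None)
def test_fast_full_consistency(V, n, h, phi, Ca, l):
    """Fast subsystem with (h, gCAN f(Ca)) frozen equals the (V, n, phi)
    components of the full field to machine precision."""
    p = ModelParams(Iextz=7.0, k1=0.3)
    full = full_rhs(FullState(V, n, h, phi, Ca, l), p)
    fp = FastParams(h_frozen=h, gCANTot=float(p.gCAN * f_can(Ca, p.KCAN, p.nCAN)),
                    base=p)
    fast = fast_rhs(np.array([V, n, phi]), fp)
    np.testing.assert_allclose(fast, full[[0, 1, 3]], rtol=1e-12, atol=1e-14)


def test_ca_rhs_decoupled_from_electrical_state():
    rng = np.random.default_rng(0)
    base = full_rhs(FullState(-50.0, 0.2, 0.4, -15.0, 0.08, 0.85), P)[[4, 5]]
    for _ in range(20):
        V, n, h, phi = rng.uniform([-70, 0, 0, -30], [0, 1, 1, 10])
        other = full_rhs(FullState(V, n, h, phi, 0.08, 0.85), P)[[4, 5]]
        np.testing.assert_array_equal(other, base)
    np.testing.assert_array_equal(ca_rhs(0.08, 0.85, P), base)


def test_v_equation_even_in_flux():
    p = ModelParams(k1=0.5)
    a = full_rhs(FullState(-50.0, 0.2, 0.4, 17.0, 0.08, 0.85), p)[0]
    b = full_rhs(FullState(-50.0, 0.2, 0.4, -17.0, 0.08, 0.85), p)[0]
    assert a == pytest.approx(b, rel=1e-14)


def test_jacobian_numeric_matches_analytic():
    rng = np.random.default_rng(7)
    p = ModelParams(Iextz=5.0, k1=0.4)
    worst = 0.0
    for _ in range(100):
        y = rng.uniform([-70, 0.01, -25], [0, 0.99, 5])
        fp = FastParams(h_frozen=rng.uniform(0, 1), gCANTot=rng.uniform(0, 0.5),
                        base=p)
        Jn = jacobian("fast", y, fp, mode="numeric")
        Ja = jacobian("fast", y, fp, mode="analytic")
        scale = np.abs(Ja).max()
        worst = max(worst, np.abs(Jn - Ja).max() / scale)
    assert worst < 1e-6


def test_jacobian_known_entries():
    y = np.array([-50.0, 0.2, 0.4, -15.0, 0.3, 0.8])
    J = jacobian("full", y, P)
    assert J[3, 3] == pytest.approx(-P.k2, rel=1e-6)          # dphi row
    Jca = jacobian("ca", np.array([0.3, 0.8]), P)
    assert Jca[1, 1] == pytest.approx(-P.A * (P.Kd + 0.3), rel=1e-6)


def test_params_validation_and_roundtrip(tmp_path):
    with pytest.raises(ValueError):
        ModelParams(gNa=-1.0)
    with pytest.raises(ValueError):
        ModelParams(sigma=1.5)
    with pytest.raises(ValueError):
        ModelParams(sigma_n=0.0)
    with pytest.raises(ValueError):
        ModelParams.from_dict({"nope": 1.0})
    for name in ("pars.yaml", "pars.json"):
        f = tmp_path / name
        p = ModelParams(Iextz=12.5, k1=0.3)
        p.save(f)
        assert ModelParams.load(f) == p
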