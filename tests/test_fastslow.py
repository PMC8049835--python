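"""Fast-subsystem bifurcation machinery: closed form, continuation, cycles."""

import numpy as np
import pytest

from prebotc_memristor.fastslow import (
    SNIC_TOL,
    classify_cycle_termination,
    continue_cycles,
    continue_equilibria,
    equilibrium_curve_direct,
    find_folds,
    find_hopf,
    find_stable_cycle,
    gcan_of_V,
    hopf_criticality,
    label_bursting,
)
from prebotc_memristor.model_core import FastParams, ModelParams, fast_rhs

P0 = ModelParams(Iextz=0.0, k1=0.0)
P30 = ModelParams(Iextz=30.0, k1=0.1)
H0, H30 = 0.2834, 0.0986


@pytest.fixture(scope="module")
def snic_branch():
    found = find_stable_cycle(0.06, H30, P30)
    return continue_cycles(0.06, H30, P30, direction=-1.0,
                           start_point=found, g_stop=-0.05)


def test_closed_form_points_are_equilibria():
    """Residual of the fast vector field vanishes on the parametrized curve."""
    for h, p in ((H0, P0), (H30, P30), (0.15, ModelParams(Iextz=10.0, k1=0.6))):
        for V in np.linspace(-70.0, 0.0, 40):
            g = float(gcan_of_V(V, h, p))
            fp = FastParams(h_frozen=h, gCANTot=max(g, 0.0), base=p)
            y = np.array([V, 1 / (1 + np.exp((V - p.theta_n) / p.sigma_n)), V / p.k2])
            r = fast_rhs(y, fp)
            r[0] -= (g - fp.gCANTot) * (V - p.VNa) / p.C  # allow negative g
            assert np.max(np.abs(r)) < 1e-10


def test_s_curve_structure_reference_configuration():
    """At the no-stimulus preset the curve is S-shaped: stable nodes below,
    saddles in the middle, a subcritical Hopf splitting the upper branch."""
    branches = equilibrium_curve_direct(H0, P0)
    ids = {b.branch_id for b in branches}
    assert {"lower", "middle", "upper"} <= ids
    lower = next(b for b in branches if b.branch_id == "lower")
    middle = next(b for b in branches if b.branch_id == "middle")
    assert set(lower.stability) == {"stable_node"}
    assert set(middle.stability) == {"saddle"}
    hopfs = find_hopf(H0, P0)
    assert len(hopfs) == 1
    upper = next(b for b in branches if b.branch_id == "upper")
    assert "stable_focus" in upper.stability and "unstable_focus" in upper.stability


def test_continuation_matches_closed_form():
    """Pseudo-arclength path following reproduces the parametrized curve."""
    rng = np.random.default_rng(11)
    configs = [(H0, P0), (H30, P30)]
    for _ in range(8):
        configs.append((float(rng.uniform(0.03, 0.3)),
                        ModelParams(Iextz=float(rng.uniform(-2, 40)),
                                    k1=float(rng.uniform(0, 1.0)))))
    for h, p in configs:
        br = continue_equilibria(h, p)
        err = np.abs(br.gCANTot - gcan_of_V(br.V, h, p))
        assert br.V.size > 100
        assert float(err.max()) < 1e-8


def test_folds_have_zero_eigenvalue():
    for h, p in ((H0, P0), (H30, P30)):
        folds = find_folds(h, p)
        assert len(folds) == 2
        for f in folds:
            assert f.diagnostics["min_abs_eig"] < 1e-6


def test_fold_location_matches_snic_conductance():
    """The lower fold of the depolarized preset sits at the conductance
    where the spiking cycle disappears, ~0.0294."""
    folds = find_folds(H30, P30)
    assert min(f.gCANTot for f in folds if f.gCANTot > 0) == pytest.approx(
        0.0294, abs=1e-3)


def test_hopf_point_properties():
    hopfs = find_hopf(H0, P0)
    eigs = hopfs[0].diagnostics["eigenvalues"]
    pair = eigs[np.abs(eigs.imag) > 1e-9]
    assert pair.size == 2
    assert np.max(np.abs(pair.real)) < 1e-8
    assert np.min(np.abs(pair.imag)) > 0.01


def test_hopf_is_subcritical():
    hopfs = find_hopf(H0, P0)
    assert hopf_criticality(hopfs[0].V, H0, P0) == "subcritical"


def test_stability_changes_only_at_detected_points():
    """The number of unstable eigenvalues changes only at folds and Hopf
    points along the closed-form curve."""
    folds = find_folds(H0, P0)
    hopfs = find_hopf(H0, P0)
    special_V = sorted([q.V for q in folds] + [q.V for q in hopfs])
    Vs = np.linspace(-75.0, 5.0, 1500)
    from prebotc_memristor.fastslow import _eigs_at

    n_unst = np.array([int(np.sum(_eigs_at(v, H0, P0).real > 1e-9)) for v in Vs])
    jumps = Vs[:-1][np.diff(n_unst) != 0]
    for vj in jumps:
        assert min(abs(vj - vs) for vs in special_V) < 0.1


def test_cycle_branch_snic_termination(snic_branch):
    """The depolarized preset's cycle branch diverges in period and dies on
    the lower fold: a saddle-node on an invariant circle."""
    cb = snic_branch
    assert cb.termination in ("period_blowup", "cycle_vanished")
    assert cb.period[-1] > 1000.0
    folds = find_folds(H30, P30)
    term = classify_cycle_termination(cb, folds)
    assert term.type == "snic"
    assert term.gCANTot == pytest.approx(0.0294, abs=1e-3)
    # period diverges monotonically into the termination
    assert np.all(np.diff(cb.period[-5:]) > 0)


def test_trivial_floquet_multiplier(snic_branch):
    """One Floquet multiplier equals +1 (flow direction) at every branch
    point with a resolvable period."""
    for T, mult in zip(snic_branch.period, snic_branch.multipliers):
        if T < 2000.0:
            assert np.min(np.abs(mult - 1.0)) < 1e-3


def test_cycle_branch_homoclinic_termination():
    """The no-stimulus preset's cycle dies at finite period away from any
    fold: a homoclinic collision with the middle-branch saddle."""
    found = find_stable_cycle(0.21, H0, P0)
    cb = continue_cycles(0.21, H0, P0, direction=-1.0, start_point=found,
                         g_stop=-0.05)
    term = classify_cycle_termination(cb, find_folds(H0, P0))
    assert term.type == "hc"
    assert cb.period[-1] < 5000.0
    folds_g = [f.gCANTot for f in find_folds(H0, P0)]
    assert min(abs(term.gCANTot - g) for g in folds_g) > SNIC_TOL
    # the dying cycle's minimum approaches the middle (saddle) branch
    from prebotc_memristor.fastslow import _eigs_at

    assert cb.Vmin[-1] > -50.0


def test_lpc_above_subcritical_hopf():
    """Marching the stable cycle upward ends at the fold of cycles, beyond
    the subcritical Hopf."""
    found = find_stable_cycle(0.15, H30, P30)
    up = continue_cycles(0.15, H30, P30, direction=+1.0, start_point=found,
                         g_stop=0.6)
    assert up.termination == "lpc"
    g_hopf = find_hopf(H30, P30)[0].gCANTot
    assert up.g_term > g_hopf


def test_label_not_bursting():
    import numpy as np

    from prebotc_memristor.fastslow import bifurcation_diagram

    from conftest import synthetic_trajectory

    diag = bifurcation_diagram(H0, P0)
    t = np.linspace(0, 5000, 5001)
    flat = synthetic_trajectory(t, np.full_like(t, -60.0))
    assert label_bursting(diag, flat) == "not bursting"
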