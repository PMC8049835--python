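"""Named experiment configurations and small analytic test systems.

All model inputs are parameters, so the "data generator" of the pipeline is
the catalogue of stimulation configurations the analyses run on: the
no-stimulus reference, the applied-current series, the induction-gain
series, the preset frozen-h values used by the fast-slow decomposition, and
the sweep grids used by the ISI diagrams.  Expected-outcome fields carry
qualitative labels only (pattern class, burst type, bifurcation sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams
from .simulate import SimConfig

__all__ = [
    "Scenario",
    "paper_scenarios",
    "toy_scenarios",
    "get_scenario",
    "H_PRESETS",
    "SWEEP_GRIDS",
    "cubic_fold_rhs",
    "hopf_normal_form_rhs",
]

# frozen-h presets of the fast-slow analyses: (Iextz, k1) -> burst-average h
H_PRESETS: dict[tuple[float, float], float] = {
    (0.0, 0.0): 0.2834,
    (-2.0, 0.1): 0.2788,
    (5.0, 0.1): 0.2375,
    (25.0, 0.1): 0.1288,
    (30.0, 0.1): 0.0986,
    (40.0, 0.1): 0.0490,
    (50.0, 0.1): 0.0307,
}

# default sweep grids bracketing every reported regime boundary
SWEEP_GRIDS: dict[str, np.ndarray] = {
    "Iextz": np.arange(-5.0, 55.0 + 1e-9, 0.5),
    "k1": np.arange(0.0, 2.0 + 1e-9, 0.01),
    "alpha": np.linspace(0.5, 3.0, 26),
    "beta": np.geomspace(6e-6, 6e-4, 25),
}


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ModelParams
    sim: SimConfig
    expected: dict = field(default_factory=dict)


def _mk(name: str, expected: dict, t_end: float = 60000.0,
        transient: float = 20000.0, **par) -> Scenario:
    p = ModelParams(**par)
    return Scenario(name, p, SimConfig(params=p, t_end=t_end, transient=transient),
                    expected)


def paper_scenarios() -> list[Scenario]:
    """Every named configuration the analyses use."""
    out = [
        _mk("fig2", {"pattern": "bursting_low_quiescence",
                     "burst_type": "subHopf/homoclinic via fold/homoclinic",
                     "sequence": ["fold", "fold", "hopf_sub", "lpc", "hc"],
                     "h_preset": 0.2834},
            Iextz=0.0, k1=0.0),
    ]
    fig3 = {"a": -2.0, "b": 5.0, "c": 25.0, "d": 30.0, "e": 40.0, "f": 50.0}
    expect3 = {
        "a": {"pattern": "bursting_low_quiescence", "h_preset": 0.2788,
              "burst_type": "subHopf/homoclinic via fold/homoclinic"},
        "b": {"pattern": "bursting_low_quiescence", "h_preset": 0.2375,
              "burst_type": "subHopf/homoclinic via fold/homoclinic"},
        "c": {"pattern": "bursting_low_quiescence", "h_preset": 0.1288,
              "burst_type": "subHopf/fold cycle via fold/circle"},
        "d": {"pattern": "bursting_low_quiescence", "h_preset": 0.0986,
              "burst_type": "subHopf/fold cycle via fold/circle"},
        "e": {"pattern": "continuous_spiking", "h_preset": 0.0490,
              "burst_type": "subHopf/fold cycle"},
        "f": {"pattern": "bursting_high_quiescence", "h_preset": 0.0307,
              "burst_type": "subHopf/fold cycle"},
    }
    for key, I in fig3.items():
        out.append(_mk(f"fig3{key}", expect3[key], Iextz=I, k1=0.1))
    for key, k1 in zip("abcd", (0.1, 0.8, 1.0, 1.5)):
        pattern = ("bursting_low_quiescence" if k1 < 0.88
                   else "continuous_spiking" if k1 < 1.25
                   else "bursting_high_quiescence")
        out.append(_mk(f"fig8{key}", {"pattern": pattern}, Iextz=0.0, k1=k1))
    for pname in SWEEP_GRIDS:
        out.append(_mk(f"sweep_{pname}",
                       {"sweep_param": pname,
                        "grid": SWEEP_GRIDS[pname].tolist()},
                       k1=0.1 if pname == "Iextz" else 0.0))
    return out


def toy_scenarios() -> list[Scenario]:
    """Shortened runs for fast tests (attractor reached, few cycles kept)."""
    out = []
    for s in paper_scenarios():
        if s.expected.get("sweep_param"):
            continue
        out.append(Scenario(f"{s.name}_toy", s.params,
                            s.sim.with_(t_end=5000.0, transient=0.0),
                            {**s.expected, "toy": True}))
    return out


def get_scenario(name: str) -> Scenario:
    for s in paper_scenarios() + toy_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}")


# --------------------------------------------------------------------------
# analytic test systems for the continuation machinery
# --------------------------------------------------------------------------

def cubic_fold_rhs(x: float, mu: float) -> float:
    """dx/dt = mu + 3x - x^3: folds at x = +/-1 (mu = -/+2)."""
    return mu + 3.0 * x - x**3


def hopf_normal_form_rhs(y: np.ndarray, mu: float, omega: float = 1.0,
                         a: float = -1.0, lam: float = -2.0) -> np.ndarray:
    """Hopf normal form embedded in 3-D: Hopf at mu = 0.

    dr/dt = mu*r + a*r^3 in (y0, y1), third component contracting with rate
    lam; a < 0 gives a supercritical, a > 0 a subcritical bifurcation.
    """
    x, yv, z = y
    r2 = x * x + yv * yv
    return np.array([mu * x - omega * yv + a * x * r2,
                     omega * x + mu * yv + a * yv * r2,
                     lam * z])
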