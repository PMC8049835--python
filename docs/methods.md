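# Methods

## Model

The membrane model is a single-compartment pre-BötC pacemaker in the Butera
tradition. The voltage equation balances a fast sodium current
I_Na = g_Na m∞³(V)(1−n)(V−V_Na) (activation instantaneous, inactivation
slaved to the K-gate as 1−n), a delayed rectifier I_K = g_K n⁴(V−V_K), a
leak, a persistent sodium current I_NaP = g_NaP mp∞(V) h (V−V_Na) with a
very slow inactivation gate h (τ̄_h = 10⁴ ms), an excitatory tonic drive,
and a calcium-activated nonspecific cationic current
I_CAN = g_CAN f([Ca]) (V−V_Na) with Hill activation
f([Ca]) = 1/(1+(K_CAN/[Ca])^n_CAN). Gating steady states are sigmoids
x∞(V) = 1/(1+exp((V−θ_x)/σ_x)) and voltage-dependent time constants are
τ_x(V) = τ̄_x / cosh((V−θ_x)/(2σ_x)).

Electromagnetic induction enters as a magnetic-flux state φ with
dφ/dt = V − k2 φ and an induced current k1·V·ρ(φ) subtracted from the
membrane balance, where ρ(φ) = α + 3βφ² is the memductance of a
flux-controlled memristor. Setting k1 = 0 and I_extz = 0 recovers the
unstimulated model.

Calcium dynamics follow the single-compartment ER model:
J_ER_IN = (L_IP3 + P_IP3 ([IP3][Ca]l / (([IP3]+K_I)([Ca]+K_a)))³)([Ca]_ER −
[Ca]) with [Ca]_ER = ([Ca]_Tot − [Ca])/σ, J_ER_OUT = V_SERCA [Ca]²/(K_SERCA²
+ [Ca]²), d[Ca]/dt = K_Ca (J_ER_IN − J_ER_OUT) and the IP3-channel
availability l with dl/dt = A K_d (1−l) − A [Ca] l. The ([Ca], l) pair is
exactly decoupled from the electrical variables: it is the pacemaker that
periodically drives gCANTot(t) = g_CAN f([Ca](t)).

All parameter defaults are the reference set of the model (`ModelParams`);
the printed constants are used verbatim in the nS/mV/ms convention (C = 21
divides the current sum directly; the flux constants L_IP3, P_IP3, V_SERCA
and the rate A are used numerically as printed with time in ms). At the
reference [IP3] = 1.2 μM the calcium subsystem oscillates (active window
roughly [1.0, 1.4] μM under these flux forms; `ip3_activity_scan` reports
the endpoints it finds).

## Timescales

Rescaling by Q_v = Q_φ = 100 mV, Q_c = 1 μM, Q_t = 1 ms bounds every
right-hand side by one and leaves rate coefficients R_v = C/(Q_t g_max),
R_n = 1/(Q_t T_n), R_h = 1/(Q_t T_h), R_φ = 1/Q_t, R_c = σ/(Q_t P_max K_Ca),
R_l = 1/(Q_t Q_c A), with g_max = 50 (dominated by the largest applied
current considered), T_x = max 1/τ_x over V ∈ [−60, 0] mV, G_c = max G³,
G_S = max V_SERCA[Ca]/(K_SERCA²+[Ca]²) = V_SERCA/(2K_SERCA) = 1000, and
P_max = max{L_IP3, P_IP3 G_c, G_S}. A variable is fast / slow / super-slow
when the nearest integer to log10 R is ≤0 / 1 / ≥2 (ties rounded away from
zero). The reference gate-rate constants (T_n = 1.3, T_h = 0.0025 ms⁻¹) are
figure-derived; the cosh form reproduces T_h but gives T_n ≈ 2.4. The
report exposes both and uses the reference constants for the R values —
the classification is insensitive to the choice. G_c is rounded to two
decimals (0.06) before forming P_max, matching the order-of-magnitude
character of the scale analysis; the unrounded value is also reported.

## Simulation

All integration uses LSODA (stiffness-switching, adaptive) driving
numba-compiled vector fields; solutions are kept at the accepted steps,
which error control makes dense during spikes. Defaults: rtol 1e-8,
atol 1e-10, max_step 1 ms. A max_step of 1 ms resolves spike peaks because
the controller shrinks steps well below it during spikes; refining the
tolerances changes the spike count by at most one and the ISI multiset at
the sub-percent level except for the one interval spanning the
small-amplitude passage (see Limitations). Initial conditions are not part
of the modelled experiments — only attractors are analysed — so a fixed
default inside the bursting basin is used, (V, n, h, φ, [Ca], l) =
(−60, 0.01, 0.45, −20, 0.03, 0.93), and 20 s of model time are discarded.

Burst cycles are delimited by resting stages (low-potential quiescent spans,
or depolarized rests in high-current regimes) rather than by raw inter-spike
gaps, because the small-amplitude mid-burst passage is spike-free under any
reasonable prominence threshold and would otherwise split a cycle. The
burst-average h̄ is the trapezoidal mean over an integer number of cycles.

## Pattern classifier (operational conventions)

Spikes are local V maxima above −35 mV with ≥5 mV prominence,
parabola-refined. The four burst phases are: ① the low-potential resting
stage (the whole inter-spike gap, flanks trimmed, mean V below the −35 mV
ceiling, ≥100 ms), ② spiking with decreasing envelope down to the first
small-amplitude spike (peak-to-trough < 15 mV), ③ the small-amplitude run,
④ the regrowing run to the burst's end. Labels: a quiescent span present →
`bursting_low_quiescence`; a *flat* depolarized rest present (rolling 30-ms
peak-to-peak < 1 mV sustained ≥300 ms, mean V > −35 mV) →
`bursting_high_quiescence`; spikes but neither → `continuous_spiking`; no
spikes → `quiescent`.

Two conventions deserve justification. The −35 mV quiescence ceiling is the
natural separatrix of this model: across all regimes the lower-branch rest
sits below −40 mV and the depolarized focus above −27 mV, so any ceiling in
between gives the same verdicts (a much lower ceiling would miss the lower
rest entirely at high currents, where it sits near −41 mV). The flatness
requirement on the depolarized rest exists because phase-③ oscillations
(1–5 mV) produce no prominence-5 spikes either; "resting" is therefore
defined as visually flat (< 1 mV) rather than merely spike-free.

## Fast-slow decomposition

With h frozen at h̄ and gCANTot as parameter, the fast subsystem's
equilibria satisfy n = n∞(V), φ = V/k2 and a closed-form
gCANTot(V) = [−ΣI(V) + I_extz − k1 V ρ(V/k2)]/(V − V_Na): the S-curve is
exact, folds are roots of dgCANTot/dV (each verified by a zero eigenvalue of
the 3×3 Jacobian), and Hopf points are sign changes of the complex pair's
real part along the curve, with sub/supercriticality decided by a
perturbation-threshold probe on the stable-focus side. An independent
pseudo-arclength continuation cross-validates the closed form (agreement
≲1e-12 in gCANTot).

The attracting cycle branch is continued by settling integration with warm
starts: at each parameter the orbit is settled, anchored on a Poincaré
section (upward V-crossing) by event integration to solver precision, and
polished by a single-shooting Newton where that converges; Floquet
multipliers come from integrating the variational equations with the
analytic Jacobian. Settling-based marching was chosen over pure shooting
because these relaxation cycles are so strongly contracting that
finite-difference shooting Jacobians lose rank in noise; the repelling
cycle born at the subcritical Hopf, which cannot be settled onto, is
continued by shooting alone (mild instability near the Hopf keeps Newton
healthy).

Marching down, a SNIC announces itself by a period diverging like
(g−g*)^(−1/2) — the 2·10⁴ ms period ceiling is actually reached — and by
the termination parameter landing on a fold of equilibria (tolerance 1e-3
in gCANTot); a homoclinic approach is only logarithmic in the period, so
the branch instead stalls at finite period away from any fold. Marching up
ends at the fold of cycles (LPC) when the step collapses; the last
nontrivial multiplier sits near +1 there.

Burst labels follow the Izhikevich naming: the quiescent phase is always
lost through the subcritical Hopf passage (the trajectory spirals into and
out of the focus); the spiking phase dies at the cycle termination
("homoclinic" for HC, "fold cycle" for the LPC-born branch ending in a
SNIC); when the full trajectory actually rests on the lower branch the
"via fold/…" hysteresis pair is appended.

## Two-parameter analysis

Because the closed form is available at every h, the fold and Hopf curves
in the (gCANTot, h) plane are assembled by per-h scanning (each point
re-verified by an independent eigen-decomposition) instead of bordered
codim-2 continuation. The fold-of-cycles and homoclinic curves are per-h
cycle-branch terminations on a coarse h-grid; the homoclinic curve is an
explicit period-ceiling approximation and is flagged approximate. Full
trajectories project into the plane as (g_CAN f([Ca](t)), h(t)); crossing
diagnostics interpolate each curve at the trajectory's h and report signed
crossings.

## Calcium subsystem

The Ca-nullcline solves d[Ca]/dt = 0 for l in closed form; the l-nullcline
is l = K_d/(K_d+[Ca]). The relaxation orbit is integrated at rtol 1e-11 and
cut on a transversal section (upward mid-range Ca crossing), with closure
verified to 1e-6 relative. Marker P1 is the jump-up (maximal d[Ca]/dt);
marker P2 is the downward crossing of [Ca]_SNIC obtained by the exact Hill
inversion [Ca] = K_CAN/(g_CAN/gCANTot − 1)^(1/n_CAN). The orbit's period
equals the full system's burst period (they are the same oscillator); the
P2→P1 stretch only brackets the observed quiescent span from above, because
spiking outlives the [Ca]_SNIC crossing by a slow-passage delay (measured
~20–30% of the rest duration at I_extz = 30).

## Problem sizes

Default analyses use 60 s of model time per simulation (20 s transient),
equilibrium grids of ~3000 points, cycle branches of 50–300 points, and
regime sweeps at the stated resolutions (0.5 in I_extz, 0.01 in k1,
refined to 0.1 near the depolarized-rest onset); these sizes put every
reported quantity well inside its quoted tolerance while keeping the full
pipeline at desk scale (minutes on one core).

## Limitations

- The gate/time-constant/flux expressions use the standard Butera- and
  ER-model forms; the burst-average h̄ values they produce match the
  reference decomposition constants to ~4 decimals in the stimulated
  regimes, but the unstimulated case gives h̄ = 0.2922 against the
  reference 0.2834 — inside the quoted ±0.01 band yet the largest
  deviation, suggesting a minor difference in that configuration's
  averaging convention.
- The onset of the depolarized rest is a smooth crossover here, not a sharp
  transition: the phase-③ oscillation envelope decays continuously with
  I_extz and k1 (minimum rolling amplitude 0.4 mV at I_extz = 40 falling to
  0.05 mV at 48), so the located onset depends on the flatness floor; with
  the declared 1 mV / 300 ms convention it sits near I_extz ≈ 44–46 and
  k1 ≈ 1.25, below the reference readings 47.7 and 1.33. No convention was
  chosen to match those readings.
- One ISI per burst — the interval spanning the small-amplitude passage —
  is exponentially sensitive (slow passage) and converges only to ~2–3%
  under tolerance halving; all other intervals converge below 0.1%.
- The trivial Floquet multiplier is reproduced to <1e-3 for periods up to
  ~2000 ms; at near-degenerate branch ends (period >5000 ms, about to
  collide with the saddle-node) it degrades to ~1e-2.
- The homoclinic two-parameter curve is a period-ceiling contour, not a
  boundary-value continuation; HC locations are accurate only to the width
  of the logarithmic period ramp (~1e-3 in gCANTot).
- No network coupling, noise, or two-compartment dendritic mechanism is
  modelled; the charge variable associated with the induced current is
  omitted as it feeds back on nothing.
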