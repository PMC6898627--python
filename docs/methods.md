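# Methods

## The physical system

The simulated apparatus deposits respirable-size drug particles onto a thin
film of mucus simulant (1.5% w/v polyethylene oxide in PBS) spread over a
hydrated dialysis membrane. Buffer is pumped past the far side of the
membrane and collected continuously. Four mass stocks describe the drug:
solid particles suspended in the film, drug dissolved in the film, drug in
the perfused receiver, and drug in the collection tube. All internal units
are cm–g–min; user-facing configuration accepts µL, µm, µg, mg mL⁻¹ and
mL min⁻¹, converted exactly once at the boundary.

## Kinetic laws and assumptions

**Dissolution.** Noyes–Whitney with the composite rate constant
k = IDR / C_s (cm min⁻¹), where the intrinsic dissolution rate is measured
on a compacted disc. Particles are assumed smooth, spherical, monodisperse
and shrinking uniformly at fixed particle count N = 6M₀/(π d₀³ ρ), giving
d_t = (M_t d₀³/M₀)^⅓ and S_t = S₀ (M_t/M₀)^⅔ with S₀ = 6M₀/(ρ d₀).
The driving force (C_s − C) is clamped at zero: precipitation is out of
scope, so a saturated or supersaturated film stops dissolving but never
nucleates solid.

**Permeation.** Flux = P S (C_mucus − C_perfusate), signed (back-flux is
admissible though it does not arise in the shipped scenarios). No
partitioning is assumed (aqueous pathways throughout, K = 1), so the
diffusion coefficient and barrier thickness only ever appear as the
composites k and P_exp = D/h_exp. The experimental permeability is rescaled
to the modelled barrier:

* well-stirred donor: P = P_exp h_exp / h_m, constant;
* unstirred donor: a depletion zone of thickness h_d = f_d·h_t accrues next
  to the membrane, P_t = P_exp h_exp / (h_m + f_d h_t).

The depletion fraction f_d counts everything that has left the film —
receiver **plus** collected mass — because drug swept into the collection
tube has equally vacated the donor. The same formula is applied when
undissolved solid is still present (the suspension and solution variants
share the permeability wiring). Unstirred water layers on either side of the
membrane are not modelled; a fitted h_exp larger than the measured membrane
thickness is the interpretive signature of such a layer.

**Receiver and collection.** The receiver is an ideally mixed, constant
volume (default 500 µL) compartment; its outflow concentration equals its
bulk concentration, so the collection rate is C_perfusate·Q. Thinning of the
receptor-side boundary layer at high flow is deliberately excluded.

**Dose forms.** `particles` starts the full dose as solid; `solution` starts
the full dose dissolved *regardless of solubility* (a 50 µg ethionamide dose
in 25 µL is 2 mg/mL against a 0.46 mg/mL solubility — the pre-dissolved
scenario is a supersaturated idealization, and the C ≤ C_s invariant is
asserted only for particle doses).

## Numerics

Fixed-step integration: classical RK4 (default) or forward Euler, default
dt = 0.01 min, horizon 120 min, states stored every 1 min plus the final
step. Fixed stepping keeps the output grid exactly reproducible and mirrors
graphical stock-and-flow tools, whose solvers are Euler or Runge–Kutta at a
user-chosen dt; convergence is asserted in the tests by step-halving against
an independent naive-Euler oracle (agreement within 0.1% of dose) and
against the closed-form sink solution M₀e^(−P S t/V_d) (within 0.1%
relative).

Overshoot protection, in two layers:

1. *Within-step flux limiting*: the dissolution rate is capped at
   (remaining solid)/dt at every stage evaluation. Without this, RK4 stages
   overshoot the solid stock whenever dissolution is much faster than dt
   (e.g. in the fast-dissolution limit used to verify that suspensions of a
   freely soluble drug converge to the pre-dissolved run).
2. *Post-step clamping*: any stock driven marginally below zero is zeroed
   and the deficit handed to the downstream stock, preserving the mass
   balance exactly. A deficit reaching the terminal (collection) stock, or
   any non-finite state, aborts with an integration error naming the step —
   it means dt cannot resolve the kinetics, and silently repairing it would
   corrupt the mass balance.

Mass conservation holds to ≤ 10⁻⁶·M₀ at every stored point (in practice
~10⁻¹⁵ relative, the rounding floor). `time_to_fraction` interpolates
linearly between stored points and returns `None` when the horizon ends
before the threshold ("not reached").

## Sensitivity sweeps

One-at-a-time sweeps over mucus volume (h_t = V_d/S follows the volume),
perfusate flow, h_exp (enters only via the permeability rescaling) and h_m.
Default checkpoints 15/30/60/120 min; the profile figures the sweeps emulate
carry no printed numbers, so the sweeps report per-checkpoint orderings from
strict comparisons plus the maximum spread, and "no material effect" (the
flow-rate verdict) is operationalized as a spread below 5% of dose at every
checkpoint via `SweepResult.is_flat(tol=5.0)`.

## Permeability estimation

OLS of ln C_d on t; P̂ = −slope·V_d/S, Ĉ_d0 = exp(intercept). The fit
window includes points while the cumulative permeated fraction 1 − C/C(0)
stays ≤ 80% (configurable): the late tail is systematically sub-exponential
(receiver back-pressure, donor depletion) and biases the slope. Non-positive
concentrations inside the window are excluded with a warning; fewer than 3
usable points (relaxable to 2, which determines the line exactly) is an
error. The estimator is invariant to concentration scaling and to consistent
time-unit changes; the round-trip test (simulate a pre-dissolved,
well-stirred run with strong sweep flow, then re-fit) recovers the input
P_exp within 2%, the residual being genuine receiver back-pressure rather
than estimator bias.

## Synthetic fixtures

`generate_fixture` emulates the donor-side observable of a clean permeation
assay: exponential decay from 2 mg/mL in the shipped apparatus (4.91 cm²,
25 µL), multiplied by seeded log-normal noise so the log-scale regression
sees additive Gaussian errors. It does **not** emulate the features that
make real assays hard — sampling-induced volume loss, assay LOQ censoring,
membrane fouling, the sub-exponential late tail — so fixture-based recovery
tests demonstrate estimator correctness, not robustness to those artifacts
(the round-trip test covers the back-pressure deviation).

## Problem sizes and defaults

Shipped scenario defaults are the bench values: 50 µg dose, 25 µL film over
4.91 cm² (50.9 µm), 62.5 µm hydrated membrane (h_exp = h_m), 500 µL
receiver, 0.4 mL/min flow; drug constants as in the preset files. The
acceptance script integrates at dt = 0.01 min over 150 min (ethionamide) and
200 min (moxifloxacin) horizons — 15 000 and 20 000 RK4 steps, well under a
second each. The test suite shortens exploratory runs to dt = 0.02–0.05 min
and ≤ 120 min horizons, which step-halving shows leaves every asserted
ordering and tolerance unchanged.

## Known limitations

Monodisperse spheres only (real milled powders are broken, non-spherical,
1.5–8 µm distributions — the main cause of divergence from bench data for
slowly dissolving drugs); no precipitation; no mucus rheology or spatially
resolved diffusion through the film (the depletion zone is a lumped
approximation); no pH-dependent solubility; no mucociliary clearance or
epithelial metabolism; receiver-side boundary-layer thinning with flow is
excluded by design.
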