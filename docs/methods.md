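# Methods

This note records the modelling conventions, numerical choices and design
decisions behind `vcdesign`, and what the shipped tests do and do not
demonstrate.

## Gating models and units

Both shipped models are continuous-time Markov chains x' = A(V)x whose
off-diagonal entries are voltage-dependent transition rates of Eyring form
r(V) = r₀·exp(±sV). Column sums of A are zero, so total state occupancy is
conserved; the test suite asserts |Σx − 1| < 10⁻⁸ on every simulation.

Units are fixed throughout: time in ms, voltage in mV, rates in ms⁻¹,
voltage slopes in mV⁻¹, conductance in µS, current in nA (µS·mV). The
built-in parameter tables store values on this natural scale; the
delimited-text parameter reader/writer preserves them bit-for-bit.
Defaults are room-temperature parameterisations; no temperature dependence
is modelled.

The current equation is not part of either model's published description;
we adopt the standard ohmic form I = g·P(open)·(V − E_rev). E_rev defaults
to −88.0 mV, a room-temperature K⁺ Nernst-style value for typical
physiological solutions, and is a one-argument override on every API that
computes current.

The 4-state model factorises exactly into two independent Hodgkin–Huxley
gates (activation a, inactivation/recovery r; P(O) = a·r). We exploit this
three ways: (i) as an independent correctness oracle (Markov vs two-gate
open probability agrees < 10⁻⁶ on the staircase fixture), (ii) as the
coordinate system of the phase-voltage space, and (iii) as a fast analytic
solver — on a constant-voltage step both gates relax mono-exponentially in
closed form, which makes the thousands of trajectory evaluations inside
design loops cheap. This is a performance device, not an approximation:
steps are solved exactly in both formulations.

## Solvers

Three routes, cross-checked against each other in the tests:

* **propagator** (default): constant-voltage segments advanced by the exact
  linear propagator via eigendecomposition of A(V) (matrix-exponential
  fallback if the eigenbasis is ill-conditioned, cond > 10¹⁰); ramps by
  adaptive LSODA with rtol 10⁻⁸/atol 10⁻¹⁰ and a BDF retry for extremely
  stiff parameter draws. Bit-deterministic and output-grid independent
  (halving the sampling interval leaves shared samples unchanged).
* **adaptive**: every segment integrated with `solve_ivp`, on the full
  system or with the last state eliminated as one minus the sum of the
  rest. Propagator-vs-adaptive agreement < 10⁻⁶ and full-vs-reduced
  < 10⁻⁸ are asserted.
* **analytic two-gate** route for the 4-state model (above).

Segments are half-open in time: a sample on a boundary belongs to the next
segment. Output sampling defaults to 1 ms everywhere; objective integrals
use the rectangle rule on that grid. Whether design objectives should be
integrated on a uniform grid or on solver-native steps is genuinely open;
uniform 1 ms was chosen to match the sampling used in the original design
runs and to keep objective costs predictable.

Initial conditions default to the steady state at the −80 mV holding
potential, computed from the null space of A (SVD; a reducible chain or a
negative occupancy raises instead of returning NaN). Design objectives
always simulate candidate units with the common head (and all previously
accepted units) attached, so each unit is scored from the realistic
post-head state rather than from equilibrium.

## Protocols

Protocols are ordered lists of steps and linear ramps, read and written as
tab-separated text with a 0.1 ms / 0.1 mV practical resolution (round
trips are exact). The common head (7 commands, 3400 ms: leak ramp and a
large activation step) and tail (6 commands, 2500 ms: reversal ramp
sequence and a closing −120 mV step) wrap every designed body; hardware
export refuses protocols over 64 commands.

The square-wave family V(t) = b + Σᵢ aᵢ·sign(sin(ωᵢt + φᵢ)) (sign(0) = 0)
is converted exactly to a step list by enumerating all component
zero-crossings; the step list equals the closed form everywhere except the
measure-zero switching instants. The published component set (54/26/10 mV,
0.007/0.037/0.19 rad ms⁻¹, zero phases, −30 mV offset) ships as a fixture.
Two published details are resolved here: the frequency unit is printed as
"ms" and is interpreted as rad·ms⁻¹ (a units typo), and the body duration
is not printed, so the fixture defaults to 680 ms — the longest duration
whose conversion (51 steps) still fits the 64-command budget with head and
tail attached.

The manual staircase-family protocols are defined only in a supplementary
spreadsheet; rather than silently depending on a download, the repo ships
a clearly-labelled approximate `staircase_like` fixture (500 ms ladder
steps, −120 to +40 mV and back) for solver cross-checks and recovery
exercises.

## Design objectives

* **Local sensitivity** (per parameter i): central differences with
  δ = 0.1% of each parameter, each perturbed run re-equilibrated at the
  holding potential (as a real experiment would be). The score is the
  share ∫|∂I/∂pᵢ·pᵢ|dt / Σ_k ∫|∂I/∂p_k·p_k|dt integrated over the unit's
  *third* step only — the first two steps are free to prime the channel.
  Shares over a common window sum to one by construction (asserted).
* **Sobol**: first-order indices Var(E(I|pᵢ))/Var(I) via the Saltelli
  estimator on scrambled Sobol' sequences, over the fitted parameter
  ranges. Several ranges span up to five decades, so draws are log-uniform
  by default (linear available). The per-time-point index is averaged over
  the third-step window and clipped to [0,1]; the published formulation
  has no explicit time aggregation, so the time-average mirrors the
  local-sensitivity window. The estimator is validated against the
  closed-form indices of a linear test function (within 0.02 at base
  sample 4096) before being trusted in design.
* **Sampled-parameter spread**: (2/M²)·Σ_{j<k} RMSD(I_j, I_k) over M
  draws from the prior (default M = 100, log-uniform over the fitted
  ranges), computed over all three steps of the unit. Computed with a Gram
  matrix trick, so the M² pair cost is negligible.
* **Two-model discrimination**: RMSD between the two models' currents at
  their default parameters (a local design in parameter space), over all
  three steps. The comparison window for this and the spread objective is
  configurable; only the sensitivity objectives restrict scoring to the
  third step by definition.
* **Phase-voltage coverage**: the (a, r, V) trajectory sampled at 1 ms is
  binned into a 6×6×6 grid over [0,1]×[0,1]×[−120,60] (216 boxes,
  half-open bins, closed top edge; out-of-range samples are clamped into
  edge bins with a warning). The unit score is the number of boxes not
  visited by the head or any earlier unit, so cumulative coverage is
  non-decreasing and the sum of unit scores equals the recount on the
  exported protocol (asserted). Reported coverage counts include the head
  and tail trajectory — coverage is a property of the full applied
  waveform.

## Designers

Units are optimised sequentially by a compact (µ/µ_w, λ) CMA-ES
(standard rank-µ update and cumulative step-size adaptation, written
in-repo and validated on analytic optima) in a [0,1]-normalised box with
σ₀ = 1/6 of each range, box constraints by clipping, and restarts from
uniform random starts (default 10; the restart-start distribution is not
specified in the published description, so uniform-over-bounds was
chosen). Each restart's winner is rounded to 0.1 ms/0.1 mV and re-scored
*before* winners are compared, so the reported score is the score of the
shipped protocol; restart ties break by index. Gibbs variants draw the
frozen triple (Δt ~ U(50, 1000) ms, or U(50, 500) ms for the
randomised-time discrimination design; V ~ U(−120, 60) mV) once per unit,
rounded to the same resolution. Free durations use [50, 1000] ms bounds
(unspecified in the published description; matched to the Gibbs draw
range).

For per-parameter objectives the number of units equals the number of
kinetic parameters (8 or 14; the conductance can be included via a flag
but is excluded by default, since the sensitivity of the current to g is
trivially the current itself). For all other objectives N = 17, giving a
51-step body and 64 commands with head and tail.

The space-filling selection runs the designer for several seeds and ranks
runs by (1) coverage, (2) two-model current RMSD, and (3) the
sampled-parameter spread score, ties broken by run index. The square-wave
designer optimises 3 amplitudes, 3 angular frequencies and 3 phases with
the offset fixed at −30 mV; per-component amplitudes are capped at 30 mV
so the waveform cannot leave the [−120, 60] mV hardware window. When the
optimum lands on a parameter bound a warning flags the design as likely
impractical (very high-frequency, high-amplitude switching) — which is in
fact what happens for the two shipped models with default bounds.

Every designer is reproducible from its configuration seed: the frozen
draws, CMA-ES sampling and restart starts all consume one seeded
generator.

## Problem sizes

Default test and reproduction scales are chosen to keep a full run on one
CPU in minutes: the space-filling reproduction uses 5 seeds × 17 units ×
2 restarts of ≤ 60 CMA-ES iterations (population 10). At this scale the
best run visits ~190 of 216 boxes, comfortably above the 126-box coverage
that full-scale design runs are expected to reach; more restarts raise
per-run coverage slightly but do not change the qualitative picture.
Design-time Sobol objectives default to base sample 64 (the estimator
oracle test uses 4096).

## Synthetic data and fitting

Synthetic observations add iid Gaussian noise (default σ = 0.05 nA, a
typical RMS noise level for automated patch recordings at ~1 kHz) to a
simulated current, storing the generating parameters alongside. Real
recordings differ in ways this generator deliberately ignores: leak and
series-resistance artefacts, amplifier filtering, temporally correlated
noise and cell-to-cell variability. Passing recovery tests therefore shows
the estimator machinery is correct and well-conditioned on these
protocols, not that real-data fits will achieve similar accuracy.

Fitting minimises current RMSD over log-parameters (CMA-ES stage within a
±1 natural-log-unit box around the initial guess, then a
Levenberg-Marquardt polish). With noiseless synthetic data the generating
kinetics are recovered to ~10⁻⁹ relative; at the default noise level
recovery stays within a few percent on the staircase-like fixture. A
closed-form conductance-only fit is provided for the g-linear case.
Unsimulable parameter draws during search score a large penalty rather
than aborting.

## Known limitations

* Joint optimisation of all steps at once is out of scope (units are
  greedy-sequential by design); so are second/total-order Sobol indices
  and Fisher-information criteria.
* No drug binding, temperature dependence, or experimental-artefact
  modelling; single-channel stochasticity is not simulated.
* The `staircase_like` fixture approximates the manual staircase protocols
  (exact tables live in an external spreadsheet); results derived from it
  are representative, not row-exact.
* The 5-state model has no closed-form fast path, so design loops using it
  are slower (per-voltage eigendecomposition caching mitigates this for
  step-only candidates).
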