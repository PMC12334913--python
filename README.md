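# vcdesign

Model-driven design of voltage-clamp protocols for hERG (K<sub>v</sub>11.1)
channel kinetics.

Characterising how an ion channel gates means recording its current under a
voltage waveform that actually exercises the gating processes — activation,
deactivation, inactivation and recovery — rather than holding them at
equilibrium. `vcdesign` is a toolkit for researchers who fit Markov models
of hERG gating to patch-clamp data and want short, information-rich
protocols that (a) make model parameters identifiable, (b) separate
competing candidate models, and (c) fit the constraints of automated patch
platforms, which typically accept at most 64 step/ramp commands per
protocol.

## Models

Two continuous-time Markov gating models are built in, each a linear ODE
system x' = A(V) x with exponential voltage-dependent rates
r(V) = r₀·e^(±sV):

* a **4-state model** (states C, I, IC, O) that is exactly equivalent to a
  two-gate Hodgkin–Huxley scheme — an activation gate *a* with
  da/dt = k₁(1−a) − k₂a and an inactivation/recovery gate *r* with
  dr/dt = k₄(1−r) − k₃r, open probability P(O) = a·r;
* a **5-state model** (C1–C2–C3–O–I) with sequential closed states and one
  voltage-independent transition pair.

Current follows the ohmic convention I = g·P(O)·(V − E_rev) with g in µS,
V in mV (so I is in nA) and E_rev = −88 mV by default. Constant-voltage
steps are solved with the exact linear-ODE propagator (or the closed-form
gate relaxation for the 4-state model); ramps use adaptive integration.

## Design objectives

Designed protocols are built from *N* units of three voltage steps, each
unit optimised by CMA-ES (with restarts, and results rounded to the
0.1 ms/0.1 mV hardware resolution) against one of:

| objective | what it maximises |
|---|---|
| `local_sens` | ∫|∂I/∂pᵢ·pᵢ|dt over the unit's third step, normalised by the sum over all parameters |
| `sobol` | the first-order Sobol index Var(E(I\|pᵢ))/Var(I) over the fitted parameter ranges |
| `brute_rmsd` | (2/M²)·Σ_{j<k} RMSD(I_j, I_k) over M parameter draws from the prior |
| `discrim` | RMSD between the two candidate models' currents |
| `spacefill` | newly visited boxes of the 6×6×6 discretisation of (a, r, V) ∈ [0,1]×[0,1]×[−120,60] |

Gibbs-style variants freeze either the voltages or the durations of each
unit at uniform random draws and optimise only the other triple. A
separate designer optimises the nine parameters of a sum-of-square-waves
voltage (amplitudes, angular frequencies, phases; offset fixed at −30 mV)
to maximise two-model discrimination. Every designed protocol is wrapped
in a common head (leak ramp + conductance step) and tail (reversal-ramp
sequence) so leak, conductance and selectivity can be checked per cell.

## Worked example

```python
import numpy as np
from vcdesign import beattie_model, simulate
from vcdesign.fixtures import staircase_like_protocol
from vcdesign.design import DesignConfig, iterative_design
from vcdesign.objectives import PhaseGrid, beattie_phase_trajectory, phase_coverage

model = beattie_model()                      # 4-state model, published defaults
protocol = staircase_like_protocol()         # approximate staircase fixture
res = simulate(model, protocol)              # 1 ms sampling
print(f"protocol: {len(protocol)} commands, {protocol.total_duration:.0f} ms")
print(f"peak tail current: {res.current.max():.3f} nA")
print(f"peak open probability: {res.open_prob.max():.3f}")

cfg = DesignConfig(objective="spacefill", n_units=17, seed=1,
                   n_restarts=2, max_iter=60, popsize=10)
design = iterative_design(cfg)               # 51-step body + head/tail
count, _ = phase_coverage(beattie_phase_trajectory(model, design.protocol),
                          PhaseGrid())
print(f"designed protocol: {design.n_commands} commands, "
      f"{count}/216 phase-voltage boxes visited")
```

prints

```
protocol: 29 commands, 13900 ms
peak tail current: 4.667 nA
peak open probability: 0.895
designed protocol: 64 commands, 189/216 phase-voltage boxes visited
```

The 4.7 nA transient is the hERG tail current: channels held depolarised
are mostly inactivated, and on repolarisation they recover through the
open state before deactivating. The designed protocol uses the full
64-command budget (13 head/tail commands + 51 designed steps) and drives
the model through 189 of the 216 phase-voltage boxes — a trajectory that
probes most of the model's reachable behaviour in about 40 s of recording.

A command-line interface mirrors the library:

```sh
vcdesign fixtures --out-dir fx
vcdesign simulate --model beattie --protocol fx/staircase_like.tsv
vcdesign design --objective spacefill --runs 5 --seed 1 --out-dir designs
vcdesign design-squarewave --seed 1
```

## Layout

* `src/vcdesign/gating.py`, `parameters.py` — models, rate laws, published
  parameter tables and ranges, steady states
* `src/vcdesign/protocols.py` — step/ramp protocols, common head/tail,
  square waves, delimited-text I/O
* `src/vcdesign/simulation.py` — solvers, currents, local sensitivities
* `src/vcdesign/objectives.py` — the five design objectives and the Sobol
  estimator
* `src/vcdesign/design.py`, `cmaes.py` — the iterative designers and the
  optimiser
* `src/vcdesign/fixtures.py`, `fitting.py`, `plotting.py`, `cli.py` —
  fixture generators, model fitting, figures, command line

See `docs/methods.md` for the modelling assumptions, units, numerical
choices and known limitations.
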