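# Methods

## The medium

The controller is a kernel-weighted average over a growing memory of
sensorimotor (SM) flow. Every sensor and motor dimension is linearly
rescaled onto [0, 1]; all medium computations happen in this normalized
space, and the motor field it outputs is a rate of change of the
*normalized* motor coordinates per time-unit, converted back to raw motor
units by the body layer.

Each node stores a position `p`, a velocity `v`, a weight `w` and its
creation time. Both `p` and `v` keep all SM dimensions (sensor components
of `v` included) even though only motor components enter the field; this
keeps the stored record complete should sensor-component dynamics ever be
added. A node only influences the motors once its age exceeds the
activation delay (default 10 time-units); without the delay, a freshly
created node would dominate the field at the very state that created it and
the medium would chase its own tail instead of re-enacting earlier
trajectories.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k_d` | 1000 | 1/(normalized dist)² | distance-kernel steepness; confines a node's influence to a ≈0.05 neighborhood |
| `k_omega` | 0.0025 | 1/weight | weight-kernel steepness; weights of order ±10³ are needed to saturate influence |
| `k_t` | 1 | density | node-creation threshold: create while φ(x) < k_t |
| `activation_delay` | 10 | time-units | age before a node drives the motors |
| `decay_rate` | 1 | weight/tu | steady weight loss |
| `reinforcement_gain` | 10 | weight/tu | gain on proximity-driven weight recovery |
| `dt` | 0.01 | time-units | explicit-Euler step for all continuous dynamics |
| `phi_floor` | 0 | density | optional positive guard on the field normalization |

### Numerical choices

**Integration.** All continuous dynamics (weights, motor smoothing, body
kinematics, the field acting on the motors) use fixed-step explicit Euler
at `dt = 0.01`. The dynamics are non-stiff at the default parameters and
halving `dt` does not change any reported statistic at the precision we
quote; `dt` is a config knob.

**Step ordering.** Within one step: evaluate the motor field at the current
state (with pre-update weights), update all weights, run the node-creation
check, advance the clock. A node therefore never reinforces itself or
influences the field at the instant of its own creation. The creation check
runs once per integration step. The node velocity recorded at creation is
the backward finite difference of the normalized SM state over one step
(zero on the first step of a run and on the step after a relocation, where
the jump makes the difference meaningless).

**Which nodes enter the density.** For the creation threshold, all nodes
(activated or not) are counted — otherwise the first 10 time-units would
pile up unbounded nodes along the training trajectory. For the field's
normalization only activated nodes are counted, since only they contribute
to the numerator.

**Attraction factor.** The component of the attraction vector `p − x`
parallel to the node's stored velocity is removed by vector-projection
(`a − ((a·v)/‖v‖²) v`); a degenerate stored velocity (`‖v‖ ≤ 1e−12`)
leaves the attraction untouched rather than dividing by ~0.

**Division guard and far-field behavior.** The field is a
density-normalized average, so its magnitude does not decay with distance
from the node set — this is what lets a randomly scrambled motor state be
drawn back to a trained cycle from anywhere in the motor square. The sharp
distance kernel, however, underflows double precision beyond ‖p − x‖ ≈ 0.85.
We therefore evaluate the average with the kernel exponents shifted by
their minimum whenever the raw density drops below 1e−30; in that regime
`d ≈ 2 exp(−k_d‖p−x‖²)` to relative error < 1e−20 and the shift cancels
exactly in the ratio. The field is the zero vector only when no activated
node exists. Setting `phi_floor > 0` instead zeroes the field wherever the
raw activated density falls below the floor (motors hold), for users who
want a strictly local controller; with any meaningfully large floor the
re-enactment-after-perturbation behavior is lost, which is why the default
is 0.

**Weights** are unbounded in both directions and nodes are never deleted;
the ω kernel already drives the influence of strongly negative weights
toward zero. Extreme kernel arguments are clipped at ±700 before
exponentiation (beyond the clip both kernels are constant to double
precision).

## Bodies

The 1-D robot is a point on a line whose velocity equals its motor
`m ∈ [−1, 1]`, with a non-directional light sensor `s = 1/(1 + x²)` for a
light at the origin: a 2-D SM space with ranges m ∈ [−1, 1], s ∈ [0, 1].

The 2-D robot is a differential-drive disk (radius 0.25) in a width-4
arena with periodic boundaries: `ẋ = cos α (m_l + m_r)`,
`ẏ = sin α (m_l + m_r)`, `α̇ = 2(m_r − m_l)`. Two directional light
sensors sit on the rim at ±π/3 from the heading and read
`s = ((b·ĉ) + 1)/(1 + D²)` where `b` is the sensor's facing direction,
`c` the minimal-image vector to the light and `D = ‖c‖`; the raw range is
[0, 2] (a sensor exactly on the light reads 2 by the limit convention).
Distances to the light use the minimal-image convention, which with the
light at the arena center bounds D² ≤ 8. SM space is 4-D
(m_l, m_r, s_l, s_r). Normalization ranges are fixed a priori per body,
never adapted online. Motors are clipped to [−1, 1] after each Euler
update; the heading is wrapped to [−π, π) each step.

A third, motor-only body (two motors, no sensors, 2-D SM space) exposes the
medium's intrinsic dynamics for flow-field demonstrations and the
circle-imprinting protocol.

## Training, seeding and protocols

During a training phase the medium records and reinforces but never drives.
The circle trainer (`m₁ = 0.75 cos(2πt/10)`, `m₂ = 0.75 sin(2πt/10)`) and
the 1-D trainer (`m = cos(t/2)/2`) set the motors directly. The three
Braitenberg behaviors map sensors to motor *targets* (ipsilateral inverse
for simple phototaxis; the same plus an antisymmetric ±sin(2t)/2 wiggle;
contralateral inverse for photophobia), clip the targets to [−1, 1], and
track them through `dm/dt = χ − m` (clipping before smoothing). Weight
reinforcement operates during training as well as free action.

Random-walk seeding fills the medium with 100 walks × 50 loci = 5000
neutral nodes: each walk starts uniformly in [0, 1]⁴ and steps by
components drawn from U(−0.05, 0.05), negating any component that would
exit the unit volume (reflection at the boundary; reflecting the resulting
position instead would differ only at second order in the step size). Each
locus becomes a node with `v` equal to the accepted step out of it; the
final locus uses the next proposed, unemitted step so every node has a
defined velocity. Seeded nodes are backdated past the activation delay so
they shape behavior from the first instant of a trial.

Protocol presets: **motor_circle** (train 20 tu, free to 100 tu, motors
randomized at t = 30), **oscillation_1d** (train 20 tu from x = −2.5, free
to 80 tu, position reset to −2.5 at t = 35 with the motor left as-is),
**trained_2d** (train 100 tu, free 400 tu, robot relocated to a random pose
with random motors every 50 tu on a clock that runs across the phase
boundary; the mean-distance-to-light statistic is evaluated on the
[100, 500] window), and **random_init_2d** (seeded medium, 10 trials of
100 tu, each starting from a random pose and random motors, the medium
persisting and continuing to adapt across trials). Relocations never touch
the medium. The frozen flow-field probe evaluates velocity, attraction and
combined fields on a grid without side effects. One seeded generator per
run drives all randomness; identical config + seed gives bit-identical
trajectories.

## Analysis

Mean distance to the light is the time-average of the minimal-image
Euclidean distance. Region coding subdivides normalized SM space into a
10-per-dimension lattice (half-open bins, top bin closed) and numbers
hypercubes in first-visit order. PCA projections are fit on states pooled
across trials so different trials share one projection plane. Oscillation
amplitude is half the 5–95% interquantile span (robust to the non-sinusoidal
shape of re-enacted cycles); the period is the mean interval between rising
mean-crossings. The recurrence fraction is the share of window states whose
nearest earlier-in-window state, at least one time-unit older, lies within
δ in normalized SM space; states in the first guard interval, which cannot
have an eligible predecessor, are excluded from both numerator and
denominator, so a perfectly closed loop scores 1 − (period/window), tending
to 1 as the window grows.

## What the experiments show — and what they do not

All inputs are generated internally; there is no sensor noise, inertia or
friction, and the environments are stationary (fixed light, fixed arena).
Passing tests show that the medium imprints, re-enacts, and spontaneously
forms repetitive SM patterns *in these idealized bodies*; they say nothing
about robustness to noise, non-stationary environments, or real actuators.
The hand-categorization of emergent habits into discrete classes is out of
scope: the package emits the region sequences, recurrence fractions and PCA
coordinates from which such a categorization can be made by inspection.

A known quantitative limitation: along a cycle that is enacted at the
trained speed, the reinforcement a node collects per pass (the time
integral of `10·d` as the state sweeps by at ≈0.24 normalized units/tu)
is about half the weight it loses to decay over one period, so even
perfectly re-enacted behavior shows slowly *declining* node weights.
Self-maintenance at these parameters is relative, not absolute: on-cycle
nodes decay markedly slower than unvisited ones (≈0.7 vs 1.0 per
time-unit), and because the weight kernel's scale is 1/k_ω = 400, their
influence ω(w) stays near 1 for run lengths orders of magnitude beyond the
experiments here. Behavior that dwells (e.g., a phototaxis robot stopped at
the light) does achieve absolute weight growth, since reinforcement at
d ≈ 1 outpaces decay tenfold.

## Problem sizes

Default experiment durations are 100 tu (motor circle), 80 tu (1-D), 500 tu
per behavior (trained 2-D) and 10 × 100 tu (emergence), all at dt = 0.01;
node counts reach ≈10² for the motor-only agent, ≈10³ for trained 2-D runs
and ≈6.5 × 10³ for the seeded emergence run. These sizes reproduce the
qualitative regimes stably across seeds; the acceptance statistics are
medians over 10 seeds.
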