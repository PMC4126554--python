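# idsm

An **iterant deformable sensorimotor medium (IDSM)**: a plastic, node-based
controller for simulated robots in which trajectories through sensorimotor
space reinforce themselves, so that patterns of behavior — *habits* — can be
imprinted by training, maintain themselves through re-enactment, and emerge
spontaneously from a randomly initialized medium.

The package is for researchers in embodied cognition, adaptive behavior and
minimal-cognition robotics who want a continuous-time, sensorimotor-level
model of habit formation that sits between neuron-level models and discrete
stimulus–response descriptions. It provides the medium itself, two simulated
robot bodies (a 1-D light-seeking point robot and a 2-D two-wheel robot in a
periodic arena), the external training controllers, random-walk seeding,
phase-scheduled experiment protocols, and trajectory analysis.

## The model

The agent's sensorimotor (SM) state `x` lives in a normalized space where
every sensor and motor dimension is rescaled to [0, 1]. The medium is a
growing set of **nodes** `N = ⟨p, v, w⟩`: a past SM position `p`, the SM
velocity `v` observed there, and a weight `w`. Node density at a state is

    φ(x) = Σ_N ω(N_w) · d(N_p, x)
    ω(w)  = 2 / (1 + exp(−k_ω w)),        k_ω = 0.0025
    d(p,x) = 2 / (1 + exp(k_d ‖p − x‖²)),  k_d = 1000

A node is created at the current state (with `w = 0` and `v` the observed SM
velocity) whenever `φ(x) < k_t = 1`. Weights evolve as

    dw/dt = −1 + 10 · d(N_p, x)

— steady decay, offset by reinforcement whenever the state revisits the
node's neighborhood. Ten time-units after creation a node is *activated* and
contributes to the motor field

    dμ/dt = (1/φ(x)) Σ_N ω(N_w) · d(N_p, x) · (N_v + Γ(N_p − x, N_v))^μ

where `Γ(a, v)` removes from `a` its component parallel to `v`, and the
superscript μ keeps only motor components. The first term re-enacts recorded
motion (velocity factor); the second pulls the state toward familiar regions
(attraction factor). Because the sum is divided by the density, the field is
an *average* of node influences and remains O(1) arbitrarily far from the
nodes. All dynamics are integrated with explicit Euler at `dt = 0.01`
time-units.

## Worked example: imprinting and re-enacting a motor cycle

Drive a 2-motor, 0-sensor agent around a circle of radius 0.75 with period
10 for 20 time-units, hand control to the medium, scramble the motors at
t = 30, and let it run to t = 100:

```python
import numpy as np
from idsm import motor_circle_preset, run, oscillation_stats

record, medium = run(motor_circle_preset(seed=1))
m = record.window(80, 100)[["m1", "m2"]].to_numpy()
radius = np.hypot(m[:, 0], m[:, 1]).mean()
amp, period, _ = oscillation_stats(record.window(60, 100)["m1"].to_numpy(), dt=0.01)
print(f"nodes recorded:        {medium.n_nodes}")
print(f"re-enacted radius:     {radius:.3f}   (trained: 0.75)")
print(f"re-enacted period:     {period:.2f}   (trained: 10.0)")
```

prints

```
nodes recorded:        105
re-enacted radius:     0.755   (trained: 0.75)
re-enacted period:     10.25   (trained: 10.0)
```

After the perturbation the medium pulls the motor state back onto the
trained cycle and re-enacts it at the trained amplitude and period: the
circle has been imprinted as a habit. The same machinery runs the other
protocols — `oscillation_1d_preset` (a 1-D oscillation habit that resumes
after the robot is displaced), `trained_2d_preset` (Braitenberg-trained
phototaxis/photophobia habits of the two-wheel robot), and
`random_init_2d_preset` (habit emergence from a medium seeded with 5000
random-walk nodes). A thin CLI mirrors the library:

```
idsm run motor_circle --seed 1 --out out/        # trajectory + node snapshot
idsm field out/nodes.csv --grid 21               # frozen flow-field probe
idsm analyze out/trajectory.csv --t0 80          # window statistics
```

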