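"""Phase-scheduled coupled simulation of medium, body and environment.

A run is a sequence of phases:

* ``train`` — an external training controller drives the motors while the
  medium records nodes and updates weights;
* ``free``  — the motor field drives the motors (medium keeps updating);
* ``frozen`` — the motor field drives the motors but the medium itself is
  held fixed (no weight change, no new nodes).

Timed events (random relocation, relocation to a pose, motor
randomization) perturb the body without touching the medium.  Presets
reproduce the four study protocols: imprinting a motor circle into a
motor-only agent, the 1-D oscillation habit with a perturbation,
Braitenberg-trained functional habits of the two-wheel robot, and habit
emergence from a random-walk-seeded medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import core
from .bodies import (ARENA_WIDTH, Body1DState, Body2DState, MotorOnlyState,
                     _advance_motors, wrap_angle)
from .core import IDSMParams, IDSMState
from .seeding import RandomWalkConfig, seed_idsm
from .training import BRAITENBERG_KINDS, TrainerConfig, apply_trainer

__all__ = [
    "Event",
    "ExperimentConfig",
    "TrajectoryRecord",
    "run",
    "flow_field",
    "motor_grid",
    "relocate",
    "motor_circle_preset",
    "oscillation_1d_preset",
    "trained_2d_preset",
    "random_init_2d_preset",
    "make_config",
]

_BODY_CLASSES = {
    "motor_only": MotorOnlyState,
    "body_1d": Body1DState,
    "body_2d": Body2DState,
}

PHASE_KINDS = ("train", "free", "frozen")
EVENT_KINDS = ("relocate_random", "relocate_to", "randomize_motors")


@dataclass(frozen=True)
class Event:
    """A timed perturbation of the body; the medium is never touched."""

    time: float
    kind: str
    pose: dict | None = None  # for relocate_to

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    body: str
    phases: tuple[tuple[str, float], ...]
    events: tuple[Event, ...] = ()
    trainer: TrainerConfig | None = None
    seeding: RandomWalkConfig | None = None
    idsm: IDSMParams = dc_field(default_factory=IDSMParams)
    seed: int = 0
    stride: int = 1

    def __post_init__(self) -> None:
        if self.body not in _BODY_CLASSES:
            raise ValueError(f"unknown body {self.body!r}")
        for kind, dur in self.phases:
            if kind not in PHASE_KINDS:
                raise ValueError(f"unknown phase kind {kind!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")
        if any(k == "train" for k, _ in self.phases) and self.trainer is None:
            raise ValueError("a train phase requires a trainer")
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be sorted by time")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.phases)


class TrajectoryRecord:
    """Time series of a run: body state, raw sensors, normalized SM state,
    per-step phase labels and event markers, as a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame, meta: dict):
        self.df = df
        self.meta = meta

    def window(self, t0: float, t1: float) -> pd.DataFrame:
        """Rows with t in [t0, t1)."""
        t = self.df["t"].to_numpy()
        return self.df[(t >= t0 - 1e-9) & (t < t1 - 1e-9)]

    def sm(self, df: pd.DataFrame | None = None) -> np.ndarray:
        """Normalized SM states as an (n, dim) array."""
        df = self.df if df is None else df
        cols = [c for c in df.columns if c.startswith("sm_")]
        return df[cols].to_numpy()


# ------------------------------------------------------------------ relocation

def relocate(body, rng: np.random.Generator, mode: str = "random",
             pose: dict | None = None):
    """Reset body pose and/or motors; sensors are recomputed, medium untouched.

    ``random``: position uniform over the arena, heading uniform over
    [-pi, pi), motors uniform over [-1, 1].  ``to_pose``: set the given
    pose fields exactly, leaving everything else as-is.
    """
    if mode == "random":
        if isinstance(body, Body2DState):
            half = ARENA_WIDTH / 2.0
            body.x = float(rng.uniform(-half, half))
            body.y = float(rng.uniform(-half, half))
            body.alpha = wrap_angle(float(rng.uniform(-np.pi, np.pi)))
            body.set_motors(rng.uniform(-1.0, 1.0, size=2))
            body.refresh_sensors()
        elif isinstance(body, Body1DState):
            body.x = float(rng.uniform(-3.0, 3.0))
            body.m = float(rng.uniform(-1.0, 1.0))
            body.advance_pose(0.0)
        else:
            body.set_motors(rng.uniform(-1.0, 1.0, size=2))
    elif mode == "to_pose":
        for key, val in (pose or {}).items():
            setattr(body, key, val)
        if isinstance(body, Body2DState):
            body.refresh_sensors()
        elif isinstance(body, Body1DState):
            body.advance_pose(0.0)
    else:
        raise ValueError(f"unknown relocation mode {mode!r}")
    return body


def _randomize_motors(body, rng: np.random.Generator) -> None:
    n = len(body.MOTOR_INDICES)
    body.set_motors(rng.uniform(-1.0, 1.0, size=n))
    if isinstance(body, Body2DState):
        body.refresh_sensors()
    elif isinstance(body, Body1DState):
        body.advance_pose(0.0)


# ------------------------------------------------------------------------ run

def _phase_at(boundaries: np.ndarray, kinds: list[str], t: float) -> str:
    i = int(np.searchsorted(boundaries, t, side="right"))
    return kinds[min(i, len(kinds) - 1)]


def _record_columns(body) -> dict:
    if isinstance(body, MotorOnlyState):
        return {"m1": body.m1, "m2": body.m2}
    if isinstance(body, Body1DState):
        return {"x": body.x, "m": body.m, "s": body.s}
    return {"x": body.x, "y": body.y, "alpha": body.alpha,
            "m_l": body.m_l, "m_r": body.m_r,
            "s_l": body.s_l, "s_r": body.s_r}


def run(config: ExperimentConfig) -> tuple[TrajectoryRecord, IDSMState]:
    """Execute the configured experiment; returns the trajectory and medium.

    Within each integration step: events due at that instant are applied,
    the normalized SM state and its backward-difference velocity are
    formed, the medium performs its bookkeeping (field evaluation in
    free/frozen phases, then weight update and node-creation check unless
    frozen), the state is recorded, and finally the motors (trainer or
    field) and body pose advance.  Identical config and seed give
    bit-identical trajectories.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.idsm.dt
    body = _BODY_CLASSES[config.body]()
    nmap = body.normalization()
    dim = nmap.dim
    if config.seeding is not None:
        idsm = seed_idsm(config.seeding, dim, body.MOTOR_INDICES,
                         config.idsm, rng=rng)
    else:
        idsm = IDSMState(dim, config.idsm, body.MOTOR_INDICES)

    kinds = [k for k, _ in config.phases]
    boundaries = np.cumsum([d for _, d in config.phases])
    n_steps = int(round(config.duration / dt))
    events = list(config.events)
    ev_ptr = 0

    rows: dict[str, list] = {}
    x_prev: np.ndarray | None = None
    zero_v = np.zeros(dim)

    for k in range(n_steps):
        t = k * dt
        event_label = ""
        while ev_ptr < len(events) and events[ev_ptr].time <= t + dt / 2.0:
            ev = events[ev_ptr]
            if ev.kind == "relocate_random":
                relocate(body, rng, "random")
            elif ev.kind == "relocate_to":
                relocate(body, rng, "to_pose", ev.pose)
            else:
                _randomize_motors(body, rng)
            event_label = (event_label + "+" + ev.kind) if event_label else ev.kind
            x_prev = None  # SM state jumps; no meaningful backward difference
            ev_ptr += 1

        phase = _phase_at(boundaries, kinds, t)

        if phase == "train":
            # direct-drive trainers define the motor state *at* time t
            if config.trainer.kind not in BRAITENBERG_KINDS:
                apply_trainer(config.trainer, body, t, dt)

        x = nmap.normalize(body.sm_raw())
        v_est = zero_v if x_prev is None else (x - x_prev) / dt

        if phase == "free":
            _, fld = core.step_idsm(idsm, x, v_est, dt)
        elif phase == "frozen":
            fld = core.motor_field(idsm, x)
            idsm.t += dt
        else:
            core.update_weights(idsm, x, dt)
            core.maybe_create_node(idsm, x, v_est)
            idsm.t += dt
            fld = None

        if k % config.stride == 0:
            row = {"t": t, "phase": phase, "event": event_label,
                   **_record_columns(body)}
            for j in range(dim):
                row[f"sm_{j}"] = x[j]
            for key, val in row.items():
                rows.setdefault(key, []).append(val)

        # advance motors and pose into [t, t+dt)
        if phase == "train":
            if config.trainer.kind in BRAITENBERG_KINDS:
                apply_trainer(config.trainer, body, t, dt)
        else:
            _advance_motors(body, nmap, fld, dt)
        body.advance_pose(dt)
        x_prev = x

    df = pd.DataFrame(rows)
    meta = {
        "experiment": config.experiment,
        "body": config.body,
        "dim": dim,
        "motor_indices": list(body.MOTOR_INDICES),
        "seed": config.seed,
        "dt": dt,
        "phases": [list(p) for p in config.phases],
        "normalization": {"raw_min": list(map(float, nmap.raw_min)),
                          "raw_max": list(map(float, nmap.raw_max))},
        "n_nodes": idsm.n_nodes,
    }
    return TrajectoryRecord(df, meta), idsm


# ------------------------------------------------------------------ flow probe

def flow_field(idsm: IDSMState, points) -> dict[str, np.ndarray]:
    """Probe a frozen copy of the medium on a set of SM points.

    Returns the velocity factor, the attraction factor and their sum
    (the full motor field) at each point, each as an (n_points, n_motors)
    array.  Purely read-only: the medium is not modified.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_m = len(idsm.motor_indices)
    vel = np.empty((points.shape[0], n_m))
    att = np.empty((points.shape[0], n_m))
    for i, x in enumerate(points):
        vel[i], att[i] = core.field_components(idsm, x)
    return {"velocity": vel, "attraction": att, "combined": vel + att}


def motor_grid(n: int = 21, sensor_values=()) -> np.ndarray:
    """Regular n x n grid over the two motor dimensions of normalized SM
    space, with any sensor dimensions held at the given fixed values."""
    g = np.linspace(0.0, 1.0, n)
    m1, m2 = np.meshgrid(g, g, indexing="ij")
    cols = [m1.ravel(), m2.ravel()]
    for s in sensor_values:
        cols.append(np.full(n * n, float(s)))
    return np.column_stack(cols)


# -------------------------------------------------------------------- presets

def motor_circle_preset(seed: int = 0, train: float = 20.0,
                        total: float = 100.0, randomize_at: float = 30.0,
                        idsm: IDSMParams | None = None) -> ExperimentConfig:
    """Imprint a period-10, radius-0.75 motor circle, release, perturb.

    Training drives the motor-only agent around the circle for ``train``
    time-units; the medium then controls the motors; at ``randomize_at``
    both motors are set to uniform-random values and the run continues to
    ``total``.
    """
    return ExperimentConfig(
        experiment="motor_circle", body="motor_only",
        phases=(("train", train), ("free", total - train)),
        events=(Event(randomize_at, "randomize_motors"),),
        trainer=TrainerConfig("circle_2motor", duration=train),
        idsm=idsm or IDSMParams(), seed=seed)


def oscillation_1d_preset(seed: int = 0, train: float = 20.0,
                          total: float = 80.0, relocate_at: float = 35.0,
                          idsm: IDSMParams | None = None) -> ExperimentConfig:
    """1-D oscillation habit: train m = cos(t/2)/2 from x = -2.5, release,
    relocate the robot back to its starting position mid-run."""
    return ExperimentConfig(
        experiment="oscillation_1d", body="body_1d",
        phases=(("train", train), ("free", total - train)),
        events=(Event(relocate_at, "relocate_to", pose={"x": -2.5}),),
        trainer=TrainerConfig("oscillation_1d", duration=train),
        idsm=idsm or IDSMParams(), seed=seed)


def trained_2d_preset(kind: str, seed: int = 0, train: float = 100.0,
                      free: float = 400.0, relocate_every: float = 50.0,
                      idsm: IDSMParams | None = None) -> ExperimentConfig:
    """Braitenberg-trained functional habit of the two-wheel robot.

    Training runs for ``train`` time-units, then the medium controls the
    robot for ``free`` time-units; every ``relocate_every`` time-units
    (from t = 0, across the phase boundary) the robot is relocated to a
    random position with a random motor state.
    """
    if kind not in BRAITENBERG_KINDS:
        raise ValueError(f"kind must be one of {BRAITENBERG_KINDS}")
    total = train + free
    times = np.arange(0.0, total - 1e-9, relocate_every)
    events = tuple(Event(float(t), "relocate_random") for t in times)
    return ExperimentConfig(
        experiment="trained_2d", body="body_2d",
        phases=(("train", train), ("free", free)),
        events=events,
        trainer=TrainerConfig(kind, duration=train),
        idsm=idsm or IDSMParams(), seed=seed)


def random_init_2d_preset(seed: int = 0, n_trials: int = 10,
                          trial_length: float = 100.0,
                          seeding: RandomWalkConfig | None = None,
                          idsm: IDSMParams | None = None) -> ExperimentConfig:
    """Habit emergence from a random-walk-seeded medium: a sequence of
    trials, each starting with the robot at a random pose with random
    motors, the medium controlling it for ``trial_length`` time-units."""
    events = tuple(Event(i * trial_length, "relocate_random")
                   for i in range(n_trials))
    return ExperimentConfig(
        experiment="random_init_2d", body="body_2d",
        phases=(("free", n_trials * trial_length),),
        events=events,
        seeding=seeding or RandomWalkConfig(seed=seed),
        idsm=idsm or IDSMParams(), seed=seed)


_PRESETS = {
    "motor_circle": motor_circle_preset,
    "oscillation_1d": oscillation_1d_preset,
    "random_init_2d": random_init_2d_preset,
}


def make_config(name: str, seed: int = 0, **kwargs) -> ExperimentConfig:
    """Build a preset config by name (trained_2d requires ``kind=``)."""
    if name == "trained_2d":
        return trained_2d_preset(seed=seed, **kwargs)
    if name in _PRESETS:
        return _PRESETS[name](seed=seed, **kwargs)
    raise ValueError(f"unknown preset {name!r}")
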