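"""Simulated robot bodies and the raw <-> normalized SM-space mapping.

Three bodies are provided:

* a **motor-only** agent with two motors and no sensors (2-D SM space),
  used for the flow-field demonstrations of the medium in isolation;
* a **1-D light robot**: a point on a line with a single motor (velocity
  control, m in [-1, 1]) and one non-directional light sensor
  ``s = 1 / (1 + x^2)`` for a light at the origin (2-D SM space);
* a **2-D two-wheel robot** in a width-4 periodic arena with two
  directional light sensors (4-D SM space).

Every body exposes a fixed dimension ordering (motors first, then
sensors) and a :class:`NormalizationMap` that rescales each raw dimension
linearly onto [0, 1]; all medium computations happen in normalized
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizationMap",
    "MotorOnlyState",
    "Body1DState",
    "Body2DState",
    "ARENA_WIDTH",
    "sensor_1d",
    "sensors_2d",
    "step_motor_only",
    "step_body_1d",
    "step_body_2d",
    "wrap_position",
    "wrap_angle",
    "minimal_image",
]

ARENA_WIDTH = 4.0  # 2-D arena is [-2, 2)^2 with periodic boundaries


# ----------------------------------------------------------------- normalization

@dataclass(frozen=True)
class NormalizationMap:
    """Per-dimension linear map between raw SM ranges and [0, 1]."""

    raw_min: np.ndarray
    raw_max: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.raw_min, dtype=float)
        hi = np.asarray(self.raw_max, dtype=float)
        object.__setattr__(self, "raw_min", lo)
        object.__setattr__(self, "raw_max", hi)
        if lo.shape != hi.shape or np.any(lo >= hi):
            raise ValueError("require raw_min < raw_max per dimension")

    @property
    def dim(self) -> int:
        return self.raw_min.shape[0]

    def normalize(self, raw) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        z = (raw - self.raw_min) / (self.raw_max - self.raw_min)
        if np.any(z < -1e-9) or np.any(z > 1 + 1e-9):
            warnings.warn("raw SM value outside declared range; clipping",
                          stacklevel=2)
        return np.clip(z, 0.0, 1.0)

    def denormalize(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.raw_min + z * (self.raw_max - self.raw_min)


# ---------------------------------------------------------------- periodic arena

def wrap_position(u: float, width: float = ARENA_WIDTH) -> float:
    """Wrap a coordinate into [-width/2, width/2)."""
    return (u + width / 2.0) % width - width / 2.0


def wrap_angle(a: float) -> float:
    """Wrap an angle into [-pi, pi)."""
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def minimal_image(delta, width: float = ARENA_WIDTH) -> np.ndarray:
    """Shortest periodic displacement equivalent to ``delta`` (per component)."""
    delta = np.asarray(delta, dtype=float)
    return (delta + width / 2.0) % width - width / 2.0


# --------------------------------------------------------------------- sensors

def sensor_1d(x: float) -> float:
    """Non-directional light sensor of the 1-D robot: ``1 / (1 + x^2)``."""
    return 1.0 / (1.0 + x * x)


def sensors_2d(state: "Body2DState", light=(0.0, 0.0)) -> tuple[float, float]:
    """Directional light sensor pair of the two-wheel robot.

    Each sensor sits on the body rim at angular offset +/- beta from the
    heading and reads ``s = ((b . c_hat) + 1) / (1 + D^2)`` where ``b`` is
    the unit vector the sensor faces, ``c`` the minimal-image vector from
    the sensor to the light and ``D = ||c||``; range [0, 2], directional
    with inverse-square falloff.  A sensor exactly on the light reads 2.
    """
    light = np.asarray(light, dtype=float)
    out = []
    for sgn in (+1.0, -1.0):
        ang = state.alpha + sgn * state.beta
        b = np.array([np.cos(ang), np.sin(ang)])
        pos = np.array([state.x, state.y]) + state.r_body * b
        c = minimal_image(light - pos)
        d = float(np.hypot(*c))
        if d == 0.0:
            out.append(2.0)
        else:
            out.append((float(b @ c) / d + 1.0) / (1.0 + d * d))
    return out[0], out[1]


# ---------------------------------------------------------------------- bodies

@dataclass
class MotorOnlyState:
    """Two motors, no sensors; SM space is the motor square [-1, 1]^2."""

    m1: float = 0.0
    m2: float = 0.0

    MOTOR_INDICES = (0, 1)

    @staticmethod
    def normalization() -> NormalizationMap:
        return NormalizationMap(np.array([-1.0, -1.0]), np.array([1.0, 1.0]))

    def sm_raw(self) -> np.ndarray:
        return np.array([self.m1, self.m2])

    def set_motors(self, motors) -> None:
        self.m1, self.m2 = (float(np.clip(m, -1.0, 1.0)) for m in motors)

    def advance_pose(self, dt: float) -> None:
        """No physical pose: the motor pair is the whole state."""


@dataclass
class Body1DState:
    """Point robot on a line; velocity equals its single motor state."""

    x: float = -2.5
    m: float = 0.0
    s: float = field(default=0.0)

    MOTOR_INDICES = (0,)

    def __post_init__(self) -> None:
        self.s = sensor_1d(self.x)

    @staticmethod
    def normalization() -> NormalizationMap:
        # dims: (m, s); motor in [-1, 1], sensor law bounded in (0, 1]
        return NormalizationMap(np.array([-1.0, 0.0]), np.array([1.0, 1.0]))

    def sm_raw(self) -> np.ndarray:
        return np.array([self.m, self.s])

    def set_motors(self, motors) -> None:
        self.m = float(np.clip(motors[0], -1.0, 1.0))

    def advance_pose(self, dt: float) -> None:
        """Euler-step position (xdot = m) and refresh the light sensor."""
        self.x += dt * self.m
        self.s = sensor_1d(self.x)


@dataclass
class Body2DState:
    """Two-wheel differential-drive robot in the periodic arena.

    Kinematics: xdot = cos(alpha)(m_l + m_r), ydot = sin(alpha)(m_l + m_r),
    alphadot = 2 (m_r - m_l), with wheel motors in [-1, 1].
    """

    x: float = 0.0
    y: float = 0.0
    alpha: float = 0.0
    m_l: float = 0.0
    m_r: float = 0.0
    s_l: float = field(default=0.0)
    s_r: float = field(default=0.0)
    r_body: float = 0.25
    beta: float = np.pi / 3.0
    light: tuple[float, float] = (0.0, 0.0)

    MOTOR_INDICES = (0, 1)

    def __post_init__(self) -> None:
        self.refresh_sensors()

    @staticmethod
    def normalization() -> NormalizationMap:
        # dims: (m_l, m_r, s_l, s_r); motors [-1, 1], sensor law bounded [0, 2]
        return NormalizationMap(np.array([-1.0, -1.0, 0.0, 0.0]),
                                np.array([1.0, 1.0, 2.0, 2.0]))

    def refresh_sensors(self) -> None:
        self.s_l, self.s_r = sensors_2d(self, self.light)

    def sm_raw(self) -> np.ndarray:
        return np.array([self.m_l, self.m_r, self.s_l, self.s_r])

    def set_motors(self, motors) -> None:
        self.m_l = float(np.clip(motors[0], -1.0, 1.0))
        self.m_r = float(np.clip(motors[1], -1.0, 1.0))

    def advance_pose(self, dt: float) -> None:
        """Euler-step the pose, wrap into the periodic arena, refresh sensors."""
        fwd = self.m_l + self.m_r
        self.x = wrap_position(self.x + dt * np.cos(self.alpha) * fwd)
        self.y = wrap_position(self.y + dt * np.sin(self.alpha) * fwd)
        self.alpha = wrap_angle(self.alpha + dt * 2.0 * (self.m_r - self.m_l))
        self.refresh_sensors()


# ----------------------------------------------------------------------- steps

def _advance_motors(state, nmap: NormalizationMap, motor_rates, dt: float) -> None:
    """Euler-advance the normalized motor coordinates, then de-normalize and clip."""
    idx = list(state.MOTOR_INDICES)
    z = nmap.normalize(state.sm_raw())
    z[idx] = np.clip(z[idx] + dt * np.asarray(motor_rates, dtype=float), 0.0, 1.0)
    state.set_motors(nmap.denormalize(z)[idx])


def step_motor_only(state: MotorOnlyState, motor_rates, dt: float,
                    nmap: NormalizationMap | None = None) -> MotorOnlyState:
    nmap = nmap or MotorOnlyState.normalization()
    _advance_motors(state, nmap, motor_rates, dt)
    return state


def step_body_1d(state: Body1DState, motor_rate, dt: float,
                 nmap: NormalizationMap | None = None) -> Body1DState:
    """Advance motor (in normalized coordinates), then position, then sensor."""
    nmap = nmap or Body1DState.normalization()
    _advance_motors(state, nmap, np.atleast_1d(motor_rate), dt)
    state.advance_pose(dt)
    return state


def step_body_2d(state: Body2DState, motor_rates, dt: float,
                 nmap: NormalizationMap | None = None) -> Body2DState:
    """Advance motors, Euler-step the pose, wrap periodically, refresh sensors."""
    nmap = nmap or Body2DState.normalization()
    _advance_motors(state, nmap, motor_rates, dt)
    state.advance_pose(dt)
    return state
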