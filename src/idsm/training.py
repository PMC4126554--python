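"""Externally imposed training controllers.

During a training phase the medium keeps recording nodes and updating
weights, but the motors are driven by one of these controllers rather
than by the motor field:

* ``circle_2motor`` — the period-10, radius-0.75 circular motor signal
  used to imprint a cycle into the motor-only agent;
* ``oscillation_1d`` — the 1-D robot's oscillation ``m = cos(t/2)/2``;
* three Braitenberg-style behaviors for the two-wheel robot
  (``simple_phototaxis``, ``sinusoidal_phototaxis``, ``photophobia``),
  whose sensor-derived motor *targets* are clipped to [-1, 1] and then
  tracked smoothly through ``dm/dt = chi - m``.

The circle and 1-D trainers set the motors directly; only the
Braitenberg behaviors use the smoothing update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrainerConfig",
    "TRAINER_KINDS",
    "BRAITENBERG_KINDS",
    "trainer_circle",
    "trainer_oscillation_1d",
    "braitenberg_targets",
    "motor_smoothing",
    "apply_trainer",
]

BRAITENBERG_KINDS = ("simple_phototaxis", "sinusoidal_phototaxis", "photophobia")
TRAINER_KINDS = ("circle_2motor", "oscillation_1d") + BRAITENBERG_KINDS


@dataclass(frozen=True)
class TrainerConfig:
    """Which training controller to run and for how long.

    amplitude/period apply to the direct-drive kinds (circle_2motor:
    radius 0.75, period 10; oscillation_1d: amplitude 0.5, period 4*pi).
    """

    kind: str
    duration: float = 20.0
    amplitude: float | None = None
    period: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRAINER_KINDS:
            raise ValueError(f"unknown trainer kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("trainer duration must be > 0")


def trainer_circle(t: float, amplitude: float = 0.75,
                   period: float = 10.0) -> tuple[float, float]:
    """Circular motor training signal (m1, m2) = A (cos, sin)(2 pi t / T)."""
    ang = 2.0 * np.pi * t / period
    return amplitude * np.cos(ang), amplitude * np.sin(ang)


def trainer_oscillation_1d(t: float, amplitude: float = 0.5,
                           period: float = 4.0 * np.pi) -> float:
    """1-D oscillation training signal m = A cos(2 pi t / T) (default cos(t/2)/2)."""
    return amplitude * np.cos(2.0 * np.pi * t / period)


def braitenberg_targets(kind: str, sigma_l: float, sigma_r: float,
                        t: float) -> tuple[float, float]:
    """Target motor pair (chi_l, chi_r) for the Braitenberg behaviors.

    simple_phototaxis: ipsilateral inverse coupling, chi = 1 - 1.5 sigma;
    sinusoidal_phototaxis: the same plus an antisymmetric +/- sin(2t)/2
    wiggle; photophobia: contralateral inverse coupling.  Targets are
    clipped to [-1, 1].
    """
    if kind == "simple_phototaxis":
        chi_l = 1.0 - 1.5 * sigma_l
        chi_r = 1.0 - 1.5 * sigma_r
    elif kind == "sinusoidal_phototaxis":
        chi_l = 1.0 - 1.5 * sigma_l + np.sin(2.0 * t) / 2.0
        chi_r = 1.0 - 1.5 * sigma_r - np.sin(2.0 * t) / 2.0
    elif kind == "photophobia":
        chi_l = 1.0 - 1.5 * sigma_r
        chi_r = 1.0 - 1.5 * sigma_l
    else:
        raise ValueError(f"unknown Braitenberg kind {kind!r}")
    return float(np.clip(chi_l, -1.0, 1.0)), float(np.clip(chi_r, -1.0, 1.0))


def motor_smoothing(m: float, chi: float, dt: float) -> float:
    """One Euler step of the smoothing law ``dm/dt = chi - m``."""
    return m + dt * (chi - m)


def apply_trainer(config: TrainerConfig, body, t: float, dt: float) -> None:
    """Drive the body's motors for one step of the training phase.

    Direct-drive kinds set the motors to the closed-form signal at time
    ``t``; Braitenberg kinds read the body's current sensors and smooth the
    motors toward the clipped targets.  Mutates ``body``.
    """
    kind = config.kind
    if kind == "circle_2motor":
        kw = {}
        if config.amplitude is not None:
            kw["amplitude"] = config.amplitude
        if config.period is not None:
            kw["period"] = config.period
        body.set_motors(trainer_circle(t, **kw))
    elif kind == "oscillation_1d":
        kw = {}
        if config.amplitude is not None:
            kw["amplitude"] = config.amplitude
        if config.period is not None:
            kw["period"] = config.period
        body.set_motors([trainer_oscillation_1d(t, **kw)])
    else:
        chi_l, chi_r = braitenberg_targets(kind, body.s_l, body.s_r, t)
        body.set_motors([motor_smoothing(body.m_l, chi_l, dt),
                         motor_smoothing(body.m_r, chi_r, dt)])
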