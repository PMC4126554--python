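"""The iterant deformable sensorimotor medium (IDSM).

The medium is a growing collection of *nodes*, each a record
``N = <p, v, w>`` of the sensorimotor (SM) flow at a past moment:
``p`` is a point in normalized SM space (every sensor and motor dimension
rescaled to [0, 1]), ``v`` is the SM velocity that was observed there, and
``w`` is a weight that decays steadily and is replenished whenever the
current SM state revisits the node's neighborhood.  Activated nodes exert
two influences on the motor components of the SM state: a *velocity*
factor pushing along the recorded flow, and an *attraction* factor pulling
the state toward the node (with the component parallel to the node's
velocity removed so the two influences do not fight).  The net motor
velocity is the density-normalized weighted average of these influences,
so behavior that has been performed recently and often is re-enacted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Node",
    "IDSMParams",
    "IDSMState",
    "weight_factor",
    "proximity",
    "density",
    "update_weights",
    "maybe_create_node",
    "perpendicular_component",
    "field_components",
    "motor_field",
    "step_idsm",
]

# exp() overflows above ~709 in double precision; the kernels saturate long before
_EXP_CLIP = 700.0

# below this raw density the field switches to a shift-normalized average
_UNDERFLOW_PHI = 1e-30

_DEGENERATE_V = 1e-12


class Node(NamedTuple):
    """One record of past SM flow: position, velocity, weight, creation time."""

    p: np.ndarray
    v: np.ndarray
    w: float
    t_created: float


@dataclass(frozen=True)
class IDSMParams:
    """Parameters of the medium.

    k_d
        Steepness of the distance kernel ``d(p, x) = 2 / (1 + exp(k_d ||p-x||^2))``.
    k_omega
        Steepness of the weight kernel ``omega(w) = 2 / (1 + exp(-k_omega w))``.
    k_t
        Node-creation density threshold: a node is added only while the local
        density ``phi(x)`` is below this value.
    activation_delay
        Time-units after creation before a node influences the motors.
    decay_rate
        Steady weight loss per time-unit (the degradation term of dw/dt).
    reinforcement_gain
        Gain on the proximity-driven reinforcement term of dw/dt.
    dt
        Default explicit-Euler integration step, in time-units.
    phi_floor
        Optional positive guard on the field's density normalization.  At the
        default 0.0 the field is computed as a shift-normalized weighted
        average, which stays well-defined at any distance from the nodes and
        is zero only when no activated node exists; a positive value instead
        zeroes the field wherever the raw activated density falls below it.
    """

    k_d: float = 1000.0
    k_omega: float = 0.0025
    k_t: float = 1.0
    activation_delay: float = 10.0
    decay_rate: float = 1.0
    reinforcement_gain: float = 10.0
    dt: float = 0.01
    phi_floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_d", "k_omega", "k_t", "activation_delay",
                     "decay_rate", "reinforcement_gain", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"IDSMParams.{name} must be strictly positive")
        if self.phi_floor < 0:
            raise ValueError("IDSMParams.phi_floor must be >= 0")


class IDSMState:
    """The full medium: node collection, parameters, simulation clock.

    Nodes are stored in flat numpy arrays (grown geometrically) so the
    per-step kernels vectorize over the whole collection.  Nodes are never
    deleted, and because they are appended in time order the activated
    subset is always a prefix of the arrays.
    """

    def __init__(self, dim: int, params: IDSMParams | None = None,
                 motor_indices: Sequence[int] | None = None, t: float = 0.0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self.params = params if params is not None else IDSMParams()
        self.motor_indices = (tuple(range(dim)) if motor_indices is None
                              else tuple(int(i) for i in motor_indices))
        self.t = float(t)
        self._cap = 256
        self._n = 0
        self._p = np.empty((self._cap, self.dim))
        self._v = np.empty((self._cap, self.dim))
        self._w = np.empty(self._cap)
        self._t_created = np.empty(self._cap)

    # ------------------------------------------------------------------ nodes
    @property
    def n_nodes(self) -> int:
        return self._n

    @property
    def p(self) -> np.ndarray:
        return self._p[: self._n]

    @property
    def v(self) -> np.ndarray:
        return self._v[: self._n]

    @property
    def w(self) -> np.ndarray:
        return self._w[: self._n]

    @property
    def t_created(self) -> np.ndarray:
        return self._t_created[: self._n]

    def nodes(self) -> list[Node]:
        """The node collection as Node records (copies)."""
        return [Node(self._p[i].copy(), self._v[i].copy(),
                     float(self._w[i]), float(self._t_created[i]))
                for i in range(self._n)]

    def add_node(self, p: np.ndarray, v: np.ndarray, w: float = 0.0,
                 t_created: float | None = None) -> None:
        p = np.asarray(p, dtype=float)
        v = np.asarray(v, dtype=float)
        if p.shape != (self.dim,) or v.shape != (self.dim,):
            raise ValueError("node p and v must match the medium dimensionality")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("node position must lie in [0, 1]^dim")
        if self._n == self._cap:
            self._grow()
        i = self._n
        self._p[i] = p
        self._v[i] = v
        self._w[i] = w
        self._t_created[i] = self.t if t_created is None else t_created
        self._n += 1

    def _grow(self) -> None:
        self._cap *= 2
        for name in ("_p", "_v"):
            old = getattr(self, name)
            new = np.empty((self._cap, self.dim))
            new[: self._n] = old[: self._n]
            setattr(self, name, new)
        for name in ("_w", "_t_created"):
            old = getattr(self, name)
            new = np.empty(self._cap)
            new[: self._n] = old[: self._n]
            setattr(self, name, new)

    def n_activated(self, t: float | None = None) -> int:
        """Number of activated nodes (creation at least ``activation_delay`` ago)."""
        t = self.t if t is None else t
        cutoff = t - self.params.activation_delay
        # nodes are appended in time order -> activated set is a prefix
        return int(np.searchsorted(self._t_created[: self._n], cutoff, side="right"))

    def copy(self) -> "IDSMState":
        out = IDSMState(self.dim, self.params, self.motor_indices, self.t)
        out._cap = self._cap
        out._n = self._n
        out._p = self._p.copy()
        out._v = self._v.copy()
        out._w = self._w.copy()
        out._t_created = self._t_created.copy()
        return out


# ---------------------------------------------------------------------- kernels

def weight_factor(w, k_omega: float = 0.0025):
    """Sigmoidal weight kernel ``omega(w) = 2 / (1 + exp(-k_omega w))`` in (0, 2).

    Neutral (freshly created) nodes have w = 0 and omega = 1; reinforced nodes
    approach 2, degraded nodes approach 0.
    """
    z = np.clip(-k_omega * np.asarray(w, dtype=float), -_EXP_CLIP, _EXP_CLIP)
    return 2.0 / (1.0 + np.exp(z))


def proximity(p, x, k_d: float = 1000.0):
    """Distance kernel ``d(p, x) = 2 / (1 + exp(k_d ||p - x||^2))`` in (0, 1].

    Equals 1 at zero distance and falls off sharply (k_d = 1000 confines the
    influence of a node to roughly a 0.05 neighborhood in normalized space).
    ``p`` may be an (n, dim) array of node positions.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    if p.shape[-1] != x.shape[-1]:
        raise ValueError("p and x must have the same dimensionality")
    sq = np.sum((p - x) ** 2, axis=-1)
    z = np.clip(k_d * sq, -_EXP_CLIP, _EXP_CLIP)
    return 2.0 / (1.0 + np.exp(z))


def density(idsm: IDSMState, x, activated_only: bool = False) -> float:
    """Node density ``phi(x) = sum_N omega(N.w) d(N.p, x)``.

    For the node-creation threshold all nodes are counted; for the motor
    field's normalization only activated nodes enter (``activated_only``).
    """
    n = idsm.n_activated() if activated_only else idsm.n_nodes
    if n == 0:
        return 0.0
    d = proximity(idsm.p[:n], np.asarray(x, dtype=float), idsm.params.k_d)
    om = weight_factor(idsm.w[:n], idsm.params.k_omega)
    return float(np.sum(om * d))


# ---------------------------------------------------------------- weight update

def update_weights(idsm: IDSMState, x, dt: float) -> IDSMState:
    """Advance every node's weight by one explicit Euler step of
    ``dw/dt = -decay_rate + reinforcement_gain * d(N.p, x)``.

    Applies to all nodes regardless of activation status; weights are
    unbounded (the omega kernel saturates their influence).  Mutates and
    returns ``idsm``.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if idsm.n_nodes and dt > 0:
        d = proximity(idsm.p, np.asarray(x, dtype=float), idsm.params.k_d)
        idsm.w[:] += dt * (-idsm.params.decay_rate
                           + idsm.params.reinforcement_gain * d)
    return idsm


def maybe_create_node(idsm: IDSMState, x, v_est) -> bool:
    """Add a node at ``x`` (weight 0, velocity ``v_est``) iff ``phi(x) < k_t``.

    ``v_est`` is the current normalized SM rate of change (backward finite
    difference over one integration step).  Returns True if a node was added.
    """
    x = np.asarray(x, dtype=float)
    if density(idsm, x) < idsm.params.k_t:
        idsm.add_node(np.clip(x, 0.0, 1.0), np.asarray(v_est, dtype=float))
        return True
    return False


# ------------------------------------------------------------------ motor field

def perpendicular_component(a, v, tol: float = _DEGENERATE_V):
    """Remove from ``a`` its projection onto ``v``: ``a - ((a.v)/||v||^2) v``.

    The result is orthogonal to ``v``.  A degenerate stored velocity
    (``||v|| <= tol``) returns ``a`` unchanged.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    nv2 = float(np.dot(v, v))
    if nv2 <= tol * tol:
        return a.copy()
    return a - (np.dot(a, v) / nv2) * v


def _field_terms(idsm: IDSMState, x: np.ndarray, n_act: int):
    """Per-activated-node kernel products and influence vectors at ``x``."""
    p = idsm.p[:n_act]
    v = idsm.v[:n_act]
    a = p - x
    nv2 = np.sum(v * v, axis=1)
    coef = np.zeros(n_act)
    ok = nv2 > _DEGENERATE_V ** 2
    coef[ok] = np.sum(a[ok] * v[ok], axis=1) / nv2[ok]
    gamma = a - coef[:, None] * v          # attraction, parallel part removed
    om = weight_factor(idsm.w[:n_act], idsm.params.k_omega)
    sq = np.sum(a * a, axis=1)
    return om, sq, v, gamma


def _normalized_node_weights(idsm: IDSMState, x: np.ndarray, sq: np.ndarray,
                             om: np.ndarray) -> np.ndarray | None:
    """Per-activated-node weights omega*d divided by their sum (the density).

    Returns None where the field must be zero (no activated nodes, or raw
    density below a user-set positive phi_floor).  Where the sharp distance
    kernel underflows, the weights are evaluated with the kernel exponents
    shifted by their minimum — for k_d*sq >> 1, d ~ 2 exp(-k_d sq), so the
    shift cancels in the average to relative error < 1e-20.
    """
    k_d = idsm.params.k_d
    d = 2.0 / (1.0 + np.exp(np.clip(k_d * sq, None, _EXP_CLIP)))
    phi = float(np.sum(om * d))
    if idsm.params.phi_floor > 0.0 and phi < idsm.params.phi_floor:
        return None
    if phi > _UNDERFLOW_PHI:
        return om * d / phi
    z = k_d * sq
    weights = om * np.exp(-(z - z.min()))
    phi = float(np.sum(weights))
    if phi == 0.0:
        return None
    return weights / phi


def field_components(idsm: IDSMState, x) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and attraction parts of the motor field at ``x``, separately.

    Each is the density-normalized sum over activated nodes of
    ``omega(N.w) * d(N.p, x) * N.v`` (velocity factor) and of
    ``omega(N.w) * d(N.p, x) * Gamma(N.p - x, N.v)`` (attraction factor,
    the component parallel to the node's velocity removed), restricted to
    the motor components.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (idsm.dim,):
        raise ValueError("x must match the medium dimensionality")
    motor_idx = list(idsm.motor_indices)
    zero = np.zeros(len(motor_idx))
    n_act = idsm.n_activated()
    if n_act == 0:
        return zero, zero.copy()
    om, sq, v, gamma = _field_terms(idsm, x, n_act)
    weights = _normalized_node_weights(idsm, x, sq, om)
    if weights is None:
        return zero, zero.copy()
    vel = np.asarray(weights @ v[:, motor_idx])
    att = np.asarray(weights @ gamma[:, motor_idx])
    return vel, att


def motor_field(idsm: IDSMState, x) -> np.ndarray:
    """Motor velocity (normalized units per time-unit) commanded by the medium.

    Density-normalized sum, over activated nodes, of
    ``omega(N.w) * d(N.p, x) * (N.v + Gamma(N.p - x, N.v))``, restricted to
    the motor components.  The normalization makes the field an *average* of
    node influences, so its magnitude does not vanish far from the nodes;
    where the sharp distance kernel underflows, the average is evaluated in
    shifted form (see ``_normalized_node_weights``).  With no activated
    nodes — or, when ``phi_floor`` is set positive, wherever the raw
    activated density is below it — the field is the zero vector and the
    motors hold.
    """
    vel, att = field_components(idsm, x)
    return vel + att


# ------------------------------------------------------------------- step

def step_idsm(idsm: IDSMState, x, v_est, dt: float | None = None,
              frozen: bool = False) -> tuple[IDSMState, np.ndarray]:
    """One medium step at SM state ``x``: field, weight update, node creation.

    Order within the step: the motor field is evaluated first (with the
    pre-update weights), then weights advance, then the creation check runs,
    then the clock advances — so a node never reinforces or influences the
    field at the instant of its own creation.  With ``frozen=True`` the state
    is untouched and only the field is returned.
    """
    x = np.asarray(x, dtype=float)
    dt = idsm.params.dt if dt is None else float(dt)
    field = motor_field(idsm, x)
    if frozen or dt == 0.0:
        return idsm, field
    update_weights(idsm, x, dt)
    maybe_create_node(idsm, x, v_est)
    idsm.t += dt
    return idsm, field
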