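"""Random-walk initialization of the medium.

For the habit-emergence experiment the medium starts not empty but with
5000 neutral nodes laid down by 100 reflected random walks through the
4-D normalized SM space: each walk starts uniformly at random in
[0, 1]^dim and takes 50 steps with components drawn uniformly from
[-0.05, 0.05]; any step component that would leave the unit volume is
inverted (negated).  A node is emitted at every visited locus with its
velocity set to the accepted step out of that locus and weight 0.  Seeded
nodes are marked already past their activation delay so they shape
behavior from the first instant of a trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IDSMParams, IDSMState

__all__ = ["RandomWalkConfig", "random_walk_nodes", "seed_idsm"]


@dataclass(frozen=True)
class RandomWalkConfig:
    """Random-walk seeding parameters (defaults give 100 x 50 = 5000 nodes)."""

    n_walks: int = 100
    steps_per_walk: int = 50
    step_range: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walks < 1 or self.steps_per_walk < 1:
            raise ValueError("n_walks and steps_per_walk must be >= 1")
        if self.step_range <= 0:
            raise ValueError("step_range must be > 0")

    @property
    def n_nodes(self) -> int:
        return self.n_walks * self.steps_per_walk


def random_walk_nodes(config: RandomWalkConfig, dim: int,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Generate seeded node positions and velocities.

    Returns arrays ``p`` and ``v`` of shape (n_walks * steps_per_walk, dim);
    all positions lie in [0, 1]^dim and every velocity component is bounded
    by ``step_range``.  The last locus of each walk takes its velocity from
    the next proposed (unemitted) step so every node has a defined velocity.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_nodes
    p = np.empty((n, dim))
    v = np.empty((n, dim))
    k = 0
    for _ in range(config.n_walks):
        locus = rng.uniform(0.0, 1.0, size=dim)
        for _ in range(config.steps_per_walk):
            step = rng.uniform(-config.step_range, config.step_range, size=dim)
            nxt = locus + step
            # invert any component that would leave the unit volume
            out = (nxt < 0.0) | (nxt > 1.0)
            step[out] = -step[out]
            nxt = locus + step
            p[k] = locus
            v[k] = step
            k += 1
            locus = nxt
    return p, v


def seed_idsm(config: RandomWalkConfig, dim: int,
              motor_indices=None, params: IDSMParams | None = None,
              rng: np.random.Generator | None = None) -> IDSMState:
    """Build a medium pre-populated with the random-walk nodes at t = 0.

    Nodes get weight 0 and a creation time of ``-activation_delay`` so they
    are activated from the first step.
    """
    params = params if params is not None else IDSMParams()
    idsm = IDSMState(dim, params, motor_indices)
    p, v = random_walk_nodes(config, dim, rng)
    for i in range(p.shape[0]):
        idsm.add_node(p[i], v[i], w=0.0, t_created=-params.activation_delay)
    return idsm
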