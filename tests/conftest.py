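import math

import numpy as np
import pytest

from idsm.core import IDSMParams, IDSMState


def brute_force_motor_field(idsm: IDSMState, x) -> np.ndarray:
    """Independent straight-loop oracle for the motor field.

    Literal per-node evaluation: for each activated node compute
    omega(w) = 2/(1+exp(-k_omega w)), d = 2/(1+exp(k_d ||p-x||^2)),
    Gamma(p-x, v) = (p-x) - (((p-x).v)/||v||^2) v, accumulate
    omega*d*(v+Gamma) and omega*d, then divide and take motor components.
    Pure python scalar math; shares no code with the implementation.
    """
    x = np.asarray(x, dtype=float)
    dim = idsm.dim
    num = [0.0] * dim
    phi = 0.0
    for node in idsm.nodes():
        if idsm.t - node.t_created < idsm.params.activation_delay:
            continue
        sq = sum((node.p[j] - x[j]) ** 2 for j in range(dim))
        d = 2.0 / (1.0 + math.exp(min(idsm.params.k_d * sq, 700.0)))
        om = 2.0 / (1.0 + math.exp(-idsm.params.k_omega * node.w))
        a = [node.p[j] - x[j] for j in range(dim)]
        nv2 = sum(vj * vj for vj in node.v)
        if nv2 > 1e-24:
            coef = sum(a[j] * node.v[j] for j in range(dim)) / nv2
            gamma = [a[j] - coef * node.v[j] for j in range(dim)]
        else:
            gamma = a
        for j in range(dim):
            num[j] += om * d * (node.v[j] + gamma[j])
        phi += om * d
    if phi == 0.0:
        return np.zeros(len(idsm.motor_indices))
    return np.array([num[j] / phi for j in idsm.motor_indices])


def random_medium(rng: np.random.Generator, dim: int, n_nodes: int,
                  motor_indices=None) -> IDSMState:
    """A medium with random activated nodes for oracle comparisons."""
    idsm = IDSMState(dim, IDSMParams(), motor_indices, t=100.0)
    for _ in range(n_nodes):
        idsm.add_node(rng.uniform(0, 1, dim),
                      rng.uniform(-0.3, 0.3, dim),
                      w=float(rng.uniform(-500, 500)),
                      t_created=float(rng.uniform(0, 80)))
    return idsm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
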