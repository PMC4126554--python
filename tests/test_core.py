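"""Unit and property tests for the medium's kernels, bookkeeping and field."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idsm.core import (IDSMParams, IDSMState, density, maybe_create_node,
                       motor_field, perpendicular_component, proximity,
                       step_idsm, update_weights, weight_factor)

from conftest import brute_force_motor_field, random_medium


# ----------------------------------------------------------------- kernels

@pytest.mark.parametrize("w, expected", [
    (0.0, 1.0),
    (1e7, 2.0),                       # sigmoid upper asymptote
    (-1000.0, 2.0 / (1.0 + np.exp(2.5))),
])
def test_weight_factor_values(w, expected):
    assert weight_factor(w) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("p, x, expected", [
    ([0.3, 0.7], [0.3, 0.7], 1.0),
    ([0.0, 0.0], [np.sqrt(0.001), 0.0], 2.0 / (1.0 + np.e)),
    ([0.0, 0.0], [0.1, 0.0], 2.0 / (1.0 + np.exp(10.0))),
])
def test_proximity_values(p, x, expected):
    assert proximity(p, x) == pytest.approx(expected, rel=1e-12)


def test_proximity_dimension_mismatch():
    with pytest.raises(ValueError):
        proximity([0.1, 0.2], [0.1, 0.2, 0.3])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
def test_weight_factor_monotone_bounded(w1, w2):
    f1, f2 = float(weight_factor(w1)), float(weight_factor(w2))
    assert 0.0 < f1 < 2.0
    if w1 < w2:
        assert f1 <= f2


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_proximity_monotone_decreasing(r1, r2):
    d1 = float(proximity([0.0], [r1]))
    d2 = float(proximity([0.0], [r2]))
    assert 0.0 < d1 <= 1.0
    if r1 < r2:
        assert d1 >= d2


# ----------------------------------------------------------------- density

def test_density_empty_is_zero():
    assert density(IDSMState(2), [0.5, 0.5]) == 0.0


def test_density_fresh_nodes_at_point():
    s = IDSMState(2)
    s.add_node([0.5, 0.5], [0, 0])
    assert density(s, [0.5, 0.5]) == pytest.approx(1.0)
    s.add_node([0.5, 0.5], [0, 0])
    assert density(s, [0.5, 0.5]) == pytest.approx(2.0)


# ------------------------------------------------------------ weight update

def test_update_weights_euler_step():
    s = IDSMState(2)
    s.add_node([0.5, 0.5], [0, 0])          # exactly at x: dw/dt = -1 + 10 = 9
    s.add_node([0.0, 0.0], [0, 0])          # far: dw/dt ~ -1
    update_weights(s, [0.5, 0.5], dt=0.01)
    assert s.w[0] == pytest.approx(0.09)
    assert s.w[1] == pytest.approx(-0.01, rel=1e-6)


def test_update_weights_zero_dt_noop():
    s = IDSMState(2)
    s.add_node([0.2, 0.2], [0, 0], w=3.0)
    update_weights(s, [0.9, 0.9], dt=0.0)
    assert s.w[0] == 3.0


def test_unreinforced_decay_rate():
    """With the state clamped far from all nodes, every weight decays at
    decay_rate to within 1%% per time-unit."""
    rng = np.random.default_rng(0)
    s = IDSMState(3)
    for _ in range(15):
        s.add_node(rng.uniform(0.5, 1.0, 3), rng.uniform(-0.1, 0.1, 3),
                   w=float(rng.uniform(-5, 5)))
    x = np.zeros(3)  # every node is > 0.3 away
    assert np.all(np.linalg.norm(s.p - x, axis=1) > 0.3)
    w0 = s.w.copy()
    for _ in range(100):
        update_weights(s, x, 0.01)
    drop = w0 - s.w
    assert np.all(np.abs(drop - 1.0) < 0.01)


# ------------------------------------------------------------ node creation

def test_create_in_empty_medium():
    s = IDSMState(2)
    assert maybe_create_node(s, [0.3, 0.4], [0.1, 0.0])
    node = s.nodes()[0]
    assert node.w == 0.0
    assert np.allclose(node.p, [0.3, 0.4])
    assert np.allclose(node.v, [0.1, 0.0])


def test_creation_refused_at_threshold():
    """A fresh node exactly at x gives density 1 = k_t; the strict
    inequality refuses a second node there."""
    s = IDSMState(2)
    maybe_create_node(s, [0.5, 0.5], [0, 0])
    assert not maybe_create_node(s, [0.5, 0.5], [0, 0])
    assert s.n_nodes == 1


def test_creation_below_threshold():
    s = IDSMState(2)
    s.add_node([0.5, 0.5], [0, 0], w=-500.0)  # omega < 1 -> density < 1
    assert density(s, [0.5, 0.5]) < 1.0
    assert maybe_create_node(s, [0.5, 0.5], [0, 0])


def test_creation_counts_unactivated_nodes():
    """The creation threshold sums over ALL nodes, activated or not."""
    s = IDSMState(2)
    s.add_node([0.5, 0.5], [0, 0], t_created=s.t)   # not yet activated
    assert s.n_activated() == 0
    assert not maybe_create_node(s, [0.5, 0.5], [0, 0])


def test_creation_pushes_density_toward_threshold(rng):
    s = IDSMState(2)
    for _ in range(30):
        x = rng.uniform(0, 1, 2)
        before = density(s, x)
        maybe_create_node(s, x, rng.uniform(-0.1, 0.1, 2))
        after = density(s, x)
        assert after >= min(s.params.k_t, before) - 1e-12


def test_node_count_never_decreases(rng):
    s = IDSMState(2)
    counts = []
    for _ in range(50):
        step_idsm(s, rng.uniform(0, 1, 2), rng.uniform(-0.1, 0.1, 2), 0.01)
        counts.append(s.n_nodes)
    assert all(b >= a for a, b in zip(counts, counts[1:]))


# ------------------------------------------------- perpendicular component

@pytest.mark.parametrize("a, v, expected", [
    ([1, 0], [0, 1], [1, 0]),
    ([0, 2], [0, 1], [0, 0]),
    ([1, 1], [1, 0], [0, 1]),
])
def test_perpendicular_component_examples(a, v, expected):
    assert np.allclose(perpendicular_component(a, v), expected)


def test_perpendicular_degenerate_velocity_returns_a():
    a = np.array([0.3, -0.2])
    assert np.allclose(perpendicular_component(a, [0.0, 0.0]), a)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(-1, 1), min_size=2, max_size=4),
       st.lists(st.floats(-1, 1), min_size=2, max_size=4),
       st.integers(2, 4))
def test_perpendicular_orthogonality(a, v, dim):
    a = np.resize(np.asarray(a), dim)
    v = np.resize(np.asarray(v), dim)
    out = perpendicular_component(a, v)
    nv = np.linalg.norm(v)
    na = np.linalg.norm(out)
    # well-conditioned cases only: near-parallel a and v cancel to a residual
    # dominated by rounding, where the direction is meaningless
    if nv > 1e-12 and na > 1e-6 * np.linalg.norm(a):
        assert abs(out @ v) / (na * nv) < 1e-9


# ---------------------------------------------------------------- the field

def test_single_node_field_equals_velocity_at_node():
    s = IDSMState(2, t=20.0)
    s.add_node([0.5, 0.5], [0.0, 0.1], t_created=0.0)
    assert np.allclose(motor_field(s, [0.5, 0.5]), [0.0, 0.1])


def test_field_zero_with_no_activated_nodes():
    s = IDSMState(3)
    s.add_node([0.5, 0.5, 0.5], [0.1, 0, 0], t_created=s.t)
    assert np.allclose(motor_field(s, [0.5, 0.5, 0.5]), 0.0)


@pytest.mark.parametrize("dim", [2, 4])
def test_field_matches_brute_force_oracle(dim):
    """The vectorized field equals a literal per-node scalar-loop sum on
    100 random media (up to 20 nodes) to 1e-9 relative accuracy."""
    rng = np.random.default_rng(dim)
    for _ in range(100):
        n = int(rng.integers(1, 21))
        motor_idx = tuple(range(dim)) if dim == 2 else (0, 1)
        s = random_medium(rng, dim, n, motor_idx)
        j = int(rng.integers(n))
        x = np.clip(s.p[j] + rng.uniform(-0.05, 0.05, dim), 0.0, 1.0)
        got = motor_field(s, x)
        want = brute_force_motor_field(s, x)
        scale = max(1.0, float(np.linalg.norm(want)))
        assert np.allclose(got, want, atol=1e-9 * scale)


def test_field_respects_positive_phi_floor():
    params = IDSMParams(phi_floor=1e-8)
    s = IDSMState(2, params, t=20.0)
    s.add_node([0.5, 0.5], [0.0, 0.1], t_created=0.0)
    # raw density at distance 0.5 underflows below the floor -> motors hold
    assert np.allclose(motor_field(s, [0.0, 0.5]), 0.0)
    assert np.allclose(motor_field(s, [0.5, 0.5]), [0.0, 0.1])


def test_field_average_survives_kernel_underflow():
    """Far from all nodes the density-normalized average stays finite and
    points with the node influences (the kernel underflows raw)."""
    s = IDSMState(2, t=20.0)
    s.add_node([0.9, 0.9], [0.0, 0.0], t_created=0.0)
    f = motor_field(s, [0.05, 0.05])
    assert np.all(np.isfinite(f))
    assert f[0] > 0 and f[1] > 0  # pure attraction toward the node


# ---------------------------------------------------------------- step_idsm

def test_step_empty_medium_creates_node_returns_zero_field():
    s = IDSMState(2)
    s, f = step_idsm(s, [0.4, 0.6], [0.0, 0.0], 0.01)
    assert np.allclose(f, 0.0)
    assert s.n_nodes == 1
    assert s.t == pytest.approx(0.01)


def test_step_frozen_leaves_state_unchanged():
    s = IDSMState(2, t=20.0)
    s.add_node([0.5, 0.5], [0.0, 0.1], t_created=0.0)
    w_before = s.w.copy()
    n_before = s.n_nodes
    t_before = s.t
    _, f = step_idsm(s, [0.5, 0.5], [0, 0], 0.01, frozen=True)
    assert np.allclose(f, [0.0, 0.1])
    assert s.n_nodes == n_before and s.t == t_before
    assert np.array_equal(s.w, w_before)


def test_step_zero_dt_noop():
    s = IDSMState(2, t=20.0)
    s.add_node([0.5, 0.5], [0.0, 0.1], t_created=0.0, w=1.0)
    _, f = step_idsm(s, [0.5, 0.5], [0, 0], 0.0)
    assert s.t == 20.0 and s.w[0] == 1.0


def test_params_validation():
    with pytest.raises(ValueError):
        IDSMParams(k_d=0.0)
    with pytest.raises(ValueError):
        IDSMParams(phi_floor=-1.0)
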