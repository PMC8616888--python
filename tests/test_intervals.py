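"""Interval propagation: case formulas, soundness, containment, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from innuq.intervals import (
    IntervalBox,
    forward_interval,
    propagate_nonneg_interval,
    propagate_point_input,
    wrap_network,
)
from innuq.nets import Conv1d, Dense, PredictionNetwork, make_conv_net

from conftest import oracle_interval_layer, oracle_point_layer


def _scalar_layer(activation="relu"):
    return Dense(np.array([[1.0]]), np.array([0.0]), activation=activation)


def _boxes(w_lo, w_hi, b_lo=0.0, b_hi=0.0):
    return (IntervalBox(np.array([[w_lo]]), np.array([[w_hi]])),
            IntervalBox(np.array([b_lo]), np.array([b_hi])))


class TestIntervalBox:
    def test_invariant_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            IntervalBox(np.array([1.0]), np.array([0.5]))

    def test_width_nonnegative_and_point(self):
        box = IntervalBox(np.array([0.0, 1.0]), np.array([0.5, 1.0]))
        assert np.all(box.width >= 0)
        p = IntervalBox.point(np.array([3.0]))
        assert np.all(p.width == 0)


class TestPointInputPropagation:
    def test_point_intervals_reduce_to_base_layer(self, rng):
        W = rng.standard_normal((3, 4))
        b = rng.standard_normal(3)
        lay = Dense(W, b)
        z = rng.standard_normal((5, 4))
        box = propagate_point_input(lay, IntervalBox.point(W),
                                    IntervalBox.point(b), z)
        expected = np.maximum(z @ W.T + b, 0.0)
        np.testing.assert_allclose(box.lower, expected, atol=1e-12)
        np.testing.assert_allclose(box.upper, expected, atol=1e-12)

    @pytest.mark.parametrize(
        "z, expected_lo, expected_hi",
        [(-1.0, 0.0, 0.0),     # pre-activation [-2,-1], clipped by ReLU
         (0.5, 0.5, 1.0)],     # pre-activation [0.5, 1]
    )
    def test_scalar_relu_examples(self, z, expected_lo, expected_hi):
        lay = _scalar_layer()
        w_box, b_box = _boxes(1.0, 2.0)
        box = propagate_point_input(lay, w_box, b_box, np.array([[z]]))
        assert box.lower[0, 0] == pytest.approx(expected_lo, abs=1e-9)
        assert box.upper[0, 0] == pytest.approx(expected_hi, abs=1e-9)

    def test_matches_vertex_oracle_on_random_small_layers(self, rng):
        """Closed-form bounds equal brute-force vertex enumeration (1x1, 2x2)."""
        for shape in [(1, 1), (2, 2)]:
            for act in ("relu", "identity"):
                W = rng.standard_normal(shape)
                dW = rng.uniform(0, 1, shape)
                b = rng.standard_normal(shape[0])
                db = rng.uniform(0, 1, shape[0])
                lay = Dense(W, b, activation=act)
                w_box = IntervalBox(W - dW, W + dW)
                b_box = IntervalBox(b - db, b + db)
                z = rng.standard_normal(shape[1])
                got = propagate_point_input(lay, w_box, b_box, z[None])
                lo, hi = oracle_point_layer(W - dW, W + dW, b - db, b + db,
                                            z, act)
                np.testing.assert_allclose(got.lower[0], lo, atol=1e-9)
                np.testing.assert_allclose(got.upper[0], hi, atol=1e-9)

    def test_shape_mismatch_raises(self):
        lay = _scalar_layer()
        w_box, b_box = _boxes(1.0, 2.0)
        with pytest.raises(ValueError):
            propagate_point_input(lay, w_box, b_box, np.zeros((1, 3)))


class TestNonnegIntervalPropagation:
    def test_degenerate_box_with_point_weights_is_base_layer(self, rng):
        W = rng.standard_normal((3, 4))
        b = rng.standard_normal(3)
        lay = Dense(W, b)
        z = np.abs(rng.standard_normal((2, 4)))
        box = propagate_nonneg_interval(lay, IntervalBox.point(W),
                                        IntervalBox.point(b),
                                        IntervalBox.point(z))
        expected = np.maximum(z @ W.T + b, 0.0)
        np.testing.assert_allclose(box.lower, expected, atol=1e-12)
        np.testing.assert_allclose(box.upper, expected, atol=1e-12)

    @pytest.mark.parametrize(
        "w_lo, w_hi, expected_lo, expected_hi",
        [(-1.0, 1.0, 0.0, 1.0),   # pre-activation [-1, 1]
         (1.0, 2.0, 0.5, 2.0)],
    )
    def test_scalar_relu_examples(self, w_lo, w_hi, expected_lo, expected_hi):
        lay = _scalar_layer()
        w_box, b_box = _boxes(w_lo, w_hi)
        z_box = IntervalBox(np.array([[0.5]]), np.array([[1.0]]))
        box = propagate_nonneg_interval(lay, w_box, b_box, z_box)
        assert box.lower[0, 0] == pytest.approx(expected_lo, abs=1e-9)
        assert box.upper[0, 0] == pytest.approx(expected_hi, abs=1e-9)

    def test_matches_vertex_oracle_on_random_small_layers(self, rng):
        for shape in [(1, 1), (2, 2)]:
            W = rng.standard_normal(shape)
            dW = rng.uniform(0, 1, shape)
            b = rng.standard_normal(shape[0])
            db = rng.uniform(0, 1, shape[0])
            lay = Dense(W, b)
            z_lo = rng.uniform(0, 1, shape[1])
            z_hi = z_lo + rng.uniform(0, 1, shape[1])
            got = propagate_nonneg_interval(
                lay, IntervalBox(W - dW, W + dW), IntervalBox(b - db, b + db),
                IntervalBox(z_lo[None], z_hi[None]))
            lo, hi = oracle_interval_layer(W - dW, W + dW, b - db, b + db,
                                           z_lo, z_hi, "relu")
            np.testing.assert_allclose(got.lower[0], lo, atol=1e-9)
            np.testing.assert_allclose(got.upper[0], hi, atol=1e-9)

    def test_negative_lower_bound_rejected(self):
        lay = _scalar_layer()
        w_box, b_box = _boxes(1.0, 2.0)
        z_box = IntervalBox(np.array([[-0.1]]), np.array([[1.0]]))
        with pytest.raises(ValueError):
            propagate_nonneg_interval(lay, w_box, b_box, z_box)


class TestWrapNetwork:
    def test_zero_width_wrap_reproduces_base(self, toy_dense_net, rng):
        inn = wrap_network(toy_dense_net, init_width=0.0, eps0=0.0)
        z = rng.standard_normal((6, 4))
        lo, hi, pred = forward_interval(inn, z)
        # equal up to floating-point associativity and outward rounding
        np.testing.assert_allclose(lo, pred, atol=1e-9)
        np.testing.assert_allclose(hi, pred, atol=1e-9)

    def test_positive_width_strictly_contains_base_params(self, toy_dense_net):
        inn = wrap_network(toy_dense_net, init_width=0.01)
        for lay, wb in zip(toy_dense_net.layers, inn.weight_intervals):
            assert np.all(wb.lower <= lay.W) and np.all(lay.W <= wb.upper)
            assert np.all(wb.width > 0)

    def test_wrapped_net_contains_base_prediction(self, toy_dense_net, rng):
        inn = wrap_network(toy_dense_net, init_width=0.01)
        for _ in range(10):
            z = rng.standard_normal((1, 4))
            lo, hi, pred = forward_interval(inn, z)
            assert np.all(lo <= pred) and np.all(pred <= hi)

    def test_invalid_layer_selection_rejected(self, toy_dense_net):
        with pytest.raises(ValueError):
            wrap_network(toy_dense_net, interval_layers=[7])


class TestForwardInterval:
    def test_monte_carlo_soundness_toy_net(self, toy_dense_net, rng):
        """Any parameter selection inside the intervals stays inside the
        propagated output interval (1000 random selections)."""
        inn = wrap_network(toy_dense_net, init_width=0.05)
        z = rng.standard_normal((3, 4))
        lo, hi, _ = forward_interval(inn, z)
        probe = PredictionNetwork(
            [Dense(l.W.copy(), l.b.copy(), activation=l.activation)
             for l in toy_dense_net.layers])
        for _ in range(1000):
            for lay, wb, bb in zip(probe.layers, inn.weight_intervals,
                                   inn.bias_intervals):
                lay.W[...] = rng.uniform(wb.lower, wb.upper)
                lay.b[...] = rng.uniform(bb.lower, bb.upper)
            out = probe.forward(z)
            assert np.all(lo <= out) and np.all(out <= hi)

    def test_inclusion_monotonicity_single_weight(self, toy_dense_net, rng):
        """Widening one weight interval never shrinks any output interval."""
        z = rng.standard_normal((2, 4))
        inn = wrap_network(toy_dense_net, init_width=0.02)
        lo0, hi0, _ = forward_interval(inn, z)
        for layer_idx, entry in [(0, (0, 0)), (1, (2, 3)), (2, (1, 1))]:
            inn2 = wrap_network(toy_dense_net, init_width=0.02)
            wb = inn2.weight_intervals[layer_idx]
            wb.lower[entry] -= 0.3
            wb.upper[entry] += 0.3
            lo1, hi1, _ = forward_interval(inn2, z)
            assert np.all(lo1 <= lo0 + 1e-12)
            assert np.all(hi1 >= hi0 - 1e-12)

    def test_violated_constraints_refuse_to_evaluate(self, toy_dense_net, rng):
        inn = wrap_network(toy_dense_net, init_width=0.01)
        inn.weight_intervals[0].lower[0, 0] = \
            toy_dense_net.layers[0].W[0, 0] + 1.0
        with pytest.raises(ValueError):
            forward_interval(inn, rng.standard_normal((1, 4)))

    def test_conv_network_containment(self, rng):
        net = make_conv_net(n_layers=4, channels=6, kernel_size=3,
                            dropout_rate=0.0, seed=7)
        inn = wrap_network(net, init_width=0.03)
        z = rng.standard_normal((3, 1, 16))
        lo, hi, pred = forward_interval(inn, z)
        assert np.all(lo <= pred) and np.all(pred <= hi)
        np.testing.assert_allclose(pred, net.forward(z), atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_containment_property_random_dense_nets(net_seed):
    """For random small nets, inputs and widths: lower <= base <= upper."""
    r = np.random.default_rng(net_seed)
    dims = [int(d) for d in r.integers(1, 5, size=4)]
    layers = []
    for i in range(3):
        act = "identity" if i == 2 else "relu"
        layers.append(Dense(r.standard_normal((dims[i + 1], dims[i])),
                            r.standard_normal(dims[i + 1]), activation=act))
    net = PredictionNetwork(layers)
    inn = wrap_network(net, init_width=float(r.uniform(0, 0.3)))
    z = r.standard_normal((2, dims[0])) * 3
    lo, hi, pred = forward_interval(inn, z)
    assert np.all(lo <= pred) and np.all(pred <= hi)
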