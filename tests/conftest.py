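"""Shared fixtures and brute-force oracles.

The interval-propagation oracles enumerate the vertices of the parameter
(and input) boxes: a single affine layer followed by a monotone activation
is affine in each weight, bias and input entry separately, so the exact
component-wise output extremes are attained at box vertices.  This gives an
independent reference for the closed-form interval formulas.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from innuq.nets import Dense, PredictionNetwork


def _act(x, activation):
    return np.maximum(x, 0.0) if activation == "relu" else x


def oracle_point_layer(W_lo, W_hi, b_lo, b_hi, z, activation="relu"):
    """Vertex-enumeration bounds of act(Wz+b) over the parameter box."""
    W_lo, W_hi = np.atleast_2d(W_lo), np.atleast_2d(W_hi)
    b_lo, b_hi = np.atleast_1d(b_lo), np.atleast_1d(b_hi)
    z = np.atleast_1d(z)
    lo = np.full(b_lo.shape, np.inf)
    hi = np.full(b_lo.shape, -np.inf)
    w_entries = list(np.ndindex(W_lo.shape))
    b_entries = list(range(b_lo.size))
    n_par = len(w_entries) + len(b_entries)
    for bits in itertools.product((0, 1), repeat=n_par):
        W = W_lo.copy()
        b = b_lo.copy()
        for bit, idx in zip(bits[: len(w_entries)], w_entries):
            if bit:
                W[idx] = W_hi[idx]
        for bit, i in zip(bits[len(w_entries):], b_entries):
            if bit:
                b[i] = b_hi[i]
        out = _act(W @ z + b, activation)
        lo = np.minimum(lo, out)
        hi = np.maximum(hi, out)
    return lo, hi


def oracle_interval_layer(W_lo, W_hi, b_lo, b_hi, z_lo, z_hi,
                          activation="relu"):
    """Vertex-enumeration bounds over the parameter *and* input boxes."""
    W_lo, W_hi = np.atleast_2d(W_lo), np.atleast_2d(W_hi)
    b_lo, b_hi = np.atleast_1d(b_lo), np.atleast_1d(b_hi)
    z_lo, z_hi = np.atleast_1d(z_lo), np.atleast_1d(z_hi)
    lo = np.full(b_lo.shape, np.inf)
    hi = np.full(b_lo.shape, -np.inf)
    for z_bits in itertools.product((0, 1), repeat=z_lo.size):
        z = np.where(np.array(z_bits, dtype=bool), z_hi, z_lo)
        l2, h2 = oracle_point_layer(W_lo, W_hi, b_lo, b_hi, z, activation)
        lo = np.minimum(lo, l2)
        hi = np.maximum(hi, h2)
    return lo, hi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dense_net(rng):
    """A small 3-layer dense ReLU network with signed identity output."""
    layers = [
        Dense(rng.standard_normal((8, 4)) * 0.6, rng.standard_normal(8) * 0.1),
        Dense(rng.standard_normal((6, 8)) * 0.5, rng.standard_normal(6) * 0.1),
        Dense(rng.standard_normal((4, 6)) * 0.5, rng.standard_normal(4) * 0.1,
              activation="identity"),
    ]
    return PredictionNetwork(layers)
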