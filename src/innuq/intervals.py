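"""Interval arithmetic forward propagation through ReLU networks.

An interval neural network (INN) wraps a trained prediction network with
per-layer parameter intervals [W_lo, W_hi], [b_lo, b_hi] that contain the
base parameters.  Propagating an input through the network with interval
arithmetic yields component-wise output bounds that are guaranteed to
contain the base prediction, and — more strongly — the output of *any*
network whose parameters are selected inside the intervals.

Two propagation cases suffice for ReLU architectures:

* a point input to the first layer (the input itself may be signed), and
* a nonnegative interval input to every later layer (guaranteed after ReLU).

For a point input z with z+ = max(z,0), z- = min(z,0):

    upper = act( W_hi z+ + W_lo z- + b_hi )
    lower = act( W_lo z+ + W_hi z- + b_lo )

For a nonnegative interval input [z_lo, z_hi]:

    upper = act( min(W_hi,0) z_lo + max(W_hi,0) z_hi + b_hi )
    lower = act( max(W_lo,0) z_lo + min(W_lo,0) z_hi + b_lo )

with all max/min taken component-wise.  Architectures where a *signed*
interval could reach a hidden layer (i.e. non-ReLU hidden activations) are
rejected at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nets import _as_float, from_internal, to_internal

__all__ = [
    "IntervalBox",
    "IntervalNetwork",
    "propagate_point_input",
    "propagate_nonneg_interval",
    "wrap_network",
    "forward_interval",
]


@dataclass(frozen=True)
class IntervalBox:
    """A pair of arrays bounding a quantity component-wise: lower <= upper."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = _as_float(self.lower)
        hi = _as_float(self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("lower/upper shape mismatch")
        if not np.all(lo <= hi):
            raise ValueError("interval invariant violated: lower > upper somewhere")

    @classmethod
    def point(cls, a) -> "IntervalBox":
        a = np.asarray(a, dtype=float)
        return cls(a.copy(), a.copy())

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x, atol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(self.lower - atol <= x) and np.all(x <= self.upper + atol)
        )


def _activate(lo, hi, activation):
    if activation == "relu":
        return np.maximum(lo, 0.0), np.maximum(hi, 0.0)
    if activation == "identity":
        return lo, hi
    raise ValueError(f"unknown activation {activation!r}")


#: relative outward-rounding slack applied per layer during full-network
#: propagation.  Floating-point sums of a few hundred terms carry rounding
#: error up to ~n_ops * eps relative to the sum of absolute terms (~3.5e-14
#: here); 1e-12 covers this with ample margin, so the computed bounds are a
#: rigorous envelope despite round-to-nearest arithmetic.
OUTWARD_GAMMA = 1e-12


def _point_bounds(layer, w_box, b_box, z, outward: float = 0.0):
    """Pre-activation bounds for a point input (internal layout)."""
    ctx_p = layer.prepare(np.maximum(z, 0.0))
    ctx_n = layer.prepare(np.minimum(z, 0.0))
    Wl, Wh = w_box.lower, w_box.upper
    hi = layer.add_bias(layer.affine(ctx_p, Wh) + layer.affine(ctx_n, Wl),
                        b_box.upper)
    lo = layer.add_bias(layer.affine(ctx_p, Wl) + layer.affine(ctx_n, Wh),
                        b_box.lower)
    if outward:
        err = _rounding_slack(layer, w_box, b_box,
                              layer.prepare(np.abs(z)), outward)
        lo = lo - err
        hi = hi + err
    return lo, hi, ctx_p, ctx_n


def _nonneg_bounds(layer, w_box, b_box, z_lo, z_hi, outward: float = 0.0):
    """Pre-activation bounds for a nonnegative interval input (internal)."""
    ctx_l = layer.prepare(z_lo)
    ctx_h = layer.prepare(z_hi)
    Wl, Wh = w_box.lower, w_box.upper
    hi = layer.add_bias(
        layer.affine(ctx_l, np.minimum(Wh, 0.0))
        + layer.affine(ctx_h, np.maximum(Wh, 0.0)),
        b_box.upper,
    )
    lo = layer.add_bias(
        layer.affine(ctx_l, np.maximum(Wl, 0.0))
        + layer.affine(ctx_h, np.minimum(Wl, 0.0)),
        b_box.lower,
    )
    if outward:
        # z_hi dominates |z| for nonnegative inputs
        err = _rounding_slack(layer, w_box, b_box, ctx_h, outward)
        lo = lo - err
        hi = hi + err
    return lo, hi, ctx_l, ctx_h


def _rounding_slack(layer, w_box, b_box, ctx_abs, gamma):
    """Per-component bound on the affine map's floating-point error."""
    absW = np.maximum(np.abs(w_box.lower), np.abs(w_box.upper))
    absb = np.maximum(np.abs(b_box.lower), np.abs(b_box.upper))
    mag = layer.add_bias(layer.affine(ctx_abs, absW), absb)
    return gamma * mag


def _check_shapes(layer, w_box: IntervalBox, b_box: IntervalBox):
    if w_box.lower.shape != layer.weight_shape:
        raise ValueError("weight interval shape does not match layer")
    if b_box.lower.shape != layer.b.shape:
        raise ValueError("bias interval shape does not match layer")


def propagate_point_input(layer, w_box: IntervalBox, b_box: IntervalBox, z,
                          activation: str | None = None) -> IntervalBox:
    """Propagate a (possibly signed) point input through one interval layer.

    ``z`` is in public layout: (B, D) for dense layers, (B, C, L) for
    convolutions; the returned box matches.
    """
    _check_shapes(layer, w_box, b_box)
    act = layer.activation if activation is None else activation
    conv = layer.kind == "conv1d"
    zi = to_internal(z, conv)
    lo, hi, _, _ = _point_bounds(layer, w_box, b_box, zi)
    lo, hi = _activate(lo, hi, act)
    return IntervalBox(from_internal(lo, conv), from_internal(hi, conv))


def propagate_nonneg_interval(layer, w_box: IntervalBox, b_box: IntervalBox,
                              z_box: IntervalBox,
                              activation: str | None = None) -> IntervalBox:
    """Propagate a nonnegative interval input through one interval layer.

    Requires ``z_box.lower >= 0`` (guaranteed after a ReLU layer); for signed
    point inputs use :func:`propagate_point_input` instead.
    """
    if np.any(z_box.lower < 0):
        raise ValueError(
            "nonnegative-interval propagation requires z_box.lower >= 0"
        )
    _check_shapes(layer, w_box, b_box)
    act = layer.activation if activation is None else activation
    conv = layer.kind == "conv1d"
    z_lo = to_internal(z_box.lower, conv)
    z_hi = to_internal(z_box.upper, conv)
    lo, hi, _, _ = _nonneg_bounds(layer, w_box, b_box, z_lo, z_hi)
    lo, hi = _activate(lo, hi, act)
    return IntervalBox(from_internal(lo, conv), from_internal(hi, conv))


class IntervalNetwork:
    """A prediction network plus parameter intervals and tightness ``beta``.

    Layers not listed in ``interval_layers`` carry point intervals equal to
    the base parameters.  Construction validates the box constraints
    ``W_lo <= W <= W_hi`` and ``b_lo <= b <= b_hi`` for every layer; these
    are what make the output interval a guaranteed envelope of the base
    prediction.
    """

    def __init__(self, base, weight_intervals, bias_intervals,
                 interval_layers=None, beta: float = 0.0):
        n = base.n_layers
        if len(weight_intervals) != n or len(bias_intervals) != n:
            raise ValueError("need one weight and one bias interval per layer")
        if interval_layers is None:
            interval_layers = tuple(range(n))
        interval_layers = tuple(sorted(set(int(i) for i in interval_layers)))
        if interval_layers and not (0 <= interval_layers[0]
                                    and interval_layers[-1] < n):
            raise ValueError("interval_layers out of range")
        if beta < 0:
            raise ValueError("beta must be nonnegative")
        self.base = base
        self.weight_intervals = list(weight_intervals)
        self.bias_intervals = list(bias_intervals)
        self.interval_layers = interval_layers
        self.beta = float(beta)
        self.validate()

    def validate(self, atol: float = 0.0):
        """Check the box constraints against the (frozen) base parameters."""
        for i, lay in enumerate(self.base.layers):
            wb, bb = self.weight_intervals[i], self.bias_intervals[i]
            if wb.lower.shape != lay.W.shape or bb.lower.shape != lay.b.shape:
                raise ValueError(f"interval shape mismatch at layer {i}")
            if not (wb.contains(lay.W, atol) and bb.contains(lay.b, atol)):
                raise ValueError(
                    f"parameter constraints violated at layer {i}: base "
                    "parameters not inside their intervals"
                )

    def interval_parameters(self):
        """The trainable interval arrays (W_lo, W_hi, b_lo, b_hi) per
        interval-equipped layer, as a flat list of views."""
        out = []
        for i in self.interval_layers:
            wb, bb = self.weight_intervals[i], self.bias_intervals[i]
            out.extend([wb.lower, wb.upper, bb.lower, bb.upper])
        return out


def wrap_network(base, interval_layers=None, init_width: float = 0.0,
                 eps0: float = 1e-6, beta: float = 0.0) -> IntervalNetwork:
    """Construct an INN around a trained network (post hoc).

    Each interval-equipped layer gets ``[W - init_width*|W| - eps0,
    W + init_width*|W| + eps0]`` (and likewise for biases), so the box
    constraints hold by construction.  ``eps0`` is a tiny absolute floor so
    width gradients are nonzero from the start; ``init_width=0`` starts at
    the guaranteed-valid (near-point) configuration.
    """
    if init_width < 0:
        raise ValueError("init_width must be nonnegative")
    n = base.n_layers
    if interval_layers is None:
        interval_layers = tuple(range(n))
    interval_set = set(int(i) for i in interval_layers)
    if not interval_set.issubset(range(n)):
        raise ValueError("interval_layers must be a subset of base layers")
    w_boxes, b_boxes = [], []
    for i, lay in enumerate(base.layers):
        if i in interval_set:
            dw = init_width * np.abs(lay.W) + eps0
            db = init_width * np.abs(lay.b) + eps0
            w_boxes.append(IntervalBox(lay.W - dw, lay.W + dw))
            b_boxes.append(IntervalBox(lay.b - db, lay.b + db))
        else:
            w_boxes.append(IntervalBox.point(lay.W))
            b_boxes.append(IntervalBox.point(lay.b))
    return IntervalNetwork(base, w_boxes, b_boxes,
                           interval_layers=sorted(interval_set), beta=beta)


def forward_interval(inn: IntervalNetwork, z, validate: bool = True):
    """Propagate ``z`` through the INN.

    Returns ``(lower, upper, prediction)`` in public layout, where
    ``prediction`` is the base network output (dropout off) and
    ``lower <= prediction <= upper`` component-wise.  Refuses to evaluate if
    the parameter constraints are violated, since that would void the
    containment guarantee.
    """
    if validate:
        inn.validate()
    conv = inn.base.conv
    layers = inn.base.layers
    zi = to_internal(z, conv)
    lo, hi, _, _ = _point_bounds(
        layers[0], inn.weight_intervals[0], inn.bias_intervals[0], zi,
        outward=OUTWARD_GAMMA,
    )
    lo, hi = _activate(lo, hi, layers[0].activation)
    for i in range(1, len(layers)):
        lo, hi, _, _ = _nonneg_bounds(
            layers[i], inn.weight_intervals[i], inn.bias_intervals[i], lo, hi,
            outward=OUTWARD_GAMMA,
        )
        lo, hi = _activate(lo, hi, layers[i].activation)
    prediction = inn.base.forward(z)
    return from_internal(lo, conv), from_internal(hi, conv), prediction


# ---------------------------------------------------------------------------
# Cached interval forward/backward used by interval training.  The interval
# formulas are piecewise linear in the parameter bounds, so backpropagation
# only needs the ReLU masks and the sign patterns of W_lo / W_hi.
# ---------------------------------------------------------------------------


def interval_forward_cached(inn: IntervalNetwork, z):
    """Interval forward pass retaining caches for ``interval_backward``.

    Input and output bounds are in public layout; caches stay internal.
    Leading layers that carry point intervals (interval training restricted
    to a trailing subset) keep the running interval degenerate, so they are
    evaluated with a single affine pass instead of the four-term interval
    form; no gradient flows below the first interval-equipped layer.
    """
    conv = inn.base.conv
    layers = inn.base.layers
    first_interval = min(inn.interval_layers) if inn.interval_layers else 0
    caches = []
    lo = hi = None
    a = to_internal(z, conv)
    point = True  # running interval is degenerate (lo == hi == a)
    for i, lay in enumerate(layers):
        wb, bb = inn.weight_intervals[i], inn.bias_intervals[i]
        if point and i < first_interval and np.all(wb.width == 0) \
                and np.all(bb.width == 0):
            W = wb.lower.astype(a.dtype, copy=False)
            b = bb.lower.astype(a.dtype, copy=False)
            pre = lay.add_bias(lay.affine(lay.prepare(a), W), b)
            a = np.maximum(pre, 0.0) if lay.activation == "relu" else pre
            caches.append(dict(kind="degenerate"))
            continue
        if point:
            lo_pre, hi_pre, ctx_a, ctx_b = _point_bounds(lay, wb, bb, a)
            kind = "point"
            point = False
        else:
            lo_pre, hi_pre, ctx_a, ctx_b = _nonneg_bounds(lay, wb, bb, lo, hi)
            kind = "nonneg"
        lo, hi = _activate(lo_pre, hi_pre, lay.activation)
        relu = lay.activation == "relu"
        caches.append(dict(kind=kind, ctx_a=ctx_a, ctx_b=ctx_b,
                           mask_lo=lo_pre > 0 if relu else None,
                           mask_hi=hi_pre > 0 if relu else None))
    return from_internal(lo, conv), from_internal(hi, conv), caches


def interval_backward(inn: IntervalNetwork, caches, g_lo, g_hi):
    """Backpropagate gradients w.r.t. the output bounds to the interval
    parameters.

    ``g_lo``/``g_hi`` are in public layout.  Returns a dict
    ``layer index -> (dW_lo, dW_hi, db_lo, db_hi)`` for the interval-equipped
    layers.  Subgradients at kinks (ReLU at 0, weight-bound sign changes at
    0) take the right-hand branch.
    """
    conv = inn.base.conv
    layers = inn.base.layers
    need = set(inn.interval_layers)
    min_needed = min(need) if need else 0
    grads: dict[int, tuple] = {}
    g_lo = to_internal(g_lo, conv)
    g_hi = to_internal(g_hi, conv)
    for i in range(len(layers) - 1, -1, -1):
        lay = layers[i]
        c = caches[i]
        if c["mask_lo"] is not None:
            g_lo = g_lo * c["mask_lo"]
            g_hi = g_hi * c["mask_hi"]
        wb = inn.weight_intervals[i]
        Wl, Wh = wb.lower, wb.upper
        if i in need:
            if c["kind"] == "point":
                # hi = Wh z+ + Wl z- ; lo = Wl z+ + Wh z-
                dWh = lay.weight_grad(g_hi, c["ctx_a"]) \
                    + lay.weight_grad(g_lo, c["ctx_b"])
                dWl = lay.weight_grad(g_lo, c["ctx_a"]) \
                    + lay.weight_grad(g_hi, c["ctx_b"])
            else:
                # hi = min(Wh,0) z_lo + max(Wh,0) z_hi
                dWh = np.where(Wh < 0,
                               lay.weight_grad(g_hi, c["ctx_a"]),
                               lay.weight_grad(g_hi, c["ctx_b"]))
                # lo = max(Wl,0) z_lo + min(Wl,0) z_hi
                dWl = np.where(Wl > 0,
                               lay.weight_grad(g_lo, c["ctx_a"]),
                               lay.weight_grad(g_lo, c["ctx_b"]))
            grads[i] = (dWl, dWh, lay.bias_grad(g_lo), lay.bias_grad(g_hi))
        if i == 0 or i <= min_needed:
            break  # nothing below needs a gradient
        if c["kind"] == "nonneg":
            new_g_lo = lay.input_grad(g_hi, np.minimum(Wh, 0.0)) \
                + lay.input_grad(g_lo, np.maximum(Wl, 0.0))
            new_g_hi = lay.input_grad(g_hi, np.maximum(Wh, 0.0)) \
                + lay.input_grad(g_lo, np.minimum(Wl, 0.0))
            g_lo, g_hi = new_g_lo, new_g_hi
    return grads
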