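"""Post-hoc training of interval parameters.

The base network stays frozen; only the per-layer parameter intervals are
optimized.  The empirical loss over samples (z_i, x_i) is

    sum_i ||max(x_i - upper_i, 0)||_2^2 + ||max(lower_i - x_i, 0)||_2^2
          + beta * ||upper_i - lower_i||_1

where [lower_i, upper_i] is the propagated output interval for z_i.  The two
hinge terms push the interval to cover the target; the l1 width penalty keeps
it tight, with the tightness parameter beta trading coverage against
tightness.  The box constraints W_lo <= W <= W_hi (and likewise for biases)
are maintained by exact projection — clamping against the frozen base
parameters — after every optimizer step, so the containment guarantee holds
at all times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import (
    IntervalNetwork,
    interval_backward,
    interval_forward_cached,
    wrap_network,
)
from .nets import Adam, PredictionNetwork

__all__ = [
    "TrainingConfig",
    "interval_loss",
    "project_constraints",
    "train_inn",
    "select_beta",
]


@dataclass
class TrainingConfig:
    """Hyperparameters for interval training.

    beta : l1 tightness penalty weight (>= 0); ``None`` means "select from
        the base network's mean absolute error" (see :func:`select_beta`).
    interval_layers : which layers carry trainable intervals (None = all).
    """

    beta: float | None = None
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    interval_layers: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid batch size or learning rate")


def interval_loss(x, lo, hi, beta: float) -> float:
    """Hinge-coverage loss plus l1 width penalty, summed over the batch."""
    x = np.asarray(x, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo > hi):
        raise ValueError("invalid interval: lo > hi")
    over = np.maximum(x - hi, 0.0)
    under = np.maximum(lo - x, 0.0)
    return float(
        np.sum(over * over) + np.sum(under * under) + beta * np.sum(hi - lo)
    )


def _interval_loss_grads(x, lo, hi, beta):
    over = np.maximum(x - hi, 0.0)
    under = np.maximum(lo - x, 0.0)
    loss = np.sum(over * over) + np.sum(under * under) + beta * np.sum(hi - lo)
    d_hi = -2.0 * over + beta
    d_lo = 2.0 * under - beta
    return float(loss), d_lo, d_hi


def _project_against(inn: IntervalNetwork, base_params) -> IntervalNetwork:
    for i, (W, b) in enumerate(base_params):
        wb, bb = inn.weight_intervals[i], inn.bias_intervals[i]
        np.minimum(wb.lower, W, out=wb.lower, casting="same_kind")
        np.maximum(wb.upper, W, out=wb.upper, casting="same_kind")
        np.minimum(bb.lower, b, out=bb.lower, casting="same_kind")
        np.maximum(bb.upper, b, out=bb.upper, casting="same_kind")
    return inn


def project_constraints(inn: IntervalNetwork) -> IntervalNetwork:
    """Clamp interval bounds so they contain the frozen base parameters.

    W_lo <- min(W_lo, W), W_hi <- max(W_hi, W) (same for biases), in place.
    Total: always succeeds, and afterwards all INN invariants hold.
    """
    return _project_against(inn, [(lay.W, lay.b) for lay in inn.base.layers])


def _cast_box(box, dtype):
    from .intervals import IntervalBox

    return IntervalBox(box.lower.astype(dtype), box.upper.astype(dtype))


def select_beta(base: PredictionNetwork, inputs, targets,
                floor: float = 1e-8, batch_size: int = 64) -> float:
    """Tightness parameter heuristic: the mean absolute prediction error of
    the base network over the samples, floored at ``floor``."""
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    total = 0.0
    count = 0
    for start in range(0, inputs.shape[0], batch_size):
        z = inputs[start : start + batch_size]
        x = targets[start : start + batch_size]
        pred = base.forward(z)
        total += float(np.sum(np.abs(pred - x)))
        count += x.size
    return max(total / count, floor)


def train_inn(inn: IntervalNetwork, inputs, targets, cfg: TrainingConfig):
    """Optimize the interval parameters of ``inn`` (in place).

    Adam steps on the interval bounds of the layers in
    ``inn.interval_layers``, with exact projection onto the box constraints
    after every step.  Returns ``(inn, history)`` where ``history`` is the
    per-epoch mean (per-sample) training loss.  The base network is never
    touched.

    The optimization itself runs in single precision (ample for stochastic
    gradients); the intervals are cast back to float64 and re-projected
    against the float64 base parameters afterwards, so the containment
    guarantee holds exactly at evaluation precision.
    """
    from .intervals import IntervalBox

    if np.asarray(inputs).shape[0] == 0:
        raise ValueError("need at least one training sample")
    beta = cfg.beta
    if beta is None:
        beta = select_beta(inn.base, inputs, targets)
    inn.beta = float(beta)
    inputs = np.asarray(inputs).astype(np.float32)
    targets = np.asarray(targets).astype(np.float32)
    for i in range(inn.base.n_layers):
        inn.weight_intervals[i] = _cast_box(inn.weight_intervals[i], np.float32)
        inn.bias_intervals[i] = _cast_box(inn.bias_intervals[i], np.float32)
    base32 = [(lay.W.astype(np.float32), lay.b.astype(np.float32))
              for lay in inn.base.layers]
    rng = np.random.default_rng(cfg.seed)
    params = inn.interval_parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    n = inputs.shape[0]
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z, x = inputs[idx], targets[idx]
            lo, hi, caches = interval_forward_cached(inn, z)
            batch_loss, d_lo, d_hi = _interval_loss_grads(x, lo, hi, beta)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite interval loss at epoch {epoch}")
            scale = 1.0 / len(idx)
            grads = interval_backward(inn, caches, d_lo * scale, d_hi * scale)
            flat = []
            for i in inn.interval_layers:
                dWl, dWh, dbl, dbh = grads[i]
                flat.extend([dWl, dWh, dbl, dbh])
            opt.step(flat)
            _project_against(inn, base32)
            epoch_loss += batch_loss
        history.append(epoch_loss / n)
    for i in range(inn.base.n_layers):
        inn.weight_intervals[i] = _cast_box(inn.weight_intervals[i], np.float64)
        inn.bias_intervals[i] = _cast_box(inn.bias_intervals[i], np.float64)
    project_constraints(inn)
    inn.validate()
    return inn, history
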