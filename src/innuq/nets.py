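"""Minimal feed-forward network core: dense and 1D convolution layers.

Networks here are plain containers of NumPy parameter arrays with explicit
forward/backward passes.  Only what the interval wrapper needs is supported:
affine layers (dense or stride-1 "same" 1D convolution), ReLU hidden
activations, an identity output activation, and inverted dropout at
designated sites.

Each layer kind exposes the same small affine API so that interval
propagation can drive it with arbitrary substituted weight/bias arrays
(bounds, or sign-split parts of bounds):

* ``prepare(a)``        -> context for the layer input (padding for conv)
* ``affine(ctx, W)``    -> W applied to the prepared input, no bias
* ``input_grad(g, W)``  -> gradient w.r.t. the (unpadded) layer input
* ``weight_grad(g, ctx)`` / ``bias_grad(g)``

Convolution layers operate internally in channel-major layout (C, B, L) so
that the kernel taps become full-width matrix products on contiguous
blocks; the public network API still takes batches shaped (B, C, L).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1d",
    "PredictionNetwork",
    "ProbOutNetwork",
    "Adam",
    "train_network",
    "make_conv_net",
    "make_probout_net",
]

_ACTIVATIONS = ("relu", "identity")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _as_float(a) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float64)
    return a


class Dense:
    """Fully connected affine layer ``x -> x @ W.T + b``; data shape (B, D)."""

    kind = "dense"

    def __init__(self, W, b, activation: str = "relu"):
        self.W = np.asarray(W, dtype=float)
        self.b = np.asarray(b, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("dense weight must be 2-D")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("bias shape mismatch")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    @property
    def weight_shape(self):
        return self.W.shape

    def prepare(self, a: np.ndarray):
        a = _as_float(a)
        if a.ndim != 2 or a.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"dense layer expects input (B, {self.W.shape[1]}), got {a.shape}"
            )
        return a

    def affine(self, ctx, W=None) -> np.ndarray:
        W = self.W if W is None else W
        return ctx @ W.T

    def add_bias(self, out, b=None) -> np.ndarray:
        return out + (self.b if b is None else b)

    def input_grad(self, g, W=None) -> np.ndarray:
        W = self.W if W is None else W
        return g @ W

    def weight_grad(self, g, ctx) -> np.ndarray:
        return g.T @ ctx

    def bias_grad(self, g) -> np.ndarray:
        return g.sum(axis=0)


class Conv1d:
    """Stride-1 "same" 1D convolution (cross-correlation) with odd kernel.

    Weight shape is (C_out, C_in, K); data flows through in channel-major
    layout (C, B, L).  ``prepare`` zero-pads once; every kernel tap is then
    one full-width matrix product accumulated with a shifted view, which
    keeps all heavy operations inside BLAS.
    """

    kind = "conv1d"

    def __init__(self, W, b, activation: str = "relu"):
        self.W = np.asarray(W, dtype=float)
        self.b = np.asarray(b, dtype=float)
        if self.W.ndim != 3:
            raise ValueError("conv1d weight must be 3-D (C_out, C_in, K)")
        if self.W.shape[2] % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("bias shape mismatch")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    @property
    def weight_shape(self):
        return self.W.shape

    def prepare(self, a: np.ndarray):
        """Zero-pad channel-major input (C, B, L) -> (C, B, L + K - 1)."""
        a = _as_float(a)
        c_out, c_in, k = self.W.shape
        if a.ndim != 3 or a.shape[0] != c_in:
            raise ValueError(
                f"conv1d layer expects input ({c_in}, B, L), got {a.shape}"
            )
        pad = k // 2
        c, b, length = a.shape
        ap = np.zeros((c, b, length + 2 * pad), dtype=a.dtype)
        ap[:, :, pad : pad + length] = a
        return ap

    def affine(self, ctx, W=None) -> np.ndarray:
        W = self.W if W is None else W
        c_out, c_in, k = W.shape
        c, b, lp = ctx.shape
        length = lp - (k - 1)
        # all taps at once: (K*C_out, C_in) @ (C_in, B*Lp)
        W2 = np.ascontiguousarray(W.transpose(2, 0, 1)).reshape(k * c_out, c_in)
        out_all = (W2 @ ctx.reshape(c_in, b * lp)).reshape(k, c_out, b, lp)
        acc = np.zeros((c_out, b, length), dtype=np.result_type(W, ctx))
        for kk in range(k):
            acc += out_all[kk][:, :, kk : kk + length]
        return acc

    def add_bias(self, out, b=None) -> np.ndarray:
        bias = self.b if b is None else b
        return out + bias[:, None, None]

    def input_grad(self, g, W=None) -> np.ndarray:
        W = self.W if W is None else W
        c_out, c_in, k = W.shape
        _, b, length = g.shape
        pad = k // 2
        Wt = np.ascontiguousarray(W.transpose(2, 1, 0)).reshape(k * c_in, c_out)
        tmp = (Wt @ g.reshape(c_out, b * length)).reshape(k, c_in, b, length)
        dap = np.zeros((c_in, b, length + 2 * pad),
                       dtype=np.result_type(W, g))
        for kk in range(k):
            dap[:, :, kk : kk + length] += tmp[kk]
        return dap[:, :, pad : pad + length]

    def weight_grad(self, g, ctx) -> np.ndarray:
        c_out, c_in, k = self.W.shape
        _, b, lp = ctx.shape
        length = lp - (k - 1)
        g2 = g.reshape(c_out, b * length)
        dW = np.empty((c_out, c_in, k), dtype=np.result_type(g, ctx))
        for kk in range(k):
            sl = np.ascontiguousarray(ctx[:, :, kk : kk + length])
            dW[:, :, kk] = g2 @ sl.reshape(c_in, b * length).T
        return dW

    def bias_grad(self, g) -> np.ndarray:
        return g.sum(axis=(1, 2))


def to_internal(z: np.ndarray, conv: bool) -> np.ndarray:
    """Public batch (B, C, L) -> internal channel-major (C, B, L)."""
    z = _as_float(z)
    return z.transpose(1, 0, 2) if conv else z


def from_internal(a: np.ndarray, conv: bool) -> np.ndarray:
    return a.transpose(1, 0, 2) if conv else a


class PredictionNetwork:
    """An ordered stack of affine+activation layers with optional dropout.

    All hidden activations must be ReLU (interval propagation relies on
    nonnegative hidden states); the final activation may be identity so that
    reconstructions can be signed.  ``dropout_sites`` maps a layer index to a
    dropout rate applied to that layer's activation output; dropout is active
    only when a random generator is passed to :meth:`forward`.
    """

    def __init__(self, layers, dropout_sites: dict[int, float] | None = None):
        layers = list(layers)
        if not layers:
            raise ValueError("network needs at least one layer")
        kinds = {lay.kind for lay in layers}
        if len(kinds) > 1:
            raise ValueError("mixed dense/conv networks are not supported")
        for lay in layers[:-1]:
            if lay.activation != "relu":
                raise ValueError("hidden activations must be ReLU")
        self.layers = layers
        self.conv = layers[0].kind == "conv1d"
        self.dropout_sites = dict(dropout_sites or {})
        for idx, rate in self.dropout_sites.items():
            if not 0 <= idx < len(layers):
                raise ValueError(f"dropout site {idx} out of range")
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rate must be in [0, 1)")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend([lay.W, lay.b])
        return out

    def forward(self, z: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Evaluate the network on a batch (B, C, L) or (B, D).

        Deterministic when ``dropout_rng`` is None (dropout disabled).
        """
        a = to_internal(z, self.conv)
        for i, lay in enumerate(self.layers):
            ctx = lay.prepare(a)
            pre = lay.add_bias(lay.affine(ctx))
            a = _relu(pre) if lay.activation == "relu" else pre
            if dropout_rng is not None and i in self.dropout_sites:
                rate = self.dropout_sites[i]
                if rate > 0:
                    mask = dropout_rng.random(a.shape) >= rate
                    a = a * (mask.astype(a.dtype) / a.dtype.type(1.0 - rate))
        return from_internal(a, self.conv)

    def forward_cached(self, z, dropout_rng=None):
        """Forward pass retaining per-layer caches for :meth:`backward`."""
        a = to_internal(z, self.conv)
        caches = []
        for i, lay in enumerate(self.layers):
            ctx = lay.prepare(a)
            pre = lay.add_bias(lay.affine(ctx))
            a = _relu(pre) if lay.activation == "relu" else pre
            mask = pre > 0 if lay.activation == "relu" else None
            dmask = None
            if dropout_rng is not None and i in self.dropout_sites:
                rate = self.dropout_sites[i]
                if rate > 0:
                    keep = dropout_rng.random(a.shape) >= rate
                    dmask = keep.astype(a.dtype) / a.dtype.type(1.0 - rate)
                    a = a * dmask
            caches.append((ctx, mask, dmask))
        return from_internal(a, self.conv), caches

    def backward(self, caches, gout: np.ndarray):
        """Backpropagate ``gout`` (gradient w.r.t. the output).

        Returns (list of (dW, db) per layer, gradient w.r.t. the input),
        both in public layout.
        """
        g = to_internal(gout, self.conv)
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            lay = self.layers[i]
            ctx, mask, dmask = caches[i]
            if dmask is not None:
                g = g * dmask
            if mask is not None:
                g = g * mask
            grads[i] = (lay.weight_grad(g, ctx), lay.bias_grad(g))
            g = lay.input_grad(g)
        return grads, from_internal(g, self.conv)

    def input_gradient(self, z, gout):
        """Gradient of ``sum(forward(z) * gout)`` w.r.t. ``z`` (dropout off)."""
        _, caches = self.forward_cached(z)
        _, dz = self.backward(caches, gout)
        return dz


class ProbOutNetwork:
    """Direct variance estimation: the output head is doubled into a mean
    channel and a log-variance channel; the variance is ``exp`` of the latter
    and therefore strictly positive by construction."""

    def __init__(self, net: PredictionNetwork):
        n_out = net.layers[-1].weight_shape[0]
        if n_out % 2 != 0:
            raise ValueError("ProbOut network must have an even number of outputs")
        self.net = net

    def forward(self, z, dropout_rng=None):
        out = self.net.forward(z, dropout_rng=dropout_rng)
        mean, logvar = _split_head(out)
        return mean, np.exp(logvar)

    def predict(self, z):
        return self.forward(z)[0]

    def uncertainty(self, z):
        return np.sqrt(self.forward(z)[1])


def _split_head(out: np.ndarray):
    c = out.shape[1] // 2
    return out[:, :c], out[:, c:]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mse_loss_grad(out, x):
    r = out - x
    n = r.size
    return float(np.mean(r * r)), (2.0 / n) * r


def _probout_loss_grad(out, x):
    mean, logvar = _split_head(out)
    r = x - mean
    inv_var = np.exp(-logvar)
    n = r.size
    loss = float(np.sum(r * r * inv_var) + np.sum(np.abs(logvar))) / n
    dmean = (-2.0 * r * inv_var) / n
    dlogvar = (-(r * r) * inv_var + np.sign(logvar)) / n
    return loss, np.concatenate([dmean, dlogvar], axis=1)


def train_network(
    net: PredictionNetwork,
    inputs: np.ndarray,
    targets: np.ndarray,
    *,
    epochs: int = 100,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    loss: str = "mse",
    use_dropout: bool = True,
    compute_dtype=np.float32,
):
    """Train a network with Adam on mini-batches; returns per-epoch mean loss.

    ``loss='mse'`` fits reconstruction targets; ``loss='probout'`` fits a
    doubled mean/log-variance head with the Gaussian-likelihood-style loss
    ``sum((x-mean)^2/var) + sum(|log var|)`` (per-component mean for scaling).

    Optimization runs in ``compute_dtype`` (single precision by default,
    ample for stochastic gradient training); the stored parameters are cast
    back to float64 afterwards so evaluation precision is unaffected.
    """
    if loss == "mse":
        loss_grad = _mse_loss_grad
    elif loss == "probout":
        loss_grad = _probout_loss_grad
    else:
        raise ValueError(f"unknown loss {loss!r}")
    rng = np.random.default_rng(seed)
    for lay in net.layers:
        lay.W = lay.W.astype(compute_dtype)
        lay.b = lay.b.astype(compute_dtype)
    inputs = np.asarray(inputs).astype(compute_dtype)
    targets = np.asarray(targets).astype(compute_dtype)
    opt = Adam(net.parameters(), lr=learning_rate)
    n = inputs.shape[0]
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            z, x = inputs[idx], targets[idx]
            drng = rng if (use_dropout and net.dropout_sites) else None
            out, caches = net.forward_cached(z, dropout_rng=drng)
            batch_loss, g = loss_grad(out, x)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            grads, _ = net.backward(caches, g)
            flat = [a for pair in grads for a in pair]
            opt.step(flat)
            epoch_loss += batch_loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    for lay in net.layers:
        lay.W = lay.W.astype(np.float64)
        lay.b = lay.b.astype(np.float64)
    return history


def make_conv_net(
    n_layers: int = 10,
    channels: int = 32,
    kernel_size: int = 5,
    in_channels: int = 1,
    out_channels: int = 1,
    dropout_rate: float = 0.1,
    dropout_sites: tuple[int, ...] | None = None,
    seed: int = 0,
) -> PredictionNetwork:
    """Build the 1D reconstruction network: ``n_layers`` convolutions with
    ReLU, identity on the last, and three dropout sites interleaved.

    He-normal initialization; defaults give the ten-layer architecture used
    for the deconvolution benchmark.
    """
    rng = np.random.default_rng(seed)
    layers = []
    for i in range(n_layers):
        c_in = in_channels if i == 0 else channels
        c_out = out_channels if i == n_layers - 1 else channels
        std = np.sqrt(2.0 / (c_in * kernel_size))
        W = rng.normal(0.0, std, size=(c_out, c_in, kernel_size))
        b = np.zeros(c_out)
        act = "identity" if i == n_layers - 1 else "relu"
        layers.append(Conv1d(W, b, activation=act))
    if dropout_sites is None:
        # three sites spread through the hidden stack
        dropout_sites = (n_layers // 4, n_layers // 2, (3 * n_layers) // 4)
    sites = {i: dropout_rate for i in dropout_sites} if dropout_rate > 0 else {}
    return PredictionNetwork(layers, dropout_sites=sites)


def make_probout_net(
    n_layers: int = 10,
    channels: int = 32,
    kernel_size: int = 5,
    in_channels: int = 1,
    seed: int = 0,
) -> ProbOutNetwork:
    """Build a ProbOut variant of the 1D network (doubled output head)."""
    net = make_conv_net(
        n_layers=n_layers,
        channels=channels,
        kernel_size=kernel_size,
        in_channels=in_channels,
        out_channels=2,
        dropout_rate=0.0,
        seed=seed,
    )
    return ProbOutNetwork(net)
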