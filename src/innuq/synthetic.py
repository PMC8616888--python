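"""Synthetic 1D deconvolution benchmark.

The forward operator is A = D^T S D with D an orthonormal Type-I discrete
cosine transform and S diagonal with entries

    s_j = ((n - j) / (n - 1))^nu,   j = 1..n,

so s_1 = 1, s_n = 0 and all eigenvalues lie in [0, 1]; the decay exponent
``nu`` controls how ill-posed the deconvolution is (reference: n = m = 512,
nu = 8).  Signals are piecewise-constant vectors with random jump positions
and plateau heights in [0, 1].  Measurements are y = A x + eta with optional
Gaussian noise on the measurements and/or the signal; the model-based
inversion is the identity, so network inputs are z = y.  The module also
provides out-of-distribution artifact insertion for the atypical-artifact
detection protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

__all__ = [
    "InverseProblem",
    "SampleSet",
    "make_forward_operator",
    "sample_signal",
    "simulate_measurements",
    "insert_artifact",
    "random_block_mask",
    "make_dataset",
]

NOISE_MODES = ("none", "measurement", "measurement_and_signal")


@dataclass
class InverseProblem:
    """A linear inverse problem y = A x + eta with model-based inversion."""

    n: int
    nu: float
    A: np.ndarray
    noise_mode: str = "none"
    sigma: float = 0.0

    def __post_init__(self):
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def m(self) -> int:
        return self.n

    def inversion(self, y: np.ndarray) -> np.ndarray:
        """Model-based inversion A†; the identity for this benchmark."""
        return y


@dataclass
class SampleSet:
    """Paired network inputs and targets with train/val/test split labels."""

    signals: np.ndarray      # clean x, shape (N, n)
    measurements: np.ndarray  # y, shape (N, n)
    inputs: np.ndarray       # z = A†(y), shape (N, n)
    splits: np.ndarray       # strings in {train, val, test}, shape (N,)
    seed: int

    def subset(self, name: str):
        sel = self.splits == name
        if not np.any(sel):
            raise KeyError(f"empty split {name!r}")
        return self.inputs[sel], self.signals[sel]


def make_forward_operator(n: int, nu: float) -> np.ndarray:
    """DCT-diagonalized forward operator A = D^T S D, eigenvalues in [0,1]."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    D = dct(np.eye(n), type=1, norm="ortho", axis=0)
    j = np.arange(1, n + 1, dtype=float)
    s = ((n - j) / (n - 1)) ** nu
    return D.T @ (s[:, None] * D)


def sample_signal(n: int, jump_count_range=(4, 12), height_range=(0.0, 1.0),
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one piecewise-constant signal in [0, 1]^n.

    The number of jumps is uniform over ``jump_count_range`` (inclusive),
    positions are uniform without replacement among the n-1 interior
    boundaries, and plateau heights are uniform in ``height_range`` (clipped
    to [0, 1]).
    """
    rng = np.random.default_rng() if rng is None else rng
    lo_j, hi_j = int(jump_count_range[0]), int(jump_count_range[-1])
    if lo_j > hi_j:
        raise ValueError("empty jump_count_range")
    if hi_j > n - 1:
        raise ValueError("more jumps requested than n-1")
    k = int(rng.integers(lo_j, hi_j + 1))
    positions = np.sort(rng.choice(np.arange(1, n), size=k, replace=False))
    edges = np.concatenate([[0], positions, [n]])
    heights = rng.uniform(height_range[0], height_range[1], size=k + 1)
    x = np.empty(n)
    for h, a, b in zip(heights, edges[:-1], edges[1:]):
        x[a:b] = h
    return np.clip(x, 0.0, 1.0)


def simulate_measurements(problem: InverseProblem, x: np.ndarray,
                          rng: np.random.Generator | None = None):
    """Simulate (y, z) for signal(s) x under the problem's noise model.

    noise_mode 'measurement': y = A x + eta, eta ~ N(0, sigma^2 Id);
    'measurement_and_signal': y = A (x + eta1) + eta2 with independent
    eta1, eta2 ~ N(0, sigma^2 Id); 'none': y = A x.  Works on a single
    signal (n,) or a batch (N, n); z = A†(y) = y here.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)
    sig = problem.sigma
    if problem.noise_mode == "none" or sig == 0.0:
        y = x @ problem.A.T
    elif problem.noise_mode == "measurement":
        y = x @ problem.A.T + rng.normal(0.0, sig, size=x.shape)
    else:
        eta1 = rng.normal(0.0, sig, size=x.shape)
        eta2 = rng.normal(0.0, sig, size=x.shape)
        y = (x + eta1) @ problem.A.T + eta2
    z = problem.inversion(y)
    return y, z


def random_block_mask(n: int, length: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """A binary mask with one contiguous block of ones at a random offset."""
    rng = np.random.default_rng() if rng is None else rng
    if not 0 < length <= n:
        raise ValueError("block length out of range")
    start = int(rng.integers(0, n - length + 1))
    mask = np.zeros(n)
    mask[start : start + length] = 1.0
    return mask


def insert_artifact(x: np.ndarray, mask: np.ndarray, amplitude: float):
    """Insert an out-of-distribution artifact: x_ood = clip(x + a*mask, 0, 1).

    ``mask`` must be binary and shaped like ``x``; returns (x_ood, mask).
    Measurements for x_ood are then simulated with
    :func:`simulate_measurements` exactly as for in-distribution signals.
    """
    x = np.asarray(x, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if mask.shape != x.shape:
        raise ValueError("mask shape mismatch")
    if not np.all((mask == 0) | (mask == 1)):
        raise ValueError("mask must be binary")
    x_ood = np.clip(x + amplitude * mask, 0.0, 1.0)
    return x_ood, mask


def make_dataset(problem: InverseProblem, n_total: int = 2000,
                 split_sizes=(1600, 200, 200), seed: int = 0,
                 jump_count_range=(4, 12),
                 height_range=(0.0, 1.0)) -> SampleSet:
    """Generate the benchmark dataset (reference: 2000 pairs, 1600/200/200).

    Signals, noise draws and the split assignment are all driven by ``seed``;
    splits are disjoint by construction.
    """
    split_sizes = tuple(int(s) for s in split_sizes)
    if sum(split_sizes) != n_total:
        raise ValueError("split sizes must sum to n_total")
    rng = np.random.default_rng(seed)
    signals = np.stack([
        sample_signal(problem.n, jump_count_range, height_range, rng)
        for _ in range(n_total)
    ])
    measurements, inputs = simulate_measurements(problem, signals, rng)
    labels = np.array(
        ["train"] * split_sizes[0] + ["val"] * split_sizes[1]
        + ["test"] * split_sizes[2]
    )
    rng.shuffle(labels)
    return SampleSet(signals=signals, measurements=measurements,
                     inputs=inputs, splits=labels, seed=seed)
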