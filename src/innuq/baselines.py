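"""Baseline uncertainty-quantification methods: MCDrop and ProbOut.

MCDrop estimates epistemic uncertainty as the component-wise sample standard
deviation of T stochastic forward passes with independently drawn dropout
masks.  ProbOut doubles the network's output head into mean and variance
channels trained jointly with a Gaussian-likelihood-style loss; its
uncertainty score is the predicted standard deviation.  Unlike the interval
wrapper and MCDrop, ProbOut cannot be applied post hoc to an already trained
network — it is trained from scratch (see ``nets.train_network`` with
``loss='probout'``).
"""

from __future__ import annotations

import numpy as np

from .nets import PredictionNetwork, ProbOutNetwork

__all__ = ["mcdrop_uncertainty", "probout_loss", "probout_uncertainty"]


def mcdrop_uncertainty(net: PredictionNetwork, z, T: int = 64,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample standard deviation over T dropout forward passes.

    Uses the unbiased-variance form
    ``sqrt( (sum_t f_t^2 - (sum_t f_t)^2 / T) / (T-1) )`` accumulated over
    passes, so memory stays at two heatmaps regardless of T.  Reproducible
    for a fixed integer seed.
    """
    if T < 2:
        raise ValueError("MCDrop needs T >= 2 passes for a sample variance")
    if not net.dropout_sites:
        raise ValueError("network has no dropout sites")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    s1 = None
    s2 = None
    for _ in range(T):
        out = net.forward(z, dropout_rng=rng)
        if s1 is None:
            s1 = out.copy()
            s2 = out * out
        else:
            s1 += out
            s2 += out * out
    var = (s2 - (s1 * s1) / T) / (T - 1)
    return np.sqrt(np.maximum(var, 0.0))


def probout_loss(x, mean, var) -> float:
    """ProbOut training objective ``||(x-mean)/sqrt(var)||_2^2 +
    ||log var||_1`` summed over the batch; requires var > 0."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variance must be strictly positive")
    r = x - mean
    return float(np.sum(r * r / var) + np.sum(np.abs(np.log(var))))


def probout_uncertainty(var) -> np.ndarray:
    """Component-wise ProbOut uncertainty score sqrt(var)."""
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variance must be strictly positive")
    return np.sqrt(var)
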