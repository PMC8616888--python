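"""Targeted adversarial perturbations via box-constrained L-BFGS.

The attack operates in the input space z (after model-based inversion): it
seeks z_adv in the valid input box minimizing ||Phi(z_adv) - x_adv_tar||_2^2
starting from a clean input z.  The adversarial target x_adv_tar is the
clean reconstruction with 1.5 times its mean value subtracted inside a
randomly placed contiguous region, producing a clearly visible dark artifact
in the reconstruction while the input perturbation itself stays small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .nets import PredictionNetwork

__all__ = ["AttackConfig", "make_adversarial_target", "adversarial_perturb"]


@dataclass
class AttackConfig:
    """Attack hyperparameters.

    region_size: length of the perturbation target region (1D analog of the
        50x50 square used on 2D images).
    depth_factor: multiple of the reconstruction mean subtracted inside the
        region (1.5 in the reference protocol).
    box: valid input range, default [0, 1].
    """

    region_size: int = 50
    depth_factor: float = 1.5
    box: tuple[float, float] = (0.0, 1.0)
    max_iterations: int = 200
    tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.depth_factor < 0:
            raise ValueError("depth_factor must be positive")
        if not self.box[0] < self.box[1]:
            raise ValueError("box lower must be below box upper")


def make_adversarial_target(x_rec: np.ndarray, region: np.ndarray,
                            depth_factor: float = 1.5) -> np.ndarray:
    """Subtract ``depth_factor * mean(x_rec)`` inside ``region``.

    ``region`` is an integer index array or boolean mask selecting the
    components to darken; everything else is left untouched.
    """
    x_rec = np.asarray(x_rec, dtype=float)
    region = np.asarray(region)
    if region.dtype == bool:
        if not np.any(region):
            raise ValueError("empty region")
        sel = region
    else:
        if region.size == 0:
            raise ValueError("empty region")
        sel = region
    target = x_rec.copy()
    target[sel] = target[sel] - depth_factor * float(np.mean(x_rec))
    return target


def adversarial_perturb(net: PredictionNetwork, z: np.ndarray,
                        x_adv_tar: np.ndarray,
                        cfg: AttackConfig | None = None) -> np.ndarray:
    """Box-constrained L-BFGS attack on a single input.

    Minimizes ``||Phi(z') - x_adv_tar||_2^2`` over ``z'`` in the box,
    starting from ``z``; gradients come from backpropagation through the
    frozen network.  Returns the best feasible iterate; the objective at the
    result never exceeds the objective at the start point.
    """
    cfg = cfg or AttackConfig()
    z = np.asarray(z, dtype=float)
    x_adv_tar = np.asarray(x_adv_tar, dtype=float)
    shape = z.shape
    lo, hi = cfg.box
    if np.any(z < lo) or np.any(z > hi):
        raise ValueError("start point outside the box")

    conv = net.layers[0].kind == "conv1d"
    if conv and z.ndim == 1:
        net_shape = (1, 1, z.size)
    elif not conv and z.ndim == 1:
        net_shape = (1, z.size)
    else:
        net_shape = shape

    def to_net(v):
        return v.reshape(net_shape)

    if x_adv_tar.ndim == 1:
        tar = x_adv_tar.reshape((1, 1, -1)) if conv \
            else x_adv_tar.reshape((1, -1))
    else:
        tar = x_adv_tar

    def objective(v):
        out, caches = net.forward_cached(to_net(v))
        r = out - tar
        f = float(np.sum(r * r))
        _, dz = net.backward(caches, 2.0 * r)
        return f, dz.ravel()

    bounds = [(lo, hi)] * z.size
    res = minimize(objective, z.ravel(), jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options=dict(maxiter=cfg.max_iterations,
                                gtol=cfg.tolerance))
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        warnings.warn(f"L-BFGS-B did not converge: {res.message}")
    z_adv = np.clip(res.x.reshape(shape), lo, hi)
    # L-BFGS-B line searches are monotone, but guard against pathologies
    f_start = objective(z.ravel())[0]
    f_adv = objective(z_adv.ravel())[0]
    if f_adv > f_start:
        return z.copy()
    return z_adv
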