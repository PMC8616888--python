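"""Uncertainty scores, directional diagnostics and detection metrics.

All evaluation quantities used by the failure-mode protocols live here:

* ``uncertainty_score`` — interval width u(z) = upper - lower;
* ``directionality_ratio`` / ``directionality_accuracy`` — does the larger
  part of the output interval point toward the true target?
* ``empirical_coverage`` — fraction of target components inside intervals
  enlarged by lambda*beta (the Markov-inequality bound predicts >= 1-1/lambda
  for a trained INN);
* ``pwcc`` — Pearson correlation between uncertainty and absolute error,
  normalized by the prediction's mean squared error, so that uniformly
  uncertain *and* inaccurate models are not rewarded;
* ``heatmap_change_correlation`` — Pearson correlation between the change in
  uncertainty heatmaps and a map of where the input/reconstruction actually
  changed (adversarial and atypical-artifact detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UQReport",
    "uncertainty_score",
    "directionality_ratio",
    "directionality_accuracy",
    "empirical_coverage",
    "pwcc",
    "heatmap_change_correlation",
    "mean_heatmap_change_correlation",
]

#: components whose smaller interval part is below this are excluded from DR
TAU_DR = 1e-12


@dataclass
class UQReport:
    """Aggregated evaluation results for one UQ method on one test set."""

    uncertainty: np.ndarray | None = None
    dr_table: pd.DataFrame | None = None
    coverage: dict = field(default_factory=dict)
    pwcc_mean: float | None = None
    pwcc_std: float | None = None
    pearson: float | None = None
    extra: dict = field(default_factory=dict)


def uncertainty_score(lo, hi) -> np.ndarray:
    """Component-wise interval width; the INN uncertainty heatmap."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo > hi):
        raise ValueError("invalid interval: lo > hi")
    return hi - lo


def directionality_ratio(lo, hi, pred, tau: float = TAU_DR) -> np.ndarray:
    """Ratio of the larger to the smaller interval part around the prediction.

    Returns an array >= 1 with NaN where the smaller part is below ``tau``
    (prediction on an interval boundary; the ratio is undefined there).
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    pred = np.asarray(pred, dtype=float)
    up = hi - pred
    down = pred - lo
    if np.any(up < -tau) or np.any(down < -tau):
        raise ValueError("prediction outside [lo, hi]")
    larger = np.maximum(up, down)
    smaller = np.minimum(up, down)
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = larger / smaller
    dr = np.where(smaller < tau, np.nan, dr)
    return dr


def directionality_accuracy(lo, hi, pred, targets, n_bins: int = 20,
                            dr_max: float = 1e3,
                            dr_bins=None) -> pd.DataFrame:
    """Directionality accuracy (DA) binned by directionality ratio (DR).

    DA in a bin is the relative frequency of target components lying in the
    *larger* part of their interval (the side of the prediction with more
    interval mass); components with target exactly at the prediction count
    0.5.  Targets are attributed to the side of the prediction they fall on,
    which extends naturally to targets outside the interval.  Components
    with undefined DR are excluded.

    Bins are log-spaced over [1, ``dr_max``] with the last bin open-ended
    (ratios beyond ``dr_max`` describe effectively one-sided intervals and
    are pooled so that per-bin frequencies stay statistically meaningful);
    explicit ``dr_bins`` edges override this.

    Returns a DataFrame with columns bin_left, bin_right, da, count, freq;
    DA is NaN for empty bins and the last bin_right is +inf when the default
    binning is used.
    """
    lo = np.asarray(lo, dtype=float).ravel()
    hi = np.asarray(hi, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    dr = directionality_ratio(lo, hi, pred)
    defined = np.isfinite(dr)
    up = hi - pred
    down = pred - lo
    upper_is_larger = up >= down  # ties attributed to the upper part
    in_larger = np.where(
        targets == pred, 0.5,
        np.where(upper_is_larger, targets > pred, targets < pred).astype(float),
    )
    dr_d = dr[defined]
    score_d = in_larger[defined]
    if dr_bins is None:
        dr_bins = np.geomspace(1.0, dr_max, n_bins + 1)
        dr_bins[-1] = np.inf  # open-ended top bin
    dr_bins = np.asarray(dr_bins, dtype=float)
    idx = np.clip(np.searchsorted(dr_bins, dr_d, side="right") - 1, 0,
                  len(dr_bins) - 2)
    rows = []
    total = max(dr_d.size, 1)
    for b in range(len(dr_bins) - 1):
        sel = idx == b
        count = int(np.sum(sel))
        da = float(np.mean(score_d[sel])) if count else np.nan
        rows.append(
            dict(bin_left=dr_bins[b], bin_right=dr_bins[b + 1], da=da,
                 count=count, freq=count / total)
        )
    return pd.DataFrame(rows)


def empirical_coverage(lo, hi, targets, lam: float, beta: float) -> float:
    """Fraction of components with lo - lam*beta < x < hi + lam*beta.

    For an INN trained to (near) stationarity, the Markov inequality gives a
    lower bound of 1 - 1/lam on this fraction in expectation.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    x = np.asarray(targets, dtype=float)
    inside = (x > lo - lam * beta) & (x < hi + lam * beta)
    return float(np.mean(inside))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.sqrt(np.sum(a * a)))
    nb = float(np.sqrt(np.sum(b * b)))
    if na == 0.0 or nb == 0.0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def pwcc(pred, target, u) -> float:
    """Performance-weighted correlation coefficient.

    Pearson correlation between the absolute error |pred - target| and the
    uncertainty u, divided by the mean squared error of the prediction.
    Returns NaN (undefined) if either argument is constant.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if pred.size < 2:
        raise ValueError("pwcc needs at least two components")
    if np.any(u < 0):
        raise ValueError("uncertainty must be nonnegative")
    err = np.abs(pred - target)
    if np.all(u == u[0]) or np.all(err == err[0]):
        return np.nan
    corr = _pearson(err, u)
    mse = float(np.mean(err * err))
    if not np.isfinite(corr) or mse == 0.0:
        return np.nan
    return corr / mse


def heatmap_change_correlation(u_ref, u_pert, change_map) -> float:
    """Pearson correlation between |u_ref - u_pert| and a change map.

    The change map is |x_rec - Phi(z_adv)| for adversarial detection and a
    binary insertion mask for atypical-artifact detection.  Returns NaN if
    either argument is constant (e.g. no change at all).
    """
    u_ref = np.asarray(u_ref, dtype=float)
    u_pert = np.asarray(u_pert, dtype=float)
    du = np.abs(u_ref - u_pert)
    cm = np.asarray(change_map, dtype=float)
    if du.shape != cm.shape:
        raise ValueError("shape mismatch")
    # changes at rounding level of the heatmaps are "no change"
    scale = max(np.max(np.abs(u_ref), initial=0.0),
                np.max(np.abs(u_pert), initial=0.0), 1.0)
    if np.ptp(du) <= 1e-12 * scale:
        return np.nan
    return _pearson(du.ravel(), cm.ravel())


def mean_heatmap_change_correlation(u_refs, u_perts, change_maps):
    """Per-sample heatmap-change correlations averaged over a test set.

    Each argument is a sequence/array of per-sample heatmaps.  Undefined
    (constant-argument) samples are excluded; returns
    ``(mean_correlation, n_excluded)`` with ``mean`` NaN if all excluded.
    """
    vals = []
    excluded = 0
    for ur, up, cm in zip(u_refs, u_perts, change_maps):
        r = heatmap_change_correlation(ur, up, cm)
        if np.isnan(r):
            excluded += 1
        else:
            vals.append(r)
    mean = float(np.mean(vals)) if vals else np.nan
    return mean, excluded
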