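"""Signed point-biserial correlation and significance-masked r^2 maps.

For each channel x time cell, the discriminability of target vs non-target
amplitudes is summarised by the point-biserial correlation

    r = sqrt(N2 * N1) / (N2 + N1) * (mu2 - mu1) / sigma,

where class 2 is target, class 1 non-target, and sigma is the population
standard deviation of the pooled sample at that cell.  This equals the Pearson
correlation between amplitude and a 0/1 class label.  Cells whose
no-correlation test does not survive Bonferroni correction over all
channel x time cells are masked to zero in ``r2_masked``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import stats

from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RSquaredMap:
    """Channel x time map of signed r, r^2, p-values and the masked r^2."""

    r: np.ndarray
    r2: np.ndarray
    p: np.ndarray
    r2_masked: np.ndarray
    channels: tuple[str, ...]
    times: np.ndarray
    n_target: int
    n_nontarget: int
    alpha: float
    n_comparisons: int


def no_correlation_test(r, n: int):
    """Two-sided p-value of the test of no correlation.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom; |r| = 1 maps
    to p = 0.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("|r| must be <= 1")
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(n - 2) / np.sqrt(1.0 - rr * rr)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rr) >= 1.0, 0.0, p)
    return p if p.ndim else float(p)


def pointbiserial_map(target_epochs: EpochSet, nontarget_epochs: EpochSet,
                      alpha: float = 0.05) -> RSquaredMap:
    """Point-biserial r / r^2 / p per channel x time cell.

    ``target_epochs`` and ``nontarget_epochs`` must share channel and time
    axes; the caller decides which epochs enter (rejected epochs are typically
    excluded upstream).  Cells with zero pooled variance get r = 0 (logged).
    The returned map is already Bonferroni-masked at ``alpha``.
    """
    if target_epochs.channels != nontarget_epochs.channels:
        raise ValueError("channel axes differ")
    if not np.allclose(target_epochs.times, nontarget_epochs.times):
        raise ValueError("time axes differ")
    x2 = target_epochs.data
    x1 = nontarget_epochs.data
    n2, n1 = x2.shape[0], x1.shape[0]
    if n2 < 2 or n1 < 2:
        raise ValueError("need at least 2 epochs per class")
    pooled = np.concatenate([x2, x1], axis=0)
    sigma = pooled.std(axis=0)  # population convention
    mu2 = x2.mean(axis=0)
    mu1 = x1.mean(axis=0)
    zero_var = sigma == 0
    if zero_var.any():
        logger.warning("%d cells with zero pooled variance; r set to 0",
                       int(zero_var.sum()))
        sigma = np.where(zero_var, 1.0, sigma)
    r = np.sqrt(n2 * n1) / (n2 + n1) * (mu2 - mu1) / sigma
    r[zero_var] = 0.0
    r = np.clip(r, -1.0, 1.0)
    p = no_correlation_test(r, n2 + n1)
    n_comp = r.shape[0] * r.shape[1]
    out = RSquaredMap(r=r, r2=r * r, p=p, r2_masked=np.zeros_like(r),
                      channels=target_epochs.channels,
                      times=target_epochs.times.copy(),
                      n_target=n2, n_nontarget=n1, alpha=alpha,
                      n_comparisons=n_comp)
    return bonferroni_mask(out, alpha)


def bonferroni_mask(rmap: RSquaredMap, alpha: float = 0.05) -> RSquaredMap:
    """Zero out r^2 cells not significant after Bonferroni correction.

    A cell survives iff ``p * n_comparisons < alpha`` with ``n_comparisons``
    the number of channel x time cells.  Idempotent.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    survives = rmap.p * rmap.n_comparisons < alpha
    return _dc_replace(rmap, r2_masked=np.where(survives, rmap.r2, 0.0),
                       alpha=alpha)


def rsq_for_sound(epochs: EpochSet, sound: int, alpha: float = 0.05
                  ) -> RSquaredMap:
    """Discriminability map for one sound across a subject's full dataset.

    Target class: retained epochs of ``sound`` from runs where it was the
    counted target; non-target class: retained epochs of ``sound`` from all
    other runs — pooled over both experiment parts.
    """
    keep = epochs.retained()
    stim = keep.info["stimulus_id"] == sound
    tgt = keep.select((stim & keep.info["is_target"]).to_numpy())
    non = keep.select((stim & ~keep.info["is_target"]).to_numpy())
    return pointbiserial_map(tgt, non, alpha=alpha)
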