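"""Weighted block jackknife.

Standard errors for genome-wide moment statistics are obtained by deleting
one contiguous SNP block at a time and recombining the leave-one-out
estimates with block weights (Busing-style weighted delete-one jackknife).
Blocks absorb local linkage, so the resulting Z-scores are approximately
standard normal under the null even though SNPs are correlated within a
block.
"""

from __future__ import annotations

import numpy as np

__all__ = ["weighted_jackknife", "block_means", "jackknife_mean_stat"]


def weighted_jackknife(
    theta_hat: float, loo: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Combine leave-one-block-out estimates into (estimate, se).

    Parameters
    ----------
    theta_hat
        Full-data estimate.
    loo
        Leave-one-out estimates, one per block.
    weights
        Positive block weights (typically SNP counts). Blocks with zero
        weight must be removed by the caller.

    Returns
    -------
    (estimate, se)
        Bias-corrected jackknife estimate and its standard error. With
        equal weights this reduces to the classic delete-one jackknife.
    """
    loo = np.asarray(loo, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if loo.shape != weights.shape:
        raise ValueError("loo and weights must have the same shape")
    g = loo.size
    if g < 2:
        raise ValueError("weighted jackknife requires at least 2 blocks")
    if np.any(weights <= 0):
        raise ValueError("block weights must be positive")
    W = weights.sum()
    h = W / weights
    est = g * theta_hat - float(np.sum((1.0 - weights / W) * loo))
    # pseudovalues
    tau = h * theta_hat - (h - 1.0) * loo
    var = float(np.sum((tau - est) ** 2 / (h - 1.0)) / g)
    return est, np.sqrt(max(var, 0.0))


def block_means(
    values: np.ndarray, mask: np.ndarray, blocks: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block means of a per-SNP statistic.

    ``values`` may contain NaN at masked-out SNPs; ``mask`` selects usable
    SNPs. Returns (block_mean, block_weight) where the weight is the count
    of usable SNPs in the block (zero-weight blocks have mean 0).
    """
    mask = np.asarray(mask, dtype=bool)
    v = np.where(mask, values, 0.0)
    sums = np.bincount(blocks, weights=v, minlength=n_blocks)
    cnts = np.bincount(blocks, weights=mask.astype(float), minlength=n_blocks)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1.0), 0.0)
    return means, cnts


def jackknife_mean_stat(
    block_vals: np.ndarray, block_weights: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Jackknife a weighted-mean statistic given per-block means.

    Zero-weight blocks are dropped. Returns (estimate, se, loo) where
    ``loo`` holds the leave-one-out estimates over retained blocks.
    """
    keep = block_weights > 0
    bv = np.asarray(block_vals, dtype=float)[keep]
    bw = np.asarray(block_weights, dtype=float)[keep]
    if bv.size < 2:
        raise ValueError(f"need >= 2 non-empty blocks, got {bv.size}")
    W = bw.sum()
    total = float(np.sum(bv * bw))
    theta = total / W
    loo = (total - bv * bw) / (W - bw)
    est, se = weighted_jackknife(theta, loo, bw)
    return est, se, loo
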