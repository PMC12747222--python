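"""Pairwise mismatch-rate (PMR) kinship detection for pseudo-haploid data.

Two unrelated pseudo-haploid individuals from the same population mismatch
at a baseline rate b = mean 2p(1-p); sharing genomic segments lowers the
rate in fixed proportions: identical genomes 0.5 b, first degree 0.75 b,
second degree 0.875 b. Classification uses midpoint thresholds between
those expectations and requires the estimate to sit at least two standard
errors away from the unrelated boundary before asserting relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .jackknife import block_means, jackknife_mean_stat

__all__ = [
    "MismatchResult",
    "pairwise_mismatch",
    "within_individual_rate",
    "classify_degree",
    "population_baseline",
    "DEGREE_RATIOS",
]

DEGREE_RATIOS = {"identical": 0.5, "first": 0.75, "second": 0.875, "unrelated": 1.0}
# midpoints between successive expected ratios
_BOUNDS = [(0.625, "identical"), (0.8125, "first"), (0.90625, "second")]
OVERLAP_FLOOR = 5000


@dataclass
class MismatchResult:
    pair: tuple[str, str]
    overlap: int
    rate: float
    se: float
    informative: bool


def _mismatch_from_calls(
    c1: np.ndarray, c2: np.ndarray, blocks: np.ndarray, n_blocks: int,
    floor: int,
) -> tuple[int, float, float, bool]:
    both = (c1 != MISSING) & (c2 != MISSING)
    overlap = int(both.sum())
    if overlap < floor:
        return overlap, np.nan, np.nan, False
    mism = (c1 != c2).astype(float)
    bv, bw = block_means(mism, both, blocks, n_blocks)
    if (bw > 0).sum() >= 2:
        est, se, _ = jackknife_mean_stat(bv, bw)
    else:
        est, se = float(mism[both].mean()), np.nan
    return overlap, est, se, True


def pairwise_mismatch(
    matrix: GenotypeMatrix,
    id1: str,
    id2: str,
    blocks: np.ndarray,
    n_blocks: int,
    site_mask: np.ndarray | None = None,
    overlap_floor: int = OVERLAP_FLOOR,
) -> MismatchResult:
    """Mean mismatch rate over sites covered in both individuals.

    ``site_mask`` restricts to eligible sites (non-CpG autosomal in the
    usual workflow); when None, all sites are used. Pairs with overlap
    below ``overlap_floor`` are reported uninformative and never
    classified.
    """
    i1, i2 = matrix.individual_index(id1), matrix.individual_index(id2)
    if matrix.ploidy[i1] != 1 or matrix.ploidy[i2] != 1:
        raise ValueError("pairwise mismatch requires pseudo-haploid calls")
    c1, c2 = matrix.calls[:, i1].copy(), matrix.calls[:, i2].copy()
    if site_mask is not None:
        c1 = np.where(site_mask, c1, MISSING)
        c2 = np.where(site_mask, c2, MISSING)
    overlap, rate, se, ok = _mismatch_from_calls(
        c1, c2, blocks, n_blocks, overlap_floor
    )
    return MismatchResult(
        pair=(id1, id2), overlap=overlap, rate=rate, se=se, informative=ok
    )


def within_individual_rate(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    blocks: np.ndarray,
    n_blocks: int,
    overlap_floor: int = OVERLAP_FLOOR,
) -> MismatchResult:
    """Mismatch rate between two independent call replicates of one
    individual (e.g. two libraries): the identical-genome anchor, which
    sits at half the unrelated baseline."""
    overlap, rate, se, ok = _mismatch_from_calls(
        np.asarray(calls_a), np.asarray(calls_b), blocks, n_blocks, overlap_floor
    )
    return MismatchResult(pair=("rep_a", "rep_b"), overlap=overlap, rate=rate,
                          se=se, informative=ok)


def population_baseline(rates: np.ndarray) -> float:
    """Unrelated-pair baseline as the median of all pair rates; robust to a
    few relatives in the comparison set."""
    rates = np.asarray(rates, dtype=float)
    rates = rates[np.isfinite(rates)]
    if rates.size == 0:
        raise ValueError("no finite pair rates to form a baseline")
    return float(np.median(rates))


def classify_degree(result: MismatchResult, baseline: float) -> dict:
    """Classify a pair from its normalized mismatch ratio.

    Boundaries at (0.625, 0.8125, 0.90625) x baseline; the relatedness
    call additionally requires the rate to be >= 2 SE below the unrelated
    boundary, otherwise the pair stays 'unrelated' with a note. Returns
    the class, the ratio, and the exclusion recommendation (second degree
    or closer).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not result.informative:
        return {"degree": "uninformative", "ratio": np.nan, "exclude": False,
                "asserted": False}
    ratio = result.rate / baseline
    degree = "unrelated"
    for bound, label in _BOUNDS:
        if ratio < bound:
            degree = label
            break
    asserted = True
    if degree != "unrelated" and np.isfinite(result.se) and result.se > 0:
        unrelated_bound = _BOUNDS[-1][0] * baseline
        asserted = result.rate <= unrelated_bound - 2 * result.se
        if not asserted:
            degree = "unrelated"
    exclude = degree in ("identical", "first", "second")
    return {"degree": degree, "ratio": float(ratio), "exclude": exclude,
            "asserted": asserted}
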