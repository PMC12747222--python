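"""f-statistics (f2, f3, f4), Hudson Fst, and FDR correction of Z-scores.

All statistics are moments of group allele frequencies p = x / n taken from
an :class:`~paleopop.genotypes.AlleleCountTable`. Finite-sample bias in
squared-difference terms is removed with the usual h/n correction,
h = p(1-p) n/(n-1), which is valid for pseudo-haploid data because n counts
observed chromosomes (one per pseudo-haploid individual). f4 is computed
through its f2 decomposition, which cancels the corrections exactly when the
four populations are distinct and keeps the estimator unbiased when a
population is repeated across the two sides.

Standard errors come from the weighted block jackknife over contiguous
genomic blocks; Z = estimate / SE is approximately standard normal under
the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotypes import AlleleCountTable
from .jackknife import block_means, jackknife_mean_stat, weighted_jackknife

__all__ = [
    "FStatResult",
    "f2",
    "f3",
    "f4",
    "hudson_fst",
    "by_correct",
    "F2BlockTable",
    "extract_f2",
]


@dataclass
class FStatResult:
    stat: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    block_values: np.ndarray
    block_weights: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"{self.stat}{self.pops}: {self.estimate:.6g} +/- {self.se:.3g} "
            f"(Z={self.z:.2f}, {self.n_snps} SNPs, {self.n_blocks} blocks)"
        )


def _freq_corr(counts: AlleleCountTable, idx: np.ndarray):
    """Frequencies and h/n corrections for the selected group rows."""
    x = counts.x[idx]
    n = counts.n[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, x / np.maximum(n, 1), np.nan)
        corr = np.where(n > 1, p * (1 - p) / np.maximum(n - 1, 1), 0.0)
    if np.any((n == 1).any(axis=1)):
        warnings.warn(
            "groups of size 1 present: h/n bias correction skipped at those sites",
            stacklevel=3,
        )
    return p, corr, n


def _finalize(
    stat: str,
    pops: tuple[str, ...],
    vals: np.ndarray,
    mask: np.ndarray,
    counts: AlleleCountTable,
) -> FStatResult:
    if not mask.any():
        raise ValueError(f"{stat}{pops}: no usable SNPs")
    bv, bw = block_means(vals, mask, counts.blocks, counts.n_blocks)
    est, se, _ = jackknife_mean_stat(bv, bw)
    z = est / se if se > 0 else np.nan
    return FStatResult(
        stat=stat,
        pops=pops,
        estimate=est,
        se=se,
        z=z,
        n_snps=int(mask.sum()),
        n_blocks=int((bw > 0).sum()),
        block_values=bv,
        block_weights=bw,
    )


def _f2_vals(p, corr, i, j):
    """Per-SNP bias-corrected f2 between rows i and j; exactly 0 if i == j."""
    if i == j:
        return np.zeros(p.shape[1])
    return (p[i] - p[j]) ** 2 - corr[i] - corr[j]


def f2(
    counts: AlleleCountTable, a: str, b: str, corrected: bool = True
) -> FStatResult:
    ia, ib = counts.index(a), counts.index(b)
    p, corr, n = _freq_corr(counts, np.arange(len(counts.groups)))
    if not corrected:
        corr = np.zeros_like(corr)
    mask = (n[ia] > 0) & (n[ib] > 0)
    vals = _f2_vals(p, corr, ia, ib)
    return _finalize("f2", (a, b), np.nan_to_num(vals), mask, counts)


def f3(
    counts: AlleleCountTable,
    a: str,
    b: str,
    c: str,
    outgroup_mode: bool = False,
) -> FStatResult:
    """f3(A; B, C) = E[(pA - pB)(pA - pC)], negative under admixture into A.

    With ``outgroup_mode`` the h_A/n_A correction is omitted (the shared
    drift to an outgroup is compared only across statistics, matching the
    outgroup-f3 convention).
    """
    ia, ib, ic = (counts.index(g) for g in (a, b, c))
    p, corr, n = _freq_corr(counts, np.arange(len(counts.groups)))
    mask = (n[ia] > 0) & (n[ib] > 0) & (n[ic] > 0)
    vals = (p[ia] - p[ib]) * (p[ia] - p[ic])
    if not outgroup_mode:
        vals = vals - corr[ia]
    return _finalize("f3", (a, b, c), np.nan_to_num(vals), mask, counts)


def f4_persnp(p: np.ndarray, corr: np.ndarray, ia: int, ib: int, ic: int, id_: int):
    """Unbiased per-SNP f4 via the f2 decomposition.

    (f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)) / 2 equals the plain product
    (pA - pB)(pC - pD) when all four populations are distinct and remains
    unbiased when a population appears on both sides.
    """
    return 0.5 * (
        _f2_vals(p, corr, ia, id_)
        + _f2_vals(p, corr, ib, ic)
        - _f2_vals(p, corr, ia, ic)
        - _f2_vals(p, corr, ib, id_)
    )


def f4(
    counts: AlleleCountTable, a: str, b: str, c: str, d: str
) -> FStatResult:
    """f4(A, B; C, D): zero when (A, B) form a clade relative to (C, D)."""
    ia, ib, ic, id_ = (counts.index(g) for g in (a, b, c, d))
    p, corr, n = _freq_corr(counts, np.arange(len(counts.groups)))
    mask = (n[ia] > 0) & (n[ib] > 0) & (n[ic] > 0) & (n[id_] > 0)
    vals = f4_persnp(p, corr, ia, ib, ic, id_)
    return _finalize("f4", (a, b, c, d), np.nan_to_num(vals), mask, counts)


def f4_many(
    counts: AlleleCountTable, quadruples: list[tuple[str, str, str, str]]
) -> list[FStatResult]:
    """Batched f4: shares the frequency/correction prep across statistics."""
    p, corr, n = _freq_corr(counts, np.arange(len(counts.groups)))
    observed = n > 0
    out = []
    for quad in quadruples:
        ia, ib, ic, id_ = (counts.index(g) for g in quad)
        mask = observed[[ia, ib, ic, id_]].all(axis=0)
        vals = f4_persnp(p, corr, ia, ib, ic, id_)
        out.append(_finalize("f4", tuple(quad), np.nan_to_num(vals), mask, counts))
    return out


def hudson_fst(
    counts: AlleleCountTable,
    a: str,
    b: str,
    inbreed: bool = True,
    min_snps: int = 5000,
) -> FStatResult:
    """Ratio-of-averages Hudson Fst with block-jackknifed SE.

    With ``inbreed`` the within-population heterozygosities are estimated
    from observed chromosome counts, treating every sampled allele as an
    independent haploid lineage; this is the pseudo-haploid-safe estimator
    (diploid genotype-based heterozygosity is meaningless for random-allele
    calls). ``min_snps`` enforces the minimum-SNP rule for pairwise
    computations (default 5000); pass 0 to disable.
    """
    ia, ib = counts.index(a), counts.index(b)
    p, corr, n = _freq_corr(counts, np.arange(len(counts.groups)))
    if not inbreed:
        # diploid-sample convention: same moment estimator, n still counts
        # chromosomes; retained as an explicit switch for API clarity
        pass
    mask = (n[ia] > 1) & (n[ib] > 1)
    usable = int(mask.sum())
    if min_snps and usable < min_snps:
        raise ValueError(
            f"Fst({a},{b}): only {usable} usable SNPs, below the "
            f"{min_snps}-SNP floor"
        )
    num = np.nan_to_num((p[ia] - p[ib]) ** 2 - corr[ia] - corr[ib])
    den = np.nan_to_num(p[ia] * (1 - p[ib]) + p[ib] * (1 - p[ia]))
    nb, blocks = counts.n_blocks, counts.blocks
    num_b, wts = block_means(num, mask, blocks, nb)
    den_b, _ = block_means(den, mask, blocks, nb)
    keep = wts > 0
    if keep.sum() < 2:
        raise ValueError("Fst jackknife needs >= 2 non-empty blocks")
    ns = num_b[keep] * wts[keep]
    ds = den_b[keep] * wts[keep]
    theta = ns.sum() / ds.sum()
    loo = (ns.sum() - ns) / (ds.sum() - ds)
    est, se = weighted_jackknife(theta, loo, wts[keep])
    z = est / se if se > 0 else np.nan
    return FStatResult(
        stat="fst", pops=(a, b), estimate=est, se=se, z=z,
        n_snps=usable, n_blocks=int(keep.sum()),
        block_values=np.where(den_b > 0, num_b / np.maximum(den_b, 1e-300), 0.0),
        block_weights=wts,
    )


def by_correct(z_scores, fdr: float = 0.05):
    """Benjamini-Yekutieli correction of two-sided f4 Z-scores.

    Returns a dict of arrays: raw two-sided p, BY-adjusted p, significance
    at the requested FDR, and the signed adjusted score
    Z_BY = sign(Z) * Phi^-1(1 - p_adj / 2).
    """
    z = np.asarray(list(z_scores), dtype=float)
    if z.size == 0:
        return {"p": z, "p_adj": z, "significant": z.astype(bool), "z_by": z}
    if not np.all(np.isfinite(z)):
        raise ValueError("Z-scores must be finite")
    p = 2 * sps.norm.sf(np.abs(z))
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_by")
    z_by = np.sign(z) * sps.norm.isf(np.minimum(p_adj, 1.0) / 2)
    return {"p": p, "p_adj": p_adj, "significant": reject, "z_by": z_by}


# ---------------------------------------------------------------------------
# Per-block f2 basis (substrate of qpAdm/qpWave and admixture-graph fitting)


@dataclass
class F2BlockTable:
    """Per-block bias-corrected f2 means for every population pair.

    ``values`` has shape (n_blocks, n_pops, n_pops) and ``weights`` holds
    the usable-SNP count per block; all pairs share the intersection SNP
    set (sites where every population has observed alleles), so every
    derived f3/f4 combination uses identical blocks and weights.
    """

    pops: list[str]
    values: np.ndarray
    weights: np.ndarray
    n_snps: int

    def index(self, pop: str) -> int:
        return self.pops.index(pop)

    def f4_blocks(self, a: str, b: str, c: str, d: str) -> np.ndarray:
        ia, ib, ic, id_ = (self.index(g) for g in (a, b, c, d))
        v = self.values
        return 0.5 * (v[:, ia, id_] + v[:, ib, ic] - v[:, ia, ic] - v[:, ib, id_])

    def f2_mean(self) -> np.ndarray:
        w = self.weights / self.weights.sum()
        return np.einsum("b,bij->ij", w, self.values)


def extract_f2(counts: AlleleCountTable, pops: list[str] | None = None) -> F2BlockTable:
    """Per-block f2 table over the intersection SNP set of ``pops``."""
    if pops is None:
        pops = list(counts.groups)
    idx = np.array([counts.index(g) for g in pops])
    p, corr, n = _freq_corr(counts, idx)
    mask = (n > 0).all(axis=0)
    if not mask.any():
        raise ValueError("no SNPs observed in every population")
    k = len(pops)
    nb = counts.n_blocks
    values = np.zeros((nb, k, k))
    weights = None
    for i in range(k):
        for j in range(i + 1, k):
            vals = np.nan_to_num(_f2_vals(p, corr, i, j))
            bv, bw = block_means(vals, mask, counts.blocks, nb)
            values[:, i, j] = values[:, j, i] = bv
            weights = bw
    return F2BlockTable(
        pops=list(pops), values=values, weights=weights, n_snps=int(mask.sum())
    )
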