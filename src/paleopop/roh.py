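"""Runs-of-homozygosity demography: eligibility filters, a constant-Ne
maximum-likelihood estimator, and the group-comparison statistics.

Model
-----
Within a diploid individual of constant effective size Ne, the coalescence
time g (generations) of the two copies of a chromosome is Exponential with
mean 2*Ne. Conditional on g, recombination breaks the chromosome into IBD
segments at rate 2g per Morgan, so on a chromosome of map length L the
expected number of segments with genetic length in [l, l+dl] is

    lambda(l | g, L) dl = [ (L - l) (2g)^2 + 2 * 2g ] exp(-2 g l) dl

(interior segments bounded by two breakpoints plus the two chromosome-end
segments). The likelihood treats observed segment counts in length bins as
Poisson conditional on g and integrates g out against its Exp(2*Ne) density
chromosome by chromosome; this mixture form keeps the likelihood correctly
specified when several long segments co-occur on one recently coalesced
chromosome, which a marginal-intensity Poisson model would misstate badly.
The 1-D MLE in Ne is profiled numerically and the 95% CI comes from the
likelihood-ratio drop of 1.92.

Only segments in the fit range (default 4-20 cM) enter the likelihood:
below 4 cM is the calling floor of HMM-based ROH callers, above 20 cM
reflects recent parental relatedness rather than background Ne.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROHSet",
    "NeEstimate",
    "eligibility_filter",
    "ne_mle",
    "roh_group_tests",
    "roh_time_regression",
    "conover_test",
    "DEFAULT_CHROMOSOME_MORGANS",
]

# autosome genetic map lengths in Morgans (sex-averaged, rounded)
DEFAULT_CHROMOSOME_MORGANS = np.array([
    2.86, 2.69, 2.23, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81,
    1.58, 1.75, 1.26, 1.20, 1.42, 1.35, 1.29, 1.20, 1.08, 1.08,
    0.62, 0.74,
])

CALL_FLOOR_CM = 4.0


@dataclass
class ROHSet:
    """Per-individual ROH segments plus individual metadata.

    ``segments``: columns individual, chrom, start_cM, end_cM, length_cM.
    ``meta``: columns individual, group, mean_date_bp, covered_snps,
    weight (fractional weights for individuals shared across groupings).
    """

    segments: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.segments) and (self.segments["length_cM"] < CALL_FLOOR_CM - 1e-9).any():
            raise ValueError(f"segments below the {CALL_FLOOR_CM} cM calling floor")
        if not np.isfinite(self.meta["mean_date_bp"]).all():
            raise ValueError("dates must be finite")

    def individuals(self) -> list[str]:
        return self.meta["individual"].tolist()

    def sum_over(self, lo_cm: float, hi_cm: float = np.inf) -> pd.Series:
        """Per-individual cumulative ROH length (cM) in (lo, hi]."""
        seg = self.segments
        sel = seg[(seg["length_cM"] > lo_cm) & (seg["length_cM"] <= hi_cm)]
        sums = sel.groupby("individual")["length_cM"].sum()
        return sums.reindex(self.meta["individual"], fill_value=0.0)


@dataclass
class NeEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_individuals: float
    unbounded: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def eligibility_filter(
    rohset: ROHSet,
    min_snps: int = 400_000,
    max_date_bp: float | None = 3000.0,
    max_sum_gt20_cm: float | None = 50.0,
) -> ROHSet:
    """Apply the study-design eligibility rules.

    Keeps individuals with at least ``min_snps`` covered SNPs; for Ne
    estimation additionally requires mean date <= ``max_date_bp`` and a
    cumulative sum of >20 cM segments strictly below ``max_sum_gt20_cm``
    (inbred individuals bias the background-relatedness signal).
    """
    meta = rohset.meta
    keep = meta["covered_snps"] >= min_snps
    if max_date_bp is not None:
        keep &= meta["mean_date_bp"] <= max_date_bp
    if max_sum_gt20_cm is not None:
        gt20 = rohset.sum_over(20.0).to_numpy()
        keep &= gt20 < max_sum_gt20_cm
    meta2 = meta[keep.to_numpy()].reset_index(drop=True)
    seg2 = rohset.segments[
        rohset.segments["individual"].isin(meta2["individual"])
    ].reset_index(drop=True)
    return ROHSet(segments=seg2, meta=meta2)


def _bin_intensity(g_grid: np.ndarray, edges_m: np.ndarray, length_m: float) -> np.ndarray:
    """Expected segment counts per length bin, conditional on g.

    Integrates lambda(l|g,L) over each bin [a, b] (Morgans) using the exact
    antiderivative. Returns shape (n_g, n_bins).
    """
    r = 2.0 * g_grid[:, None]  # breakpoint rate per Morgan
    a = edges_m[None, :-1]
    b = np.minimum(edges_m[None, 1:], length_m)
    a = np.minimum(a, length_m)

    def f0(x):  # integral of exp(-r l)
        return np.exp(-r * x) / r

    def f1(x):  # integral of l exp(-r l)
        return np.exp(-r * x) * (x / r + 1.0 / r**2)

    interior = r**2 * (length_m * (f0(a) - f0(b)) - (f1(a) - f1(b)))
    edge = 2.0 * (np.exp(-r * a) - np.exp(-r * b))
    return np.maximum(interior + edge, 0.0)


def _log_composite_likelihood(
    ne: float,
    counts: np.ndarray,  # (n_ind, n_chrom, n_bins)
    weights: np.ndarray,  # (n_ind,)
    chrom_lengths: np.ndarray,  # Morgans
    edges_m: np.ndarray,
    n_g: int = 240,
) -> float:
    # log-spaced quadrature grid over coalescence times
    lo, hi = 1e-3, max(40.0 * ne, 50.0)
    log_g = np.linspace(np.log(lo), np.log(hi), n_g)
    g = np.exp(log_g)
    dlog = log_g[1] - log_g[0]
    # Exp(mean 2 Ne) density times g (Jacobian of the log grid)
    log_prior = -np.log(2.0 * ne) - g / (2.0 * ne) + log_g + np.log(dlog)

    ll = 0.0
    for k, L in enumerate(chrom_lengths):
        lam = _bin_intensity(g, edges_m, L)  # (n_g, n_bins)
        log_lam = np.log(np.maximum(lam, 1e-300))
        # Poisson log-likelihood per (individual, g), constants dropped
        per_g = counts[:, k, :] @ log_lam.T - lam.sum(axis=1)[None, :]
        ll += float(np.dot(weights, logsumexp(per_g + log_prior[None, :], axis=1)))
    return ll


def ne_mle(
    rohset: ROHSet,
    fit_range_cm: tuple[float, float] = (4.0, 20.0),
    chromosome_map: np.ndarray | None = None,
    n_bins: int = 8,
    ne_bounds: tuple[float, float] = (10.0, 1e7),
) -> NeEstimate:
    """Constant-Ne MLE from the ROH length distribution.

    ``fit_range_cm`` bounds the segment lengths used (default 4-20 cM,
    log-spaced into ``n_bins`` bins); ``chromosome_map`` gives per-
    chromosome map lengths in Morgans (default: human autosomes, indexed
    by the ``chrom`` column as 1..22). Individuals may carry fractional
    weights (``meta['weight']``) which multiply their log-likelihood
    contribution. The 95% CI is the likelihood-ratio interval; with no
    segments in range the upper bound is unbounded and flagged.
    """
    if chromosome_map is None:
        chromosome_map = DEFAULT_CHROMOSOME_MORGANS
    chrom_lengths = np.asarray(chromosome_map, dtype=float)
    if len(rohset.meta) == 0:
        raise ValueError("no eligible individuals")
    inds = rohset.meta["individual"].tolist()
    weights = (
        rohset.meta["weight"].to_numpy(dtype=float)
        if "weight" in rohset.meta
        else np.ones(len(inds))
    )
    lo, hi = fit_range_cm
    edges_cm = np.geomspace(lo, hi, n_bins + 1)
    edges_m = edges_cm / 100.0

    counts = np.zeros((len(inds), len(chrom_lengths), n_bins))
    seg = rohset.segments
    sel = seg[(seg["length_cM"] >= lo) & (seg["length_cM"] <= hi)]
    ind_idx = {s: i for i, s in enumerate(inds)}
    for r in sel.itertuples(index=False):
        ci = int(r.chrom) - 1
        b = int(np.clip(np.searchsorted(edges_cm, r.length_cM, side="right") - 1,
                        0, n_bins - 1))
        counts[ind_idx[r.individual], ci, b] += 1

    no_segments = counts.sum() == 0

    def nll(log_ne: float) -> float:
        return -_log_composite_likelihood(
            np.exp(log_ne), counts, weights, chrom_lengths, edges_m
        )

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(ne_bounds[0]), np.log(ne_bounds[1])), method="bounded",
        options={"xatol": 1e-4},
    )
    point = float(np.exp(res.x))
    ll_max = -res.fun

    def drop(log_ne: float) -> float:
        return (-nll(log_ne)) - (ll_max - 1.92)

    lo_b, hi_b = np.log(ne_bounds[0]), np.log(ne_bounds[1])
    if drop(lo_b) > 0:
        ci_low = ne_bounds[0]
    else:
        ci_low = float(np.exp(optimize.brentq(drop, lo_b, res.x, xtol=1e-5)))
    unbounded = no_segments or drop(hi_b) > 0
    if unbounded:
        ci_high = np.inf
        if no_segments:
            point = ne_bounds[1]
    else:
        ci_high = float(np.exp(optimize.brentq(drop, res.x, hi_b, xtol=1e-5)))
    return NeEstimate(
        point=point, ci_low=ci_low, ci_high=min(ci_high, np.inf),
        n_individuals=float(weights.sum()), unbounded=bool(unbounded),
    )


# ---------------------------------------------------------------------------
# Group comparisons


def conover_test(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Conover-Iman post-hoc rank test for all group pairs.

    Returns (t_matrix, p_matrix) of pairwise statistics and two-sided
    p-values (unadjusted), using the pooled-rank variance with the
    Kruskal-Wallis tie correction.
    """
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    split = np.split(ranks, np.cumsum(sizes))[:-1]
    rbar = np.array([r.mean() for r in split])
    h = sps.kruskal(*groups).statistic if len(set(pooled.tolist())) > 1 else 0.0
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    factor = s2 * (n - 1 - h) / (n - k)
    t = np.zeros((k, k))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            tij = (rbar[i] - rbar[j]) / denom if denom > 0 else 0.0
            pij = 2 * sps.t.sf(abs(tij), n - k)
            t[i, j] = t[j, i] = tij
            p[i, j] = p[j, i] = pij
    return t, p


def roh_group_tests(
    rohset: ROHSet, min_length_cm: float = 20.0, fdr: float = 0.05
) -> dict:
    """Kruskal-Wallis omnibus + Conover pairwise tests on Sum(ROH > 20 cM).

    The response is the per-individual cumulative length of segments above
    ``min_length_cm`` (informative of recent close-kin unions). Pairwise
    Conover p-values are Benjamini-Hochberg adjusted at ``fdr``.
    """
    meta = rohset.meta
    labels = sorted(meta["group"].unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    response = rohset.sum_over(min_length_cm).to_numpy()
    samples = []
    for lab in labels:
        vals = response[(meta["group"] == lab).to_numpy()]
        if vals.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
        samples.append(vals)
    if len(set(np.concatenate(samples).tolist())) == 1:
        return {
            "groups": labels, "h": 0.0, "p": 1.0,
            "pairwise": pd.DataFrame(
                columns=["group_a", "group_b", "t", "p", "p_adj", "significant"]
            ),
        }
    kw = sps.kruskal(*samples)
    t, p = conover_test(samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "t": t[i, j], "p": p[i, j]})
    pairwise = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(pairwise["p"], alpha=fdr, method="fdr_bh")
    pairwise["p_adj"] = p_adj
    pairwise["significant"] = reject
    return {"groups": labels, "h": float(kw.statistic), "p": float(kw.pvalue),
            "pairwise": pairwise}


def roh_time_regression(
    rohset: ROHSet,
    length_range_cm: tuple[float, float] = (4.0, 12.0),
    max_date_bp: float = 2500.0,
) -> dict:
    """OLS of Sum(ROH in 4-12 cM) on mean date BP (background relatedness
    vs time). Returns slope, SE, two-sided p and the window size."""
    meta = rohset.meta
    sel = (meta["mean_date_bp"] <= max_date_bp).to_numpy()
    if sel.sum() < 3:
        raise ValueError("need >= 3 individuals in the date window")
    y = rohset.sum_over(*length_range_cm).to_numpy()[sel]
    x = meta["mean_date_bp"].to_numpy(dtype=float)[sel]
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return {"slope": 0.0, "se": np.nan, "p": 1.0, "n": int(sel.sum()),
                "degenerate": True}
    fit = sps.linregress(x, y)
    return {"slope": float(fit.slope), "se": float(fit.stderr),
            "p": float(fit.pvalue), "intercept": float(fit.intercept),
            "n": int(sel.sum()), "degenerate": False}
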