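"""qpWave rank tests and qpAdm admixture-weight estimation.

Both methods work on a matrix X of f4-statistics, X[i, j] =
f4(L1, L_{i+1}; R1, R_{j+1}), between a left set L and a right (reference)
set R. If the left and right sets are connected by at most r independent
gene-flow streams, X has rank r in expectation; the test statistic is the
jackknife-covariance-weighted distance between X and its best rank-r
approximation, chi-squared with (nL-1-r)(nR-1-r) degrees of freedom.

qpAdm augments the left set with a target T = [T, L1..Lk]. If T is a
mixture of the k sources, the augmented matrix has rank k-1 and its left
null vector c (normalized to sum 1) gives the mixture weights; standard
errors come from recomputing the weights on every delete-one-block
replicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genotypes import AlleleCountTable
from .fstats import _freq_corr, f4_persnp
from .jackknife import block_means, weighted_jackknife

__all__ = [
    "RankTestResult",
    "AdmixtureFit",
    "f4_matrix",
    "rank_test",
    "qpwave",
    "qpadm_fit",
    "rotate_models",
    "meta_weights",
]

RIDGE_CONDITION = 1e12
RIDGE_SCALE = 1e-6


@dataclass
class RankTestResult:
    rank: int
    chi_square: float
    dof: int
    p_value: float
    n_left: int
    n_right: int


@dataclass
class AdmixtureFit:
    target: str
    sources: list[str]
    references: list[str]
    weights: np.ndarray
    se: np.ndarray
    p_value: float
    feasible: bool
    n_snps: int
    rank_test: RankTestResult | None = None

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class F4Matrix:
    """f4 matrix with per-block values for jackknifing."""

    left: list[str]
    right: list[str]
    est: np.ndarray  # (nL-1, nR-1)
    block_values: np.ndarray  # (B, d) row-major entries
    block_weights: np.ndarray  # (B, d) usable-SNP counts per entry
    n_snps: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.est.shape

    def covariance(self) -> np.ndarray:
        """Delete-one-block jackknife covariance of vec(est)."""
        bw = self.block_weights
        bv = self.block_values
        tot = (bv * bw).sum(axis=0)
        W = bw.sum(axis=0)
        loo = (tot[None, :] - bv * bw) / (W[None, :] - bw)  # (B, d)
        g = bv.shape[0]
        centered = loo - loo.mean(axis=0, keepdims=True)
        return (g - 1) / g * centered.T @ centered

    def loo_estimates(self) -> np.ndarray:
        bw = self.block_weights
        bv = self.block_values
        tot = (bv * bw).sum(axis=0)
        W = bw.sum(axis=0)
        return (tot[None, :] - bv * bw) / (W[None, :] - bw)


def f4_matrix(
    counts: AlleleCountTable,
    left: list[str],
    right: list[str],
    allsnps: bool = True,
) -> F4Matrix:
    """X[i, j] = f4(L1, L_{i+1}; R1, R_{j+1}) with per-block values.

    With ``allsnps`` each entry uses every SNP where its own four
    populations are observed; otherwise all entries share the intersection
    SNP set of the full left + right population list.
    """
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need nL >= 2 and nR >= 2")
    pops = list(left) + list(right)
    if len(set(pops)) != len(pops):
        raise ValueError("left and right sets must be disjoint and unique")
    idx = np.array([counts.index(g) for g in pops])
    p, corr, n = _freq_corr(counts, idx)
    li = {g: i for i, g in enumerate(left)}
    ri = {g: len(left) + i for i, g in enumerate(right)}
    observed = n > 0
    inter = observed.all(axis=0)
    nb = counts.n_blocks
    d = (len(left) - 1) * (len(right) - 1)
    B = nb
    est = np.zeros((len(left) - 1, len(right) - 1))
    bvals = np.zeros((B, d))
    bwts = np.zeros((B, d))
    col = 0
    min_snps = np.inf
    for i, lpop in enumerate(left[1:]):
        for j, rpop in enumerate(right[1:]):
            quad = (li[left[0]], li[lpop], ri[right[0]], ri[rpop])
            mask = (
                observed[list(quad)].all(axis=0) if allsnps else inter
            )
            if not mask.any():
                raise ValueError(
                    f"no usable SNPs for f4({left[0]},{lpop};{right[0]},{rpop})"
                )
            vals = np.nan_to_num(f4_persnp(p, corr, *quad))
            bv, bw = block_means(vals, mask, counts.blocks, nb)
            if (bw > 0).sum() < 2:
                raise ValueError("fewer than 2 non-empty blocks for an f4 entry")
            tot_w = bw.sum()
            est[i, j] = float((bv * bw).sum() / tot_w)
            bvals[:, col] = bv
            bwts[:, col] = bw
            min_snps = min(min_snps, mask.sum())
            col += 1
    return F4Matrix(
        left=list(left), right=list(right), est=est,
        block_values=bvals, block_weights=np.maximum(bwts, 1e-12),
        n_snps=int(min_snps),
    )


def _regularized_inverse(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0 or evals[-1] / max(evals[0], 1e-300) > RIDGE_CONDITION:
        cov = cov + RIDGE_SCALE * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    return np.linalg.inv(cov)


def _als_rank_fit(
    X: np.ndarray, sigma_inv: np.ndarray, r: int,
    tol: float = 1e-9, max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Best rank-r approximation under the Sigma^-1-weighted quadratic form.

    Alternating generalized least squares on Z = U V'; initialized from the
    SVD of X. Returns (Z_hat, minimized quadratic form).
    """
    m, n = X.shape
    y = X.ravel()

    def objective(z: np.ndarray) -> float:
        rvec = y - z.ravel()
        return float(rvec @ sigma_inv @ rvec)

    if r == 0:
        return np.zeros_like(X), objective(np.zeros_like(X))
    if r >= min(m, n):
        return X.copy(), 0.0

    U0, s0, Vt0 = np.linalg.svd(X, full_matrices=False)
    U = U0[:, :r] * s0[:r]
    V = Vt0[:r, :].T
    prev = objective(U @ V.T)
    for _ in range(max_iter):
        A = np.kron(np.eye(m), V)  # vec_row(U V') = A @ U.ravel()
        G = A.T @ sigma_inv @ A
        u = np.linalg.solve(G + 1e-14 * np.eye(G.shape[0]), A.T @ sigma_inv @ y)
        U = u.reshape(m, r)
        A = np.kron(U, np.eye(n))  # vec_row(U V') = A @ (V.T).ravel()
        G = A.T @ sigma_inv @ A
        v = np.linalg.solve(G + 1e-14 * np.eye(G.shape[0]), A.T @ sigma_inv @ y)
        V = v.reshape(r, n).T
        cur = objective(U @ V.T)
        if prev - cur <= tol * max(abs(prev), 1e-30):
            prev = cur
            break
        prev = cur
    return U @ V.T, prev


def rank_test(
    X: np.ndarray,
    cov: np.ndarray,
    r: int,
    n_left: int,
    n_right: int,
    n_blocks: int | None = None,
) -> RankTestResult:
    """Test that X (an (nL-1) x (nR-1) f4 matrix) has rank r.

    The statistic is the covariance-weighted distance to the best rank-r
    approximation, asymptotically chi-squared with (nL-1-r)(nR-1-r)
    degrees of freedom. Because the covariance itself is estimated from a
    finite number of jackknife blocks, the chi-squared reference is
    anticonservative; when ``n_blocks`` is given, the Hotelling-style
    small-sample mapping  stat * (B - d) / (d (B - 1)) ~ F(d, B - d)
    is used instead (it converges to the chi-squared tail as B grows).
    """
    m, n = X.shape
    if not 0 <= r < min(m, n) + 1:
        raise ValueError("rank out of range")
    dof = (n_left - 1 - r) * (n_right - 1 - r)
    if dof < 1:
        raise ValueError("rank leaves no degrees of freedom to test")
    sigma_inv = _regularized_inverse(cov)
    _, stat = _als_rank_fit(X, sigma_inv, r)
    if n_blocks is not None and n_blocks > dof + 1:
        f_stat = stat * (n_blocks - dof) / (dof * (n_blocks - 1))
        p = float(sps.f.sf(f_stat, dof, n_blocks - dof))
    else:
        p = float(sps.chi2.sf(stat, dof))
    return RankTestResult(
        rank=r, chi_square=stat, dof=dof, p_value=p,
        n_left=n_left, n_right=n_right,
    )


def qpwave(
    counts: AlleleCountTable,
    left: list[str],
    right: list[str],
    r: int = 0,
    allsnps: bool = True,
) -> RankTestResult:
    """qpWave: test that at most r+1 gene-flow streams relate L and R."""
    xm = f4_matrix(counts, left, right, allsnps)
    nb = int(np.sum(xm.block_weights.mean(axis=1) > 1e-9))
    return rank_test(xm.est, xm.covariance(), r, len(left), len(right), n_blocks=nb)


def _weights_from_matrix(X: np.ndarray, sigma_inv: np.ndarray) -> np.ndarray:
    """Mixture weights from the left null vector of the rank-(k-1) fit."""
    k = X.shape[0]
    if k == 1:
        return np.array([1.0])
    Z, _ = _als_rank_fit(X, sigma_inv, k - 1)
    U, s, _ = np.linalg.svd(Z)
    if k > 1 and s.size >= k - 1 and k - 1 >= 2 and s[k - 2] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("collinear sources: null space is not one-dimensional")
    c = U[:, -1]
    total = c.sum()
    if abs(total) < 1e-12:
        raise ValueError("degenerate null vector; sources may be collinear")
    w = c / total
    return w


def qpadm_fit(
    counts: AlleleCountTable,
    target: str,
    sources: list[str],
    references: list[str],
    allsnps: bool = True,
) -> AdmixtureFit:
    """Model ``target`` as a mixture of ``sources`` given distal references.

    The rank test at r = k-1 on the (T + sources, references) f4 matrix is
    the model's p-value (a small p rejects the k-source model); weights are
    the normalized left null vector and their SEs come from delete-one-
    block jackknife replicates. Negative weights are returned with
    ``feasible=False``.
    """
    k = len(sources)
    if k < 1:
        raise ValueError("need at least one source")
    if len(references) < k + 1:
        raise ValueError("need |references| >= |sources| + 1")
    left = [target] + list(sources)
    xm = f4_matrix(counts, left, references, allsnps)
    cov = xm.covariance()
    sigma_inv = _regularized_inverse(cov)
    nb = int(np.sum(xm.block_weights.mean(axis=1) > 1e-9))
    rt = rank_test(xm.est, cov, k - 1, len(left), len(references), n_blocks=nb)

    # X rows are f4(T, L_i; ...) = F(L_i) - F(T); a null combination
    # sum_i c_i X[i] = 0 with sum c = 1 gives T = sum_i c_i L_i.
    w = _weights_from_matrix(xm.est, sigma_inv)

    loo = xm.loo_estimates()  # (B, d)
    B = loo.shape[0]
    shape = xm.est.shape
    w_loo = np.empty((B, k))
    for b in range(B):
        w_loo[b] = _weights_from_matrix(loo[b].reshape(shape), sigma_inv)
    bw = xm.block_weights.mean(axis=1)
    se = np.empty(k)
    for i in range(k):
        _, se[i] = weighted_jackknife(w[i], w_loo[:, i], bw)
    feasible = bool(np.all(w > -1e-9) and np.all(w < 1 + 1e-9))
    return AdmixtureFit(
        target=target, sources=list(sources), references=list(references),
        weights=w, se=se, p_value=rt.p_value, feasible=feasible,
        n_snps=xm.n_snps, rank_test=rt,
    )


def rotate_models(
    counts: AlleleCountTable,
    target: str,
    pool: list[str],
    fixed_right: list[str],
    max_sources: int = 2,
    p_floor: float = 0.05,
    allsnps: bool = True,
) -> list[dict]:
    """Rotation scheme: every candidate subset as sources, the rest rotated
    into the references next to the fixed distal outgroups.

    Single-source models are assessed first; larger models are tried only
    if no simpler model passes (p >= p_floor and feasible weights). Returns
    all evaluated models sorted by (n_sources, -p).
    """
    if len(pool) < 1:
        raise ValueError("candidate pool is empty")
    results: list[dict] = []
    found_passing = False
    for size in range(1, min(max_sources, len(pool)) + 1):
        if found_passing:
            break
        for srcs in itertools.combinations(pool, size):
            right = list(fixed_right) + [p for p in pool if p not in srcs]
            if len(right) < size + 1:
                continue
            try:
                fit = qpadm_fit(counts, target, list(srcs), right, allsnps)
            except ValueError:
                continue
            passed = fit.p_value >= p_floor and fit.feasible
            results.append({
                "sources": list(srcs), "right": right, "fit": fit,
                "p": fit.p_value, "feasible": fit.feasible, "passes": passed,
            })
            found_passing = found_passing or passed
    results.sort(key=lambda m: (len(m["sources"]), -m["p"]))
    return results


def meta_weights(fits: list[AdmixtureFit], source: str) -> tuple[float, float]:
    """Inverse-variance meta-analysis of one source's weight across models."""
    ws, vs = [], []
    for fit in fits:
        if not fit.feasible or source not in fit.sources:
            continue
        i = fit.sources.index(source)
        if not np.isfinite(fit.se[i]) or fit.se[i] <= 0:
            raise ValueError("meta-analysis requires positive finite SEs")
        ws.append(fit.weights[i])
        vs.append(fit.se[i] ** 2)
    if not ws:
        raise ValueError("no feasible fits carrying the source of interest")
    inv = 1.0 / np.asarray(vs)
    pooled = float(np.sum(np.asarray(ws) * inv) / inv.sum())
    return pooled, float(inv.sum() ** -0.5)
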