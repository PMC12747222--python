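"""Synthetic data with the statistical structure the analyses assume.

Population allele frequencies evolve down a rooted drift tree under the
Balding-Nichols law: a child population with drift F inherits
p_child ~ Beta(p (1-F)/F, (1-p)(1-F)/F), so E[p_child] = p and
Var[p_child] = F p (1-p). Admixture edges mix two existing populations,
p = alpha p_a + (1-alpha) p_b, optionally followed by residual drift.
Pseudo-haploid genotypes are one Bernoulli(p) allele per covered site;
SNPs are unlinked apart from contiguous jackknife-block labels.

Everything is deterministic under the configured seed; one generator
stream is used per simulation call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    AlleleCountTable,
    BlockAssignment,
    GenotypeMatrix,
    assign_blocks_equal,
)
from .pileup import ErrorTable
from .roh import CALL_FLOOR_CM, ROHSet

__all__ = [
    "DemographyModel",
    "SimulationConfig",
    "simulate_frequencies",
    "simulate_counts",
    "simulate_genotypes",
    "simulate_pileups",
    "simulate_roh",
    "simulate_relative_pair",
    "two_population_model",
    "clade_model",
    "admixture_model",
]


@dataclass
class DemographyModel:
    """Rooted drift tree plus admixture edges.

    ``edges``: (child, parent, F) drift edges spanning all nodes; ``F`` in
    [0, 1) scales one generation of Balding-Nichols drift. ``admixture_edges``:
    (recipient, source_a, source_b, alpha, order) creating the recipient as
    an alpha : (1-alpha) mixture of two already-simulated nodes; recipients
    may themselves parent further drift edges.
    """

    populations: list[str]
    edges: list[tuple[str, str, float]]
    admixture_edges: list[tuple[str, str, str, float, int]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for child, parent, f in self.edges:
            if not 0 <= f < 1:
                raise ValueError(f"drift F for {child} must be in [0, 1)")
        for rec, a, b, alpha, _ in self.admixture_edges:
            if not 0 <= alpha <= 1:
                raise ValueError(f"admixture weight for {rec} must be in [0, 1]")
        self.root = self._find_root()
        self._order = self._toposort()
        missing = set(self.populations) - set(self._order)
        if missing:
            raise ValueError(f"populations not reachable from root: {sorted(missing)}")

    def _find_root(self) -> str:
        children = {c for c, _, _ in self.edges} | {
            r for r, *_ in self.admixture_edges
        }
        parents = {p for _, p, _ in self.edges} | {
            s for _, a, b, _, _ in self.admixture_edges for s in (a, b)
        }
        roots = parents - children
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {sorted(roots)}")
        return roots.pop()

    def _toposort(self) -> list[str]:
        order = [self.root]
        done = {self.root}
        pending_drift = list(self.edges)
        pending_admix = sorted(self.admixture_edges, key=lambda e: e[4])
        progressed = True
        while progressed:
            progressed = False
            for child, parent, _ in list(pending_drift):
                if parent in done and child not in done:
                    order.append(child)
                    done.add(child)
                    pending_drift.remove((child, parent, _))
                    progressed = True
            for e in list(pending_admix):
                rec, a, b, _, _ = e
                if a in done and b in done and rec not in done:
                    order.append(rec)
                    done.add(rec)
                    pending_admix.remove(e)
                    progressed = True
        if any(c not in done for c, _, _ in pending_drift) or pending_admix:
            raise ValueError("demography graph is cyclic or disconnected")
        return order


@dataclass
class SimulationConfig:
    n_snps: int = 50_000
    samples_per_pop: int = 10
    missing_rate: float = 0.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_blocks: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_snps >= self.n_blocks >= 2:
            raise ValueError("need n_snps >= n_blocks >= 2")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be a probability")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0:
        return p.copy()
    out = p.copy()
    interior = (p > 0) & (p < 1)
    pi = p[interior]
    out[interior] = rng.beta(pi * (1 - f) / f, (1 - pi) * (1 - f) / f)
    return out


def simulate_frequencies(
    model: DemographyModel, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Per-population allele frequencies for every leaf population."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    freqs: dict[str, np.ndarray] = {
        model.root: rng.uniform(lo, hi, size=config.n_snps)
    }
    drift_by_child = {c: (p, f) for c, p, f in model.edges}
    admix_by_rec = {r: (a, b, al) for r, a, b, al, _ in model.admixture_edges}
    for node in model._order[1:]:
        if node in admix_by_rec:
            a, b, alpha = admix_by_rec[node]
            freqs[node] = alpha * freqs[a] + (1 - alpha) * freqs[b]
        else:
            parent, f = drift_by_child[node]
            freqs[node] = _balding_nichols(rng, freqs[parent], f)
    return {pop: freqs[pop] for pop in model.populations}


def simulate_counts(
    freqs: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> AlleleCountTable:
    """Pseudo-haploid group allele counts sampled directly from frequencies.

    Equivalent to simulating ``samples_per_pop`` pseudo-haploid individuals
    per population and collapsing with ``group_counts``: the derived count
    is Binomial(n, p) with n reduced by per-site missingness.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pops = sorted(freqs)
    s = config.n_snps
    x = np.zeros((len(pops), s))
    n = np.zeros((len(pops), s))
    for i, pop in enumerate(pops):
        covered = rng.binomial(config.samples_per_pop, 1 - config.missing_rate, size=s)
        n[i] = covered
        x[i] = rng.binomial(covered, freqs[pop])
    blocks = assign_blocks_equal(s, config.n_blocks)
    return AlleleCountTable(
        groups=pops, x=x, n=n, blocks=blocks.block_of, n_blocks=config.n_blocks
    )


def simulate_genotypes(
    freqs: dict[str, np.ndarray], config: SimulationConfig
) -> tuple[GenotypeMatrix, dict[str, str], BlockAssignment]:
    """Pseudo-haploid genotype matrix, group labels and block assignment."""
    rng = np.random.default_rng(config.seed + 1)
    pops = sorted(freqs)
    s = config.n_snps
    inds, labels, cols = [], {}, []
    for pop in pops:
        p = np.clip(freqs[pop], 0.0, 1.0)
        for k in range(config.samples_per_pop):
            name = f"{pop}_{k}"
            inds.append(name)
            labels[name] = pop
            calls = rng.binomial(1, p).astype(np.int8)
            miss = rng.random(s) < config.missing_rate
            calls[miss] = MISSING
            cols.append(calls)
    calls = np.column_stack(cols) if cols else np.zeros((s, 0), dtype=np.int8)
    # genome-shaped metadata: SNPs spread over 22 chromosomes covering a
    # ~35 Morgan map, so default jackknife blocks behave as on real data
    n_chrom = min(22, s)
    chrom_of = (np.arange(s) * n_chrom) // s + 1
    within = np.concatenate([np.arange(np.sum(chrom_of == c))
                             for c in range(1, n_chrom + 1)])
    spacing_m = 35.0 / s
    snps = pd.DataFrame({
        "id": [f"snp{i}" for i in range(s)],
        "chrom": chrom_of.astype(str),
        "genetic_pos": within * spacing_m,
        "physical_pos": within.astype(int) * 2000 + 1,
        "ref": "A",
        "alt": "G",
    })
    matrix = GenotypeMatrix(
        snps=snps, individuals=inds,
        ploidy=np.ones(len(inds), dtype=np.int8), calls=calls,
    )
    return matrix, labels, assign_blocks_equal(s, config.n_blocks)


def simulate_pileups(
    truth: GenotypeMatrix,
    coverage: float,
    error_profile: ErrorTable,
    seed: int,
    library_type: str = "ds_UDG",
    terminal_fraction: float = 0.3,
    fixed_depth: bool = False,
) -> pd.DataFrame:
    """Per-site read observations for every individual in ``truth``.

    Depth is Poisson(``coverage``) (or fixed); each read carries strand,
    read-position class, MQ/BQ bins and library type, and its base is the
    individual's true allele flipped to the other SNP allele with the
    stratified rate from ``error_profile`` (undefined cells mean error 0).
    Zero-coverage sites simply emit no records.
    """
    rng = np.random.default_rng(seed)
    snps = truth.snps
    rows = []
    classes = ["terminal_5", "terminal_3", "central"]
    class_p = [terminal_fraction / 2, terminal_fraction / 2, 1 - terminal_fraction]
    for ii, ind in enumerate(truth.individuals):
        dosages = truth.calls[:, ii]
        covered = np.where(dosages != MISSING)[0]
        depths = (
            np.full(covered.size, int(round(coverage)))
            if fixed_depth
            else rng.poisson(coverage, size=covered.size)
        )
        for si, depth in zip(covered, depths):
            if depth == 0:
                continue
            ref, alt = snps["ref"].iloc[si], snps["alt"].iloc[si]
            true_base = alt if dosages[si] == 1 else ref
            other = ref if true_base == alt else alt
            for _ in range(depth):
                strand = "+" if rng.random() < 0.5 else "-"
                pos_class = classes[rng.choice(3, p=class_p)]
                mq = "mq_ge30" if rng.random() < 0.9 else "mq_lt30"
                bq = "bq_ge30" if rng.random() < 0.8 else "bq_20_29"
                stratum = (library_type, pos_class, strand, mq, bq)
                e = error_profile.rate(stratum, true_base, other) or 0.0
                base = other if rng.random() < e else true_base
                rows.append({
                    "chrom": snps["chrom"].iloc[si], "pos": int(snps["physical_pos"].iloc[si]),
                    "ref": ref, "alt": alt, "base": base, "strand": strand,
                    "pos_class": pos_class, "mq_bin": mq, "bq_bin": bq,
                    "library_id": ind, "library_type": library_type,
                })
    return pd.DataFrame(rows)


def simulate_roh(
    ne: float,
    chromosome_map_lengths: np.ndarray,
    n_individuals: int,
    seed: int,
    min_length_cm: float = CALL_FLOOR_CM,
    group: str = "sim",
    mean_date_bp: float = 1000.0,
    covered_snps: int = 500_000,
) -> ROHSet:
    """ROH segments under the same constant-Ne law the estimator assumes.

    Per individual and chromosome, one coalescence time g ~ Exp(mean 2*Ne)
    is drawn; recombination breakpoints fall as a Poisson process of rate
    2g per Morgan and the resulting segments (including trimmed chromosome-
    end segments) are retained when at least ``min_length_cm`` long.
    """
    if ne <= 0:
        raise ValueError("ne must be positive")
    lengths = np.asarray(chromosome_map_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("map lengths must be positive")
    rng = np.random.default_rng(seed)
    seg_rows = []
    for i in range(n_individuals):
        ind = f"{group}_{i}"
        for ci, L in enumerate(lengths):
            g = rng.exponential(2.0 * ne)
            # deep coalescence: P(any gap >= min length) < n_bp * e^-60,
            # so skip the (possibly enormous) breakpoint draw entirely
            if 2.0 * g * (min_length_cm / 100.0) > 60.0:
                continue
            n_bp = rng.poisson(2.0 * g * L)
            cuts = np.sort(rng.uniform(0, L, size=n_bp))
            bounds = np.concatenate([[0.0], cuts, [L]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                length_cm = (b - a) * 100.0
                if length_cm >= min_length_cm:
                    seg_rows.append({
                        "individual": ind, "chrom": ci + 1,
                        "start_cM": a * 100.0, "end_cM": b * 100.0,
                        "length_cM": length_cm,
                    })
    segments = pd.DataFrame(
        seg_rows, columns=["individual", "chrom", "start_cM", "end_cM", "length_cM"]
    )
    meta = pd.DataFrame({
        "individual": [f"{group}_{i}" for i in range(n_individuals)],
        "group": group,
        "mean_date_bp": float(mean_date_bp),
        "covered_snps": int(covered_snps),
        "weight": 1.0,
    })
    return ROHSet(segments=segments, meta=meta)


def simulate_relative_pair(
    freqs: np.ndarray,
    degree: int | str,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two pseudo-haploid call vectors for a related pair.

    ``degree`` 0 means identical (same diploid genome), 1/2/3 the usual
    relatedness degrees, or "unrelated". Degree d >= 1 shares one parental
    haplotype over a fraction 2^(1-d) of sites (IBD1), giving genome-wide
    IBD proportion 2^-d and expected mismatch-rate ratios 0.5, 0.75,
    0.875, 0.9375, 1.0 relative to the unrelated baseline.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    s = p.size
    if degree == "unrelated":
        ibd1 = np.zeros(s, dtype=bool)
        identical = False
    elif degree == 0:
        ibd1 = np.zeros(s, dtype=bool)
        identical = True
    elif degree in (1, 2, 3):
        ibd1 = rng.random(s) < 2.0 ** (1 - degree)
        identical = False
    else:
        raise ValueError("degree must be 0..3 or 'unrelated'")

    shared = rng.binomial(1, p)
    h1a, h1b = rng.binomial(1, p), rng.binomial(1, p)
    h2a, h2b = rng.binomial(1, p), rng.binomial(1, p)
    if identical:
        g1 = np.stack([shared, h1b])
        g2 = g1
    else:
        g1 = np.stack([np.where(ibd1, shared, h1a), h1b])
        g2 = np.stack([np.where(ibd1, shared, h2a), h2b])
    pick1 = rng.integers(2, size=s)
    pick2 = rng.integers(2, size=s)
    return g1[pick1, np.arange(s)], g2[pick2, np.arange(s)]


# ---------------------------------------------------------------------------
# Canned demographies used throughout the tests and examples


def two_population_model(f: float = 0.05) -> DemographyModel:
    return DemographyModel(
        populations=["P1", "P2"],
        edges=[("P1", "ROOT", f), ("P2", "ROOT", f)],
    )


def clade_model(
    n_a: int = 8, n_b: int = 9, shared_f: float = 0.02, leaf_f: float = 0.02
) -> DemographyModel:
    """Two true clades {A*} and {B*}: every f4(Ai, Aj; Bk, Bl) is zero."""
    edges = [("NA", "ROOT", shared_f), ("NB", "ROOT", shared_f)]
    pops = []
    for i in range(n_a):
        pops.append(f"A{i}")
        edges.append((f"A{i}", "NA", leaf_f))
    for i in range(n_b):
        pops.append(f"B{i}")
        edges.append((f"B{i}", "NB", leaf_f))
    return DemographyModel(populations=pops, edges=edges)


def admixture_model(alpha: float = 0.3, residual_f: float = 0.005) -> DemographyModel:
    """qpAdm-style scenario: target T = alpha * (S1 side) + (1 - alpha) * (S2 side).

    Sampled populations: outgroup OUT, distal references R1..R3 splitting
    at different depths, proximal sources S1 and S2 (sisters of the true
    mixing populations), and the admixed target T with residual drift.
    """
    edges = [
        ("OUT", "ROOT", 0.10),
        ("X0", "ROOT", 0.02),
        ("R1", "X0", 0.05),
        ("X1", "X0", 0.02),
        ("BR_A", "X1", 0.03),
        ("BR_B", "X1", 0.03),
        ("R2", "BR_A", 0.04),
        ("PA", "BR_A", 0.02),
        ("R3", "BR_B", 0.04),
        ("PB", "BR_B", 0.02),
        ("S1", "PA", 0.02),
        ("MA", "PA", 0.01),
        ("S2", "PB", 0.02),
        ("MB", "PB", 0.01),
        ("T", "TMIX", residual_f),  # residual drift below the mixture node
    ]
    return DemographyModel(
        populations=["OUT", "R1", "R2", "R3", "S1", "S2", "T"],
        edges=edges,
        admixture_edges=[("TMIX", "MA", "MB", alpha, 0)],
    )
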