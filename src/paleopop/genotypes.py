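"""Genotype containers, EIGENSTRAT text I/O, site filters and block assignment.

The in-memory representation is a :class:`GenotypeMatrix` holding derived
(alt) allele dosages. On disk the EIGENSTRAT ``.geno`` digit follows the
format's convention and counts copies of the *reference* allele: ``0`` means
two alt copies, ``2`` two ref copies, ``9`` missing. Pseudo-haploid
individuals carry internal dosages in {0, 1} (ploidy 1) and are written as
0/2/9; a het digit ``1`` on a pseudo-haploid individual is malformed input.

Physical positions are 1-based as in EIGENSTRAT; no strand flipping is ever
performed (capture data are assumed pre-harmonized).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GroupMap",
    "AlleleCountTable",
    "BlockAssignment",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_group_map",
    "write_group_map",
    "filter_sites",
    "assign_blocks",
    "group_counts",
]

MISSING = -1

SNP_COLUMNS = ["id", "chrom", "genetic_pos", "physical_pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Per-individual, per-SNP derived-allele dosages.

    ``calls`` has shape (n_snps, n_individuals) with values in
    {0..ploidy} and ``MISSING`` (=-1) for no-calls. ``ploidy`` is 1 for
    pseudo-haploid individuals and 2 for diploids.
    """

    snps: pd.DataFrame  # columns SNP_COLUMNS, sorted by (chrom, physical_pos)
    individuals: list[str]
    ploidy: np.ndarray  # (n_ind,) in {1, 2}
    calls: np.ndarray  # (n_snp, n_ind) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        n_snp, n_ind = self.calls.shape
        if len(self.snps) != n_snp:
            raise ValueError("snps table and calls matrix disagree on SNP count")
        if len(self.individuals) != n_ind or self.ploidy.size != n_ind:
            raise ValueError("individual metadata and calls matrix disagree")
        if len(set(self.individuals)) != n_ind:
            raise ValueError("individual ids must be unique")
        bad = (self.calls > self.ploidy[None, :]) & (self.calls != MISSING)
        if bad.any():
            raise ValueError("dosage exceeds ploidy")

    @property
    def n_snps(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def individual_index(self, ind: str) -> int:
        try:
            return self.individuals.index(ind)
        except ValueError:
            raise KeyError(f"unknown individual {ind!r}") from None


GroupMap = dict  # individual id -> group label


@dataclass
class AlleleCountTable:
    """Per-group derived-allele count x and observed chromosome count n.

    ``n == 0`` encodes group-missing at that SNP. This table is the
    substrate of every f-statistic: the group frequency is p = x / n.
    """

    groups: list[str]
    x: np.ndarray  # (n_group, n_snp) float
    n: np.ndarray  # (n_group, n_snp) float
    snps: pd.DataFrame | None = None
    blocks: np.ndarray | None = None  # per-SNP block index
    n_blocks: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.x.shape != self.n.shape:
            raise ValueError("x and n must have equal shapes")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("require 0 <= x <= n")
        if self.blocks is None:
            # single-block fallback; callers needing SEs must assign blocks
            self.blocks = np.zeros(self.x.shape[1], dtype=int)
            self.n_blocks = 1

    @property
    def n_snps(self) -> int:
        return self.x.shape[1]

    def index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None

    def with_blocks(self, assignment: "BlockAssignment") -> "AlleleCountTable":
        return replace(
            self, blocks=assignment.block_of, n_blocks=assignment.n_blocks
        )


@dataclass
class BlockAssignment:
    """Contiguous jackknife blocks: SNP index -> block index."""

    block_of: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.block_of = np.asarray(self.block_of, dtype=int)
        if self.weights.size == 0:
            self.weights = np.bincount(self.block_of).astype(float)

    @property
    def n_blocks(self) -> int:
        return int(self.block_of.max()) + 1 if self.block_of.size else 0


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O


def read_eigenstrat(prefix: str, pseudo_haploid: list[str] | None = None) -> GenotypeMatrix:
    """Read an EIGENSTRAT ``.geno``/``.snp``/``.ind`` trio.

    Individuals whose genotype column never shows a het digit ``1`` are
    auto-flagged pseudo-haploid unless ``pseudo_haploid`` explicitly lists
    the pseudo-haploid ids (possibly empty, forcing all-diploid).
    """
    ind = pd.read_csv(
        f"{prefix}.ind", sep=r"\s+", header=None, names=["id", "sex", "group"],
        dtype=str,
    )
    snp = pd.read_csv(
        f"{prefix}.snp", sep=r"\s+", header=None, names=SNP_COLUMNS,
        dtype={"id": str, "chrom": str, "ref": str, "alt": str},
    )
    snp["genetic_pos"] = snp["genetic_pos"].astype(float)
    snp["physical_pos"] = snp["physical_pos"].astype(int)

    individuals = ind["id"].tolist()
    n_ind = len(individuals)
    rows = []
    with open(f"{prefix}.geno") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise ValueError(
                    f"{prefix}.geno line {i + 1}: {len(line)} genotypes for "
                    f"{n_ind} individuals"
                )
            row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            if np.any((row > 2) & (row != 9)):
                raise ValueError(f"{prefix}.geno line {i + 1}: unknown genotype code")
            rows.append(row)
    if len(rows) != len(snp):
        raise ValueError(
            f"{prefix}.snp has {len(snp)} rows but {prefix}.geno has {len(rows)}"
        )
    ref_count = np.array(rows, dtype=np.int16).reshape(len(rows), n_ind)

    has_het = (ref_count == 1).any(axis=0)
    if pseudo_haploid is None:
        is_ph = ~has_het
    else:
        is_ph = np.array([i in set(pseudo_haploid) for i in individuals])
        if np.any(is_ph & has_het):
            bad = [i for i, p, h in zip(individuals, is_ph, has_het) if p and h]
            raise ValueError(f"pseudo-haploid individuals with het calls: {bad}")
    ploidy = np.where(is_ph, 1, 2).astype(np.int8)

    calls = np.where(ref_count == 9, MISSING, 2 - ref_count).astype(np.int8)
    # pseudo-haploid: on-disk 0/2 (alt/ref homozygote-like) -> dosage 1/0
    ph = np.where(is_ph)[0]
    col = calls[:, ph]
    calls[:, ph] = np.where(col == 2, 1, col)
    return GenotypeMatrix(snps=snp, individuals=individuals, ploidy=ploidy, calls=calls)


def write_eigenstrat(
    matrix: GenotypeMatrix, prefix: str, groups: GroupMap | None = None
) -> None:
    """Write the EIGENSTRAT text dialect (``.geno``/``.snp``/``.ind``)."""
    # ref-allele copies: diploid digit = 2 - dosage; pseudo-haploid carries
    # dosage in {0, 1} internally and is written homozygote-like (2/0)
    out = 2 - np.where(matrix.ploidy[None, :] == 1, 2 * matrix.calls.astype(np.int16),
                       matrix.calls.astype(np.int16))
    out[matrix.calls == MISSING] = 9
    if np.any((out < 0) | ((out > 2) & (out != 9))):
        raise ValueError("dosage out of range for EIGENSTRAT encoding")
    digits = np.char.mod("%d", out)
    with open(f"{prefix}.geno", "w") as fh:
        for row in digits:
            fh.write("".join(row) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for r in matrix.snps.itertuples(index=False):
            fh.write(
                f"{r.id}\t{r.chrom}\t{r.genetic_pos:.6f}\t{r.physical_pos}"
                f"\t{r.ref}\t{r.alt}\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for ind in matrix.individuals:
            grp = groups.get(ind, "Ignore") if groups else "Ignore"
            fh.write(f"{ind}\tU\t{grp}\n")


def read_group_map(path: str) -> GroupMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "group"], dtype=str)
    return dict(zip(df["id"], df["group"]))


def write_group_map(groups: GroupMap, path: str) -> None:
    with open(path, "w") as fh:
        for ind, grp in groups.items():
            fh.write(f"{ind}\t{grp}\n")


# ---------------------------------------------------------------------------
# Filters, blocks, counts


def filter_sites(
    matrix: GenotypeMatrix,
    groups: GroupMap,
    maxmiss: float = 0.15,
    min_maf: float = 0.0,
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs by group-level missingness and minor-allele frequency.

    A SNP is dropped when the fraction of groups with no observed allele
    (n = 0) exceeds ``maxmiss``, or when its overall MAF is below
    ``min_maf``. The default ``maxmiss`` mirrors the graph-search extract
    step. Returns the filtered matrix and a report dict with kept/dropped
    counts and the number of kept SNPs polymorphic among the groups.
    """
    if not 0 <= maxmiss <= 1:
        raise ValueError("maxmiss must be in [0, 1]")
    counts = group_counts(matrix, groups)
    miss_frac = (counts.n == 0).mean(axis=0)
    tot_x = counts.x.sum(axis=0)
    tot_n = counts.n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot_n > 0, tot_x / np.maximum(tot_n, 1), np.nan)
    maf = np.fmin(p, 1 - p)
    keep = (miss_frac <= maxmiss) & ~(np.nan_to_num(maf, nan=-1.0) < min_maf)
    keep &= tot_n > 0
    kept_idx = np.where(keep)[0]
    sub_p = p[kept_idx]
    poly = int(np.sum((sub_p > 0) & (sub_p < 1)))
    report = {
        "kept": int(keep.sum()),
        "dropped": int((~keep).sum()),
        "polymorphic_kept": poly,
    }
    out = GenotypeMatrix(
        snps=matrix.snps.iloc[kept_idx].reset_index(drop=True),
        individuals=list(matrix.individuals),
        ploidy=matrix.ploidy.copy(),
        calls=matrix.calls[kept_idx],
    )
    return out, report


def assign_blocks(matrix: GenotypeMatrix, block_length: float | None = None) -> BlockAssignment:
    """Greedy contiguous jackknife blocks of at most ``block_length``.

    Uses genetic positions (Morgans, default block 0.05 M) when they are
    informative, otherwise physical positions (default 5 Mb). Chromosome
    boundaries always start a new block.
    """
    snps = matrix.snps
    chrom = snps["chrom"].to_numpy()
    gpos = snps["genetic_pos"].to_numpy(dtype=float)
    ppos = snps["physical_pos"].to_numpy(dtype=float)
    use_genetic = bool(np.any(gpos > 0))
    pos = gpos if use_genetic else ppos
    if block_length is None:
        block_length = 0.05 if use_genetic else 5_000_000.0
    if block_length <= 0:
        raise ValueError("block_length must be positive")

    block = np.empty(len(snps), dtype=int)
    b = -1
    prev_chrom = None
    start = 0.0
    prev_pos = -np.inf
    for i in range(len(snps)):
        if chrom[i] != prev_chrom:
            b += 1
            prev_chrom = chrom[i]
            start = pos[i]
            prev_pos = -np.inf
        elif pos[i] < prev_pos:
            raise ValueError("SNPs not sorted by position within chromosome")
        elif pos[i] - start > block_length:
            b += 1
            start = pos[i]
        prev_pos = pos[i]
        block[i] = b
    return BlockAssignment(block_of=block)


def assign_blocks_equal(n_snps: int, n_blocks: int) -> BlockAssignment:
    """Equal SNP-count contiguous blocks (simulation convenience)."""
    if not 2 <= n_blocks <= n_snps:
        raise ValueError("need n_snps >= n_blocks >= 2")
    edges = np.linspace(0, n_snps, n_blocks + 1).astype(int)
    block = np.zeros(n_snps, dtype=int)
    for b in range(n_blocks):
        block[edges[b]: edges[b + 1]] = b
    return BlockAssignment(block_of=block)


def group_counts(matrix: GenotypeMatrix, groups: GroupMap) -> AlleleCountTable:
    """Collapse individual dosages to per-group (x, n) allele counts."""
    if not groups:
        raise ValueError("group map is empty")
    labels = sorted(set(groups.values()))
    for ind in groups:
        if ind not in matrix.individuals:
            raise KeyError(f"labeled individual {ind!r} not in matrix")
    x = np.zeros((len(labels), matrix.n_snps))
    n = np.zeros((len(labels), matrix.n_snps))
    observed = matrix.calls != MISSING
    dosage = np.where(observed, matrix.calls, 0).astype(float)
    for gi, label in enumerate(labels):
        members = [matrix.individual_index(i) for i, g in groups.items() if g == label]
        if not members:
            raise ValueError(f"group {label!r} has no members")
        x[gi] = dosage[:, members].sum(axis=1)
        n[gi] = (observed[:, members] * matrix.ploidy[members][None, :]).sum(axis=1)
    return AlleleCountTable(groups=labels, x=x, n=n, snps=matrix.snps)
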