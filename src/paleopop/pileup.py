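"""Adaptive pseudo-haploid calling from per-site pileups.

The caller estimates sequencing/damage error rates empirically from the
sample's own reads at sites assumed monomorphic, stratified by library
type, SNP base pair, read position (terminal vs central), strand, mapping
quality and base quality. Directed error rates E(a->b) are made symmetric,
S = max{E(a,b), E(b,a)}, to avoid thresholding bias, and bases whose S is
below a parametric threshold (default 0.02) form a pileup of reliable
bases from which one is chosen uniformly at random. The threshold is an
upper bound on the error of every base that can enter a call.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "classify_position",
    "mq_bin",
    "bq_bin",
    "Observation",
    "PileupColumn",
    "ErrorTable",
    "estimate_error_rates",
    "call_pseudohaploid",
    "call_pileup_frame",
    "damage_qc",
]

BASES = ("A", "C", "G", "T")
POSITION_CLASSES = ("terminal_5", "terminal_3", "central")
TERMINAL_SPAN = 10  # bases within this distance of a read end are terminal

STRATUM_AXES = ["library_type", "pos_class", "strand", "mq_bin", "bq_bin"]


def classify_position(distance_5prime: int, distance_3prime: int) -> str:
    """Central iff more than 10 bases from both read ends; ties go 5'."""
    if distance_5prime < 0 or distance_3prime < 0:
        raise ValueError("distances must be non-negative")
    if distance_5prime > TERMINAL_SPAN and distance_3prime > TERMINAL_SPAN:
        return "central"
    return "terminal_5" if distance_5prime <= distance_3prime else "terminal_3"


def mq_bin(mq: float) -> str:
    return "mq_ge30" if mq >= 30 else "mq_lt30"


def bq_bin(bq: float) -> str:
    if bq >= 30:
        return "bq_ge30"
    return "bq_20_29" if bq >= 20 else "bq_lt20"


class Observation(NamedTuple):
    base: str
    strand: str  # '+' or '-'
    pos_class: str
    mq_bin: str
    bq_bin: str
    library_id: str
    library_type: str  # e.g. 'ds_UDG', 'ss_noUDG'

    def stratum(self) -> tuple:
        return (self.library_type, self.pos_class, self.strand,
                self.mq_bin, self.bq_bin)


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref: str
    alt: str
    observations: list[Observation] = field(default_factory=list)


@dataclass
class ErrorTable:
    """Directed error rates E(a->b) per stratum, with observation counts.

    ``rates`` maps (library_type, pos_class, strand, mq_bin, bq_bin,
    from_base, to_base) -> (rate, n_obs). Cells absent from the map are
    undefined (no observations of the from-base in that stratum) and are
    treated as failing the reliability threshold downstream.
    """

    rates: dict[tuple, tuple[float, int]] = field(default_factory=dict)

    def rate(self, stratum: tuple, a: str, b: str) -> float | None:
        cell = self.rates.get((*stratum, a, b))
        return None if cell is None else cell[0]

    def symmetric(self, stratum: tuple, a: str, b: str) -> float | None:
        """S = max{E(a,b), E(b,a)}; None when either direction is undefined."""
        ab = self.rate(stratum, a, b)
        ba = self.rate(stratum, b, a)
        if ab is None or ba is None:
            return None
        return max(ab, ba)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**dict(zip(STRATUM_AXES, k[:5])), "from_base": k[5], "to_base": k[6],
             "rate": v[0], "n_obs": v[1]}
            for k, v in sorted(self.rates.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ErrorTable":
        rates = {}
        for r in df.itertuples(index=False):
            key = (r.library_type, r.pos_class, r.strand, r.mq_bin, r.bq_bin,
                   r.from_base, r.to_base)
            rates[key] = (float(r.rate), int(r.n_obs))
        return cls(rates=rates)


def estimate_error_rates(pileup: pd.DataFrame) -> ErrorTable:
    """Empirical error table from reads at assumed-monomorphic sites.

    ``pileup`` needs columns ``truth`` (the monomorphic base), ``base``,
    and the stratum axes ``library_type, pos_class, strand, mq_bin,
    bq_bin``. Within each stratum, E(a->b) is the fraction of reads with
    true base a observed as b. Cells for every alternative b are emitted
    whenever the stratum has observations of a, so a clean stratum yields
    defined zero rates rather than undefined cells.
    """
    required = set(STRATUM_AXES + ["truth", "base"])
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup frame missing columns: {sorted(missing)}")
    totals = pileup.groupby(STRATUM_AXES + ["truth"], observed=True).size()
    mism = pileup.groupby(STRATUM_AXES + ["truth", "base"], observed=True).size()
    rates: dict[tuple, tuple[float, int]] = {}
    for key, total in totals.items():
        *stratum, a = key
        for b in BASES:
            if b == a:
                continue
            count = int(mism.get((*stratum, a, b), 0))
            rates[(*stratum, a, b)] = (count / total, int(total))
    return ErrorTable(rates=rates)


def _site_rng(seed: int, chrom: str, pos: int) -> np.random.Generator:
    # keyed by (seed, chrom, pos): per-site calls are order-independent
    key = (int(seed), zlib.crc32(str(chrom).encode()), int(pos))
    return np.random.default_rng(np.random.SeedSequence(key))


def reliable_bases(
    column: PileupColumn, table: ErrorTable, threshold: float = 0.02
) -> list[Observation]:
    out = []
    for obs in column.observations:
        if obs.base not in (column.ref, column.alt):
            continue  # tri-allelic read, never eligible
        s = table.symmetric(obs.stratum(), column.ref, column.alt)
        if s is not None and s < threshold:
            out.append(obs)
    return out


def call_pseudohaploid(
    column: PileupColumn,
    table: ErrorTable,
    threshold: float = 0.02,
    seed: int = 0,
) -> str | None:
    """One seeded random draw from the reliable pileup; None = missing."""
    pool = reliable_bases(column, table, threshold)
    if not pool:
        return None
    rng = _site_rng(seed, column.chrom, column.pos)
    return pool[int(rng.integers(len(pool)))].base


def call_pileup_frame(
    pileup: pd.DataFrame,
    table: ErrorTable,
    threshold: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Call every (library_id, site) in a pileup TSV frame.

    Expects columns chrom, pos, ref, alt, base, strand, pos_class, mq_bin,
    bq_bin, library_id, library_type. Returns one row per library and site
    with the called allele (NaN = missing) and the alt dosage in {0, 1}.
    """
    rows = []
    grouped = pileup.groupby(["library_id", "chrom", "pos"], observed=True, sort=True)
    for (lib, chrom, pos), g in grouped:
        ref, alt = g["ref"].iloc[0], g["alt"].iloc[0]
        col = PileupColumn(
            chrom=str(chrom), pos=int(pos), ref=ref, alt=alt,
            observations=[
                Observation(r.base, r.strand, r.pos_class, r.mq_bin, r.bq_bin,
                            str(lib), r.library_type)
                for r in g.itertuples(index=False)
            ],
        )
        call = call_pseudohaploid(col, table, threshold, seed)
        rows.append({
            "library_id": str(lib), "chrom": str(chrom), "pos": int(pos),
            "ref": ref, "alt": alt, "call": call,
            "dosage": np.nan if call is None else int(call == alt),
        })
    return pd.DataFrame(rows)


def damage_qc(terminal_ct_rate: float, udg_treated: bool) -> bool:
    """True = flag library as potentially contaminated.

    Authentic ancient libraries retain terminal C->T damage; the flag fires
    when the rate is below 3% (UDG-treated) or 10% (non-UDG).
    """
    if not 0 <= terminal_ct_rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    floor = 0.03 if udg_treated else 0.10
    return terminal_ct_rate < floor
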