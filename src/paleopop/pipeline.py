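"""Pipeline orchestration: configuration, fixture generation, and an
end-to-end run over synthetic data with a written manifest.

Stages run in dependency order (simulate -> f-statistics -> qpWave/qpAdm ->
graph search -> MDS/NJ -> kinship -> ROH); every stochastic stage draws its
seed from the run configuration, completed stages are skipped on re-run,
and the manifest records seeds, inputs and per-stage outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fstats, qpadm, roh, simulate, structure
from .genotypes import write_eigenstrat, write_group_map

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 1
    n_snps: int = 50_000
    samples_per_pop: int = 10
    n_blocks: int = 50
    missing_rate: float = 0.05
    caller_threshold: float = 0.02
    maxmiss: float = 0.15
    fdr: float = 0.05
    fst_snp_floor: int = 5000
    roh_snp_floor: int = 400_000
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "fstats", "qpadm", "structure", "roh",
    ])

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _checksum(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def make_fixtures(seed: int, out_dir: str) -> dict:
    """Deterministic small-scale bundle exercising every reader.

    A 6-population demography with one admixture event (EIGENSTRAT trio +
    group labels), pileups for 4 individuals, ROH tables for 3 groups, and
    2 relative pairs; a truth file records the generating parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = simulate.admixture_model(alpha=0.3)
    config = simulate.SimulationConfig(
        n_snps=50_000, samples_per_pop=6, missing_rate=0.05, n_blocks=50,
        seed=seed,
    )
    freqs = simulate.simulate_frequencies(model, config)
    # drop OUT to keep 6 sampled populations
    sampled = {p: freqs[p] for p in ["OUT", "R1", "R2", "R3", "S1", "S2", "T"]}
    matrix, labels, blocks = simulate.simulate_genotypes(sampled, config)
    write_eigenstrat(matrix, str(out / "genotypes"), labels)
    write_group_map(labels, str(out / "groups.tsv"))

    error_profile = simulate.ErrorTable(rates={})
    truth4 = simulate.simulate_genotypes(
        {p: sampled[p][:200] for p in ["S1", "S2", "T", "OUT"]},
        simulate.SimulationConfig(n_snps=200, samples_per_pop=1, n_blocks=2,
                                  seed=seed + 1),
    )[0]
    pileups = simulate.simulate_pileups(truth4, coverage=2.0,
                                        error_profile=error_profile,
                                        seed=seed + 2)
    pileups.to_csv(out / "pileups.tsv", sep="\t", index=False)

    rohset = simulate.simulate_roh(
        ne=500, chromosome_map_lengths=roh.DEFAULT_CHROMOSOME_MORGANS,
        n_individuals=9, seed=seed + 3,
    )
    rohset.meta.loc[:, "group"] = np.repeat(["g1", "g2", "g3"], 3)
    rohset.segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    rohset.meta.to_csv(out / "roh_meta.tsv", sep="\t", index=False)

    pair_freqs = sampled["T"][:20_000]
    for degree, tag in [(1, "first"), ("unrelated", "unrelated")]:
        a, b = simulate.simulate_relative_pair(pair_freqs, degree, seed=seed + 4)
        np.savetxt(out / f"pair_{tag}.tsv", np.column_stack([a, b]), fmt="%d",
                   delimiter="\t")
    truth = {
        "alpha": 0.3, "ne": 500, "seed": seed,
        "populations": list(sampled), "n_snps": config.n_snps,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages over a synthetic scenario.

    Returns (and writes) a manifest with per-stage outputs and checksums;
    stages whose outputs already exist are skipped, so re-runs are
    idempotent. Any stage error halts the run with the partial manifest
    saved under ``manifest.partial.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"seed": config.seed, "stages": {}}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    def done(stage: str) -> bool:
        return stage in manifest["stages"]

    model = simulate.admixture_model(alpha=0.3)
    sim_cfg = simulate.SimulationConfig(
        n_snps=config.n_snps, samples_per_pop=config.samples_per_pop,
        missing_rate=config.missing_rate, n_blocks=config.n_blocks,
        seed=config.seed,
    )
    counts = None

    try:
        for stage in config.stages:
            if done(stage):
                continue
            if stage == "simulate":
                freqs = simulate.simulate_frequencies(model, sim_cfg)
                counts = simulate.simulate_counts(freqs, sim_cfg)
                np.save(out / "counts_x.npy", counts.x)
                np.save(out / "counts_n.npy", counts.n)
                manifest["stages"]["simulate"] = {
                    "populations": counts.groups, "n_snps": counts.n_snps,
                }
            else:
                if counts is None:
                    freqs = simulate.simulate_frequencies(model, sim_cfg)
                    counts = simulate.simulate_counts(freqs, sim_cfg)
                if stage == "fstats":
                    res = fstats.f4(counts, "OUT", "T", "S1", "S2")
                    manifest["stages"]["fstats"] = {
                        "f4_out_t_s1_s2": res.estimate, "z": res.z,
                        "n_snps": res.n_snps,
                    }
                elif stage == "qpadm":
                    fit = qpadm.qpadm_fit(
                        counts, "T", ["S1", "S2"], ["OUT", "R1", "R2", "R3"],
                    )
                    manifest["stages"]["qpadm"] = {
                        "weights": fit.weights.tolist(),
                        "se": fit.se.tolist(), "p": fit.p_value,
                        "feasible": fit.feasible,
                    }
                elif stage == "structure":
                    dm = structure.outgroup_f3_distance(
                        counts, ["R1", "R2", "R3", "S1", "S2", "T"], "OUT"
                    )
                    mds = structure.classical_mds(dm, k=2)
                    nwk = structure.neighbor_joining(dm, root_at="R1")
                    (out / "tree.nwk").write_text(nwk + "\n")
                    manifest["stages"]["structure"] = {
                        "mds_eigenvalues": mds["eigenvalues"][:2].tolist(),
                        "tree": _checksum(out / "tree.nwk"),
                    }
                elif stage == "roh":
                    rohset = simulate.simulate_roh(
                        ne=500,
                        chromosome_map_lengths=roh.DEFAULT_CHROMOSOME_MORGANS,
                        n_individuals=20, seed=config.seed + 7,
                    )
                    eligible = roh.eligibility_filter(rohset)
                    est = roh.ne_mle(eligible)
                    manifest["stages"]["roh"] = {
                        "ne": est.point, "ci": [est.ci_low, est.ci_high],
                        "n": est.n_individuals,
                    }
                else:
                    raise ValueError(f"unknown stage {stage!r}")
            manifest_path.write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return manifest
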