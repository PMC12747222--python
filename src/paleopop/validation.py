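"""Calibration and recovery experiments run end-to-end on synthetic data.

Each experiment generates its own inputs from the synthetic-data module,
runs the corresponding inference stage, and reports summary numbers. They
are the package's evidence that the estimators are calibrated (null Z-score
rates, p-value uniformity, confidence-interval coverage) and that planted
truths (admixture proportions, graph topologies, effective sizes,
relatedness degrees) are recovered. Problem sizes default to desk scale:
every experiment runs in seconds to a few minutes on one core.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

from . import fstats, graphs, kinship, pileup, qpadm, roh, simulate, structure
from .genotypes import assign_blocks_equal

__all__ = [
    "f_identity_suite",
    "clade_null_experiment",
    "qpadm_recovery_experiment",
    "qpwave_calibration_experiment",
    "graph_recovery_experiment",
    "caller_contract_experiment",
    "kinship_experiment",
    "roh_recovery_experiment",
    "nj_mds_experiment",
]


def f_identity_suite(seed: int = 0) -> dict:
    """Exact linear identities of the f-statistic algebra on a random
    complete count table; returns the largest absolute deviation."""
    rng = np.random.default_rng(seed)
    from .genotypes import AlleleCountTable

    s = 500
    x = rng.integers(1, 20, size=(5, s)).astype(float)
    t = AlleleCountTable(groups=list("ABCDE"), x=x, n=np.full((5, s), 20.0),
                         blocks=assign_blocks_equal(s, 10).block_of,
                         n_blocks=10)
    f2 = lambda a, b: fstats.f2(t, a, b).estimate
    f4 = lambda a, b, c, d: fstats.f4(t, a, b, c, d).estimate
    f3 = lambda a, b, c: fstats.f3(t, a, b, c).estimate
    devs = [
        abs(f4("A", "B", "C", "D") + f4("A", "B", "D", "E")
            - f4("A", "B", "C", "E")),
        abs(f4("A", "B", "C", "D") - f4("C", "D", "A", "B")),
        abs(f4("A", "B", "C", "D") + f4("A", "B", "D", "C")),
        abs(f3("A", "B", "C") - (f2("A", "B") + f2("A", "C") - f2("B", "C")) / 2),
        abs(f4("A", "B", "C", "C")),
        abs(f2("A", "A")),
    ]
    return {"max_deviation": float(max(devs)), "n_identities": len(devs)}


def clade_null_experiment(
    seed: int = 0,
    n_snps: int = 100_000,
    n_blocks: int = 50,
    n_a: int = 8,
    n_b: int = 9,
) -> dict:
    """f4 Z-scores across two true clades: fraction with |Z| > 1.96.

    With 8 and 9 clade members there are 28 * 36 = 1008 f4 statistics of
    the form f4(Ai, Aj; Bk, Bl), all exactly zero in expectation.
    """
    cfg = simulate.SimulationConfig(n_snps=n_snps, samples_per_pop=10,
                                    n_blocks=n_blocks, seed=seed)
    model = simulate.clade_model(n_a=n_a, n_b=n_b)
    counts = simulate.simulate_counts(simulate.simulate_frequencies(model, cfg),
                                      cfg)
    quads = [
        (a1, a2, b1, b2)
        for a1, a2 in itertools.combinations([f"A{i}" for i in range(n_a)], 2)
        for b1, b2 in itertools.combinations([f"B{i}" for i in range(n_b)], 2)
    ]
    zs = np.array([r.z for r in fstats.f4_many(counts, quads)])
    return {
        "n_statistics": len(quads),
        "rate_abs_z_gt_196": float(np.mean(np.abs(zs) > 1.96)),
        "mean_z": float(zs.mean()),
        "sd_z": float(zs.std()),
    }


def qpadm_recovery_experiment(
    seed: int = 0,
    n_reps: int = 200,
    n_snps: int = 200_000,
    alpha: float = 0.3,
) -> dict:
    """Planted two-source mixture: weight recovery and CI coverage."""
    within3 = 0
    covered = 0
    weights, ses, ps = [], [], []
    model = simulate.admixture_model(alpha=alpha)
    for rep in range(n_reps):
        cfg = simulate.SimulationConfig(n_snps=n_snps, samples_per_pop=10,
                                        n_blocks=100,
                                        seed=(seed + 1000 * rep) % 2**31)
        counts = simulate.simulate_counts(
            simulate.simulate_frequencies(model, cfg), cfg)
        fit = qpadm.qpadm_fit(counts, "T", ["S1", "S2"],
                              ["OUT", "R1", "R2", "R3"])
        w, se = float(fit.weights[0]), float(fit.se[0])
        weights.append(w)
        ses.append(se)
        ps.append(fit.p_value)
        within3 += abs(w - alpha) <= 3 * se
        covered += (w - 1.96 * se) <= alpha <= (w + 1.96 * se)
    return {
        "n_reps": n_reps,
        "alpha_true": alpha,
        "mean_weight": float(np.mean(weights)),
        "mean_se": float(np.mean(ses)),
        "within_3se_rate": within3 / n_reps,
        "ci95_coverage": covered / n_reps,
        "mean_model_p": float(np.mean(ps)),
    }


def qpwave_calibration_experiment(
    seed: int = 0, n_reps: int = 200, n_snps: int = 50_000
) -> dict:
    """Rank-0 qpWave p-values under a true clade null: KS uniformity."""
    ps = []
    for rep in range(n_reps):
        cfg = simulate.SimulationConfig(n_snps=n_snps, samples_per_pop=10,
                                        n_blocks=200,
                                        seed=(seed + 977 * rep) % 2**31)
        model = simulate.clade_model(n_a=2, n_b=5, shared_f=0.02, leaf_f=0.02)
        counts = simulate.simulate_counts(
            simulate.simulate_frequencies(model, cfg), cfg)
        rt = qpadm.qpwave(counts, ["A0", "A1"], [f"B{i}" for i in range(5)],
                          r=0)
        ps.append(rt.p_value)
    ks = sps.kstest(ps, "uniform")
    return {
        "n_reps": n_reps,
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "rejection_rate_05": float(np.mean(np.asarray(ps) < 0.05)),
    }


TRUE_TREE = graphs.AdmixtureGraph(
    leaves=["A", "B", "C", "D"],
    drift_edges=[("A", "AB"), ("B", "AB"), ("C", "CD"), ("D", "CD"),
                 ("AB", "R"), ("CD", "R")],
)

TREE_MODEL = simulate.DemographyModel(
    populations=["A", "B", "C", "D"],
    edges=[("AB", "ROOT", 0.02), ("CD", "ROOT", 0.02),
           ("A", "AB", 0.03), ("B", "AB", 0.04),
           ("C", "CD", 0.05), ("D", "CD", 0.02)],
)


def graph_recovery_experiment(
    seed: int = 0, n_reps: int = 100, n_snps: int = 200_000
) -> dict:
    """Does the generating 4-leaf topology attain the best fit score?

    All 15 labeled rooted topologies are fitted per replicate; root
    placement is unidentifiable from f2 distances, so rooted variants of
    the generating unrooted tree tie — attaining the minimum (within a
    small tolerance) counts as recovery. A 3-population exhaustive search
    is also compared against the randomized search once.
    """
    trees = graphs.enumerate_trees(["A", "B", "C", "D"])
    true_hash = TRUE_TREE.topology_hash()
    wins = 0
    for rep in range(n_reps):
        cfg = simulate.SimulationConfig(n_snps=n_snps, samples_per_pop=10,
                                        n_blocks=50,
                                        seed=(seed + 131 * rep) % 2**31)
        counts = simulate.simulate_counts(
            simulate.simulate_frequencies(TREE_MODEL, cfg), cfg)
        tab = fstats.extract_f2(counts)
        scores = {t.topology_hash(): graphs.fit_graph(t, tab, n_starts=2,
                                                      seed=rep).score
                  for t in trees}
        best = min(scores.values())
        wins += scores[true_hash] <= best * (1 + 1e-6) + 1e-9

    # randomized search agrees with exhaustive enumeration on 3 populations
    model3 = simulate.DemographyModel(
        populations=["A", "B", "C"],
        edges=[("AB", "ROOT", 0.03), ("C", "ROOT", 0.04),
               ("A", "AB", 0.02), ("B", "AB", 0.02)],
    )
    cfg = simulate.SimulationConfig(n_snps=50_000, samples_per_pop=10,
                                    n_blocks=50, seed=seed)
    counts3 = simulate.simulate_counts(
        simulate.simulate_frequencies(model3, cfg), cfg)
    tab3 = fstats.extract_f2(counts3)
    exhaustive = min(
        graphs.fit_graph(t, tab3, n_starts=2, seed=1).score
        for t in graphs.enumerate_trees(["A", "B", "C"])
    )
    searched = graphs.find_graphs(tab3, ["A", "B", "C"], n_admix=0,
                                  iterations=5, seed=seed)[0]["score"]
    return {
        "n_reps": n_reps,
        "recovery_rate": wins / n_reps,
        "exhaustive_vs_search_gap": float(abs(exhaustive - searched)),
    }


def caller_contract_experiment(seed: int = 0, n_sites: int = 100_000) -> dict:
    """Reliable-pileup contract of the adaptive caller.

    Simulates one individual with heavy terminal damage (error 0.30) and
    low central error (0.005), estimates the stratified error table from
    the same reads, calls pseudo-haploid genotypes at S < 0.02, and
    measures the achieved error against the truth. Terminal strata fail
    the threshold, so every call must come from central reads and the
    achieved error stays below the threshold.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)
    cfg = simulate.SimulationConfig(n_snps=n_sites, samples_per_pop=1,
                                    n_blocks=2, seed=seed)
    truth, _, _ = simulate.simulate_genotypes({"P": p}, cfg)
    prof = pileup.ErrorTable()
    for strand in "+-":
        for mq in ("mq_ge30", "mq_lt30"):
            for bq in ("bq_ge30", "bq_20_29"):
                for pc, rate in (("terminal_5", 0.30), ("terminal_3", 0.30),
                                 ("central", 0.005)):
                    for a, b in (("A", "G"), ("G", "A")):
                        prof.rates[("ds_UDG", pc, strand, mq, bq, a, b)] = (rate, 1)
    pile = simulate.simulate_pileups(truth, coverage=2.0, error_profile=prof,
                                     seed=seed + 1)
    truthbase = np.where(truth.calls[:, 0] == 1, "G", "A")
    key = list(zip(truth.snps["chrom"], truth.snps["physical_pos"]))
    lookup = dict(zip(key, truthbase))
    est = pileup.estimate_error_rates(
        pile.assign(truth=[lookup[(c, q)] for c, q in zip(pile["chrom"],
                                                          pile["pos"])])
    )
    calls = pileup.call_pileup_frame(pile, est, threshold=0.02, seed=seed + 2)
    calls2 = pileup.call_pileup_frame(pile, est, threshold=0.02, seed=seed + 2)
    deterministic = calls.equals(calls2)
    called = calls.dropna(subset=["dosage"])
    truth_dosage = np.array(
        [lookup[(c, q)] == "G" for c, q in zip(called["chrom"], called["pos"])]
    ).astype(float)
    wrong = int(np.sum(called["dosage"].to_numpy() != truth_dosage))
    n_called = len(called)
    # sites whose reads are all terminal must be missing
    central = pile[pile["pos_class"] == "central"]
    sites_with_central = set(zip(central["chrom"], central["pos"]))
    called_sites = set(zip(called["chrom"], called["pos"]))
    leakage = len(called_sites - sites_with_central)
    binom = sps.binomtest(wrong, n_called, 0.02, alternative="less")
    return {
        "n_called": n_called,
        "achieved_error": wrong / n_called,
        "threshold": 0.02,
        "p_error_below_threshold": float(binom.pvalue),
        "calls_outside_reliable_strata": leakage,
        "deterministic": bool(deterministic),
    }


def kinship_experiment(
    seed: int = 0, n_sites: int = 50_000, n_pairs: int = 60
) -> dict:
    """PMR ratios by relatedness degree and first-degree classification."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)
    ba = assign_blocks_equal(n_sites, 50)
    degrees = [(0, "identical"), (1, "first"), (2, "second"),
               ("unrelated", "unrelated")]
    rates = {label: [] for _, label in degrees}
    for rep in range(n_pairs):
        for di, (degree, label) in enumerate(degrees):
            a, b = simulate.simulate_relative_pair(
                p, degree, seed=(seed + 7919 * rep + 101 * di) % 2**31)
            rates[label].append(float(np.mean(a != b)))
    baseline = float(np.median(rates["unrelated"]))
    ratios = {k: float(np.mean(v) / baseline) for k, v in rates.items()}
    ratio_se = {k: float(np.std(v, ddof=1) / np.sqrt(len(v)) / baseline)
                for k, v in rates.items()}

    correct_first = 0
    for r in rates["first"]:
        res = kinship.MismatchResult(pair=("a", "b"), overlap=n_sites,
                                     rate=r, se=r / np.sqrt(n_sites),
                                     informative=True)
        cls = kinship.classify_degree(res, baseline)
        correct_first += cls["degree"] == "first"
    return {
        "n_pairs": n_pairs,
        "ratios": ratios,
        "ratio_se": ratio_se,
        "first_degree_accuracy": correct_first / n_pairs,
    }


def roh_recovery_experiment(
    seed: int = 0, n_reps: int = 100, ne: float = 500.0, n_individuals: int = 40
) -> dict:
    """Constant-Ne MLE recovery and likelihood-ratio CI coverage."""
    points, covered = [], 0
    for rep in range(n_reps):
        rs = simulate.simulate_roh(
            ne, roh.DEFAULT_CHROMOSOME_MORGANS, n_individuals,
            seed=(seed + 613 * rep) % 2**31,
        )
        est = roh.ne_mle(roh.eligibility_filter(rs))
        points.append(est.point)
        covered += est.ci_low <= ne <= est.ci_high
    return {
        "n_reps": n_reps,
        "ne_true": ne,
        "mean_point": float(np.mean(points)),
        "mean_abs_rel_error": float(np.mean(np.abs(np.array(points) / ne - 1))),
        "ci95_coverage": covered / n_reps,
    }


def _newick_leaf_distances(nwk: str) -> dict[tuple[str, str], float]:
    """Pairwise leaf path lengths from a Newick string (no external deps)."""
    import re

    # a clade may carry a length with no name ("):0.5"), so the name part
    # of the name:length alternative must be allowed to be empty
    tokens = re.findall(r"\(|\)|,|;|[^(),;:]*:[-+\d.eE]+|[^(),;:]+", nwk)
    stack: list[list[tuple[str, float, dict]]] = [[]]
    leaf_depths: dict = {}

    def parse_item(tok):
        if ":" in tok:
            name, bl = tok.rsplit(":", 1)
            return name, float(bl)
        return tok, 0.0

    dists: dict[tuple[str, str], float] = {}

    def merge(children):
        # children: list of dicts {leaf: depth} with branch already added
        combined: dict[str, float] = {}
        for i, ci in enumerate(children):
            for j in range(i + 1, len(children)):
                for la, da in ci.items():
                    for lb, db in children[j].items():
                        dists[tuple(sorted((la, lb)))] = da + db
            combined.update(ci)
        return combined

    pos = 0

    def parse_clade():
        nonlocal pos
        if tokens[pos] == "(":
            pos += 1
            kids = []
            while True:
                kids.append(parse_clade())
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            assert tokens[pos] == ")"
            pos += 1
            bl = 0.0
            if pos < len(tokens) and tokens[pos] not in "(),;":
                name, bl = parse_item(tokens[pos])
                pos += 1
            merged = merge(kids)
            return {leaf: d + bl for leaf, d in merged.items()}
        name, bl = parse_item(tokens[pos])
        pos += 1
        return {name: bl}

    top = parse_clade()
    return dists


def nj_mds_experiment(seed: int = 0, n_matrices: int = 100) -> dict:
    """Neighbor joining on random additive matrices and classical MDS on
    planted Euclidean configurations.

    An additive matrix determines its tree uniquely, so exact recovery is
    checked by comparing every patristic leaf distance with the input
    matrix; MDS is checked by reproducing planted 2-D distances.
    """
    rng = np.random.default_rng(seed)
    nj_exact = 0
    worst_nj = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(4, 13))
        labels = [f"L{i}" for i in range(n)]
        g = graphs.AdmixtureGraph(
            leaves=labels, drift_edges=graphs._tree_edges(labels, rng))
        g = g.with_params(rng.uniform(0.5, 2.0, len(g.drift_edges)),
                          np.array([]))
        d = graphs.expected_f2_matrix(g)
        nwk = structure.neighbor_joining(
            structure.DistanceMatrix(labels=labels, values=d))
        dists = _newick_leaf_distances(nwk)
        dev = max(
            abs(dists[tuple(sorted((labels[i], labels[j])))] - d[i, j])
            for i in range(n) for j in range(i + 1, n)
        )
        worst_nj = max(worst_nj, dev)
        nj_exact += dev < 1e-9

    mds_worst = 0.0
    for _ in range(20):
        pts = rng.normal(size=(int(rng.integers(4, 10)), 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = structure.classical_mds(
            structure.DistanceMatrix(
                labels=[str(i) for i in range(len(pts))], values=d), k=2)
        c = res["coordinates"]
        d2 = np.sqrt(((c[:, None] - c[None, :]) ** 2).sum(-1))
        mds_worst = max(mds_worst, float(np.abs(d - d2).max()))
    return {
        "n_matrices": n_matrices,
        "nj_exact_recovery_rate": nj_exact / n_matrices,
        "nj_worst_deviation": worst_nj,
        "mds_worst_deviation": mds_worst,
    }
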