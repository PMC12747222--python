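import numpy as np
import pytest

from paleopop import fstats, graphs, simulate


def two_leaf_graph(a, b):
    g = graphs.AdmixtureGraph(leaves=["A", "B"],
                              drift_edges=[("A", "R"), ("B", "R")])
    return g.with_params(np.array([a, b]), np.array([]))


class TestExpectedF2:
    def test_two_leaves_sum_of_lengths(self):
        g = two_leaf_graph(0.03, 0.07)
        assert graphs.expected_f2(g, "A", "B") == pytest.approx(0.10)

    def test_zero_length_tree_is_zero(self):
        g = two_leaf_graph(0.0, 0.0)
        assert graphs.expected_f2(g, "A", "B") == 0.0

    def test_admixed_leaf_closed_form(self):
        # M = gamma A' + (1-gamma) B'; drift a on A-edge, b on B-edge.
        # w_M = (gamma, 1-gamma) on the two edges, so
        # f2(M, A) = (1-gamma)^2 (a + b), f2(M, B) = gamma^2 (a + b)
        g = graphs.AdmixtureGraph(
            leaves=["A", "B", "M"],
            drift_edges=[("A", "R"), ("B", "R"), ("M", "ADM")],
            admix_nodes={"ADM": ("A", "B")},
        ).with_params(np.array([0.04, 0.06, 0.0]), np.array([0.5]))
        total = 0.10
        assert graphs.expected_f2(g, "M", "A") == pytest.approx(0.25 * total)
        assert graphs.expected_f2(g, "M", "B") == pytest.approx(0.25 * total)

    def test_path_algebra_matches_simulated_drift(self, tree_counts,
                                                  tree_f2_blocks):
        # fitted-free check: observed f2(A,B) ~ sum of the generating drift
        # variances scaled by the ancestral heterozygosity
        counts, model = tree_counts
        grid = np.linspace(0.05, 0.95, 4001)
        het = np.mean(grid * (1 - grid))
        obs = fstats.f2(counts, "A", "B").estimate
        # A and B each sit one leaf-edge below the shared AB node
        expected = (0.03 + 0.04) * het
        assert obs == pytest.approx(expected, rel=0.1)


class TestFitGraph:
    def test_exact_input_scores_zero(self):
        true = graphs.AdmixtureGraph(
            leaves=["A", "B", "C", "D"],
            drift_edges=[("A", "AB"), ("B", "AB"), ("C", "CD"), ("D", "CD"),
                         ("AB", "R"), ("CD", "R")],
        ).with_params(np.array([0.01, 0.02, 0.03, 0.01, 0.005, 0.005]),
                      np.array([]))
        exp = graphs.expected_f2_matrix(true)
        nb = 20
        tab = fstats.F2BlockTable(
            pops=list(true.leaves),
            values=np.repeat(exp[None, :, :], nb, axis=0),
            weights=np.full(nb, 100.0), n_snps=2000,
        )
        # exact, noise-free f2 basis: variances vanish, so weight by 1
        obs, _ = graphs._observed_f2_stats(tab, true.leaves)
        assert np.allclose(obs, exp, atol=1e-12)
        fit = graphs.fit_graph(true, tab, n_starts=4, seed=0)
        assert fit.score < 1e-6

    def test_generating_topology_ties_for_best_score(self, tree_f2_blocks):
        trees = graphs.enumerate_trees(["A", "B", "C", "D"])
        true = graphs.AdmixtureGraph(
            leaves=["A", "B", "C", "D"],
            drift_edges=[("A", "AB"), ("B", "AB"), ("C", "CD"), ("D", "CD"),
                         ("AB", "R"), ("CD", "R")],
        )
        scores = {t.topology_hash(): graphs.fit_graph(t, tree_f2_blocks,
                                                      seed=1).score
                  for t in trees}
        best = min(scores.values())
        assert scores[true.topology_hash()] <= best + 1e-6

    def test_recovered_lengths_close_to_truth(self, tree_counts,
                                              tree_f2_blocks):
        counts, model = tree_counts
        true = graphs.AdmixtureGraph(
            leaves=["A", "B", "C", "D"],
            drift_edges=[("A", "AB"), ("B", "AB"), ("C", "CD"), ("D", "CD"),
                         ("AB", "R"), ("CD", "R")],
        )
        fit = graphs.fit_graph(true, tree_f2_blocks, n_starts=4, seed=3)
        grid = np.linspace(0.05, 0.95, 4001)
        het = np.mean(grid * (1 - grid))
        by_edge = dict(zip(true.drift_edges, fit.graph.lengths))
        for leaf, truth in (("A", 0.03), ("B", 0.04), ("C", 0.05), ("D", 0.02)):
            parent = "AB" if leaf in "AB" else "CD"
            assert by_edge[(leaf, parent)] == pytest.approx(truth * het,
                                                            rel=0.15)


class TestHashes:
    def test_relabeling_invariance(self):
        g1 = graphs.AdmixtureGraph(
            leaves=["A", "B", "C"],
            drift_edges=[("A", "X"), ("B", "X"), ("X", "R"), ("C", "R")])
        g2 = graphs.AdmixtureGraph(
            leaves=["A", "B", "C"],
            drift_edges=[("C", "Q"), ("A", "Z"), ("B", "Z"), ("Z", "Q")])
        assert g1.topology_hash() == g2.topology_hash()

    @pytest.mark.parametrize("n,count", [(3, 3), (4, 15), (5, 105)])
    def test_exhaustive_distinctness(self, n, count):
        trees = graphs.enumerate_trees([f"P{i}" for i in range(n)])
        assert len(trees) == count
        assert len({t.topology_hash() for t in trees}) == count

    def test_admixture_orientation_flip_invariance(self):
        rng = np.random.default_rng(0)
        g = graphs.random_graph(["A", "B", "C", "D"], 1, rng)
        anode = next(iter(g.admix_nodes))
        pa, pb = g.admix_nodes[anode]
        flipped = graphs.AdmixtureGraph(
            leaves=g.leaves, drift_edges=list(g.drift_edges),
            admix_nodes={**g.admix_nodes, anode: (pb, pa)},
        )
        assert g.topology_hash() == flipped.topology_hash()

    def test_random_admixture_graphs_have_valid_structure(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = graphs.random_graph(["A", "B", "C", "D", "E"], 1, rng)
            assert g.n_admix() == 1
            for anode, (pa, pb) in g.admix_nodes.items():
                assert pa != pb


class TestSearch:
    def test_three_populations_exhaustive_matches_search(self):
        model = simulate.DemographyModel(
            populations=["A", "B", "C"],
            edges=[("AB", "ROOT", 0.03), ("C", "ROOT", 0.04),
                   ("A", "AB", 0.02), ("B", "AB", 0.02)],
        )
        cfg = simulate.SimulationConfig(n_snps=50_000, samples_per_pop=10,
                                        n_blocks=40, seed=77)
        counts = simulate.simulate_counts(
            simulate.simulate_frequencies(model, cfg), cfg)
        tab = fstats.extract_f2(counts)
        trees = graphs.enumerate_trees(["A", "B", "C"])
        assert len(trees) == 3
        exhaustive = {t.topology_hash(): graphs.fit_graph(t, tab, seed=2).score
                      for t in trees}
        found = graphs.find_graphs(tab, ["A", "B", "C"], n_admix=0,
                                   iterations=6, seed=3)
        # three leaves: every rooted topology can fit the 3 pairwise f2
        # exactly, so all scores (exhaustive and searched) are ~0 and tied
        assert min(exhaustive.values()) == pytest.approx(found[0]["score"],
                                                         abs=1e-4)
        true = graphs.AdmixtureGraph(
            leaves=["A", "B", "C"],
            drift_edges=[("A", "AB"), ("B", "AB"), ("AB", "R"), ("C", "R")])
        assert exhaustive[true.topology_hash()] <= min(exhaustive.values()) + 1e-4

    def test_deduplication_by_hash(self, tree_f2_blocks):
        res = graphs.find_graphs(tree_f2_blocks, ["A", "B", "C", "D"],
                                 n_admix=0, iterations=6, seed=9)
        hashes = [r["hash"] for r in res]
        assert len(hashes) == len(set(hashes))


class TestCompareFits:
    def test_graph_against_itself_is_p_one(self, tree_f2_blocks):
        g = graphs.AdmixtureGraph(
            leaves=["A", "B", "C", "D"],
            drift_edges=[("A", "AB"), ("B", "AB"), ("C", "CD"), ("D", "CD"),
                         ("AB", "R"), ("CD", "R")])
        res = graphs.compare_fits(g, g, tree_f2_blocks, seed=4)
        assert res["p"] == 1.0

    def test_true_beats_misspecified_topology(self, tree_f2_blocks):
        true = graphs.AdmixtureGraph(
            leaves=["A", "B", "C", "D"],
            drift_edges=[("A", "AB"), ("B", "AB"), ("C", "CD"), ("D", "CD"),
                         ("AB", "R"), ("CD", "R")])
        wrong = graphs.AdmixtureGraph(
            leaves=["A", "B", "C", "D"],
            drift_edges=[("A", "AC"), ("C", "AC"), ("B", "BD"), ("D", "BD"),
                         ("AC", "R"), ("BD", "R")])
        res = graphs.compare_fits(true, wrong, tree_f2_blocks, seed=4)
        assert res["mean_diff"] < 0  # true topology scores lower out of sample
        assert res["p"] < 0.05

    def test_too_few_blocks_refused(self):
        tab = fstats.F2BlockTable(pops=["A", "B"],
                                  values=np.zeros((5, 2, 2)),
                                  weights=np.ones(5), n_snps=10)
        g = two_leaf_graph(0.1, 0.1)
        with pytest.raises(ValueError, match="at least 10 blocks"):
            graphs.compare_fits(g, g, tab, seed=0)
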