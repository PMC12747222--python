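import numpy as np
import pytest
import skbio

from paleopop import fstats, graphs, structure


def random_additive_matrix(rng, n):
    labels = [f"L{i}" for i in range(n)]
    g = graphs.AdmixtureGraph(leaves=labels,
                              drift_edges=graphs._tree_edges(labels, rng))
    g = g.with_params(rng.uniform(0.5, 2.0, len(g.drift_edges)), np.array([]))
    return labels, graphs.expected_f2_matrix(g)


class TestOutgroupF3Distance:
    def test_matches_inverse_f3(self, admixed_counts):
        labels = ["S1", "S2", "T"]
        dm = structure.outgroup_f3_distance(admixed_counts, labels, "OUT")
        for i in range(3):
            for j in range(i + 1, 3):
                f3 = fstats.f3(admixed_counts, "OUT", labels[i], labels[j],
                               outgroup_mode=True)
                assert dm.values[i, j] == pytest.approx(1 / f3.estimate)

    def test_duplicated_population_minimal_distance(self):
        from paleopop import simulate
        # D1/D2 are twins (no drift below their split); E is diverged
        model = simulate.DemographyModel(
            populations=["O", "D1", "D2", "E"],
            edges=[("O", "ROOT", 0.1), ("X", "ROOT", 0.02),
                   ("E", "X", 0.05), ("D", "X", 0.02),
                   ("D1", "D", 0.0), ("D2", "D", 0.0)],
        )
        cfg = simulate.SimulationConfig(n_snps=30_000, samples_per_pop=15,
                                        n_blocks=30, seed=19)
        counts = simulate.simulate_counts(
            simulate.simulate_frequencies(model, cfg), cfg)
        dm = structure.outgroup_f3_distance(counts, ["D1", "D2", "E"], "O")
        assert dm.values[0, 1] < dm.values[0, 2]
        assert dm.values[0, 1] < dm.values[1, 2]

    def test_nonpositive_f3_raises_with_pair_name(self):
        from paleopop.genotypes import AlleleCountTable, assign_blocks_equal
        # A and B sit on opposite sides of the "outgroup": f3 < 0
        x = np.array([[18.0] * 6, [2.0] * 6, [10.0] * 6])
        t = AlleleCountTable(groups=["A", "B", "O"], x=x,
                             n=np.full((3, 6), 20.0),
                             blocks=assign_blocks_equal(6, 2).block_of,
                             n_blocks=2)
        with pytest.raises(ValueError, match="unsuitable"):
            structure.outgroup_f3_distance(t, ["A", "B"], "O")


class TestMDS:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = structure.classical_mds(
            structure.DistanceMatrix(labels=list("abc"), values=d), k=2)
        ev = res["eigenvalues"]
        assert ev[0] == pytest.approx(ev[1], rel=1e-9)
        assert ev[0] > 0

    def test_euclidean_input_reproduced_to_machine_precision(self, rng):
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = structure.classical_mds(
            structure.DistanceMatrix(labels=[str(i) for i in range(8)],
                                     values=d), k=2)
        c = res["coordinates"]
        d2 = np.sqrt(((c[:, None] - c[None, :]) ** 2).sum(-1))
        assert np.abs(d - d2).max() < 1e-9

    def test_two_points_single_positive_axis(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        res = structure.classical_mds(
            structure.DistanceMatrix(labels=["a", "b"], values=d), k=2)
        assert res["truncated"]
        assert res["coordinates"].shape[1] == 1

    def test_sign_convention(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = structure.classical_mds(
            structure.DistanceMatrix(labels=[str(i) for i in range(6)],
                                     values=d), k=2)
        for a in range(res["coordinates"].shape[1]):
            col = res["coordinates"][:, a]
            assert col[np.argmax(np.abs(col))] > 0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
        nwk = structure.neighbor_joining(
            structure.DistanceMatrix(labels=["a", "b", "c"], values=d))
        t = skbio.TreeNode.read([nwk])
        assert t.find("a").distance(t.find("b")) == pytest.approx(5.0)
        assert t.find("a").distance(t.find("c")) == pytest.approx(9.0)
        assert t.find("b").distance(t.find("c")) == pytest.approx(10.0)

    def test_additive_five_taxon_exact_recovery(self, rng):
        labels, d = random_additive_matrix(rng, 5)
        nwk = structure.neighbor_joining(
            structure.DistanceMatrix(labels=labels, values=d))
        t = skbio.TreeNode.read([nwk])
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        assert t.compare_rfd(ref) == 0
        for i in range(5):
            for j in range(i + 1, 5):
                assert t.find(labels[i]).distance(t.find(labels[j])) == (
                    pytest.approx(d[i, j], abs=1e-9))

    def test_property_exact_on_random_additive_matrices(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 13))
            labels, d = random_additive_matrix(rng, n)
            nwk = structure.neighbor_joining(
                structure.DistanceMatrix(labels=labels, values=d))
            t = skbio.TreeNode.read([nwk])
            for i in range(n):
                for j in range(i + 1, n):
                    assert abs(
                        t.find(labels[i]).distance(t.find(labels[j])) - d[i, j]
                    ) < 1e-9

    def test_rooting_places_outgroup_at_root(self, rng):
        labels, d = random_additive_matrix(rng, 6)
        nwk = structure.neighbor_joining(
            structure.DistanceMatrix(labels=labels, values=d),
            root_at=labels[2])
        t = skbio.TreeNode.read([nwk])
        root_children = [c.name for c in t.children]
        assert labels[2] in root_children
        # patristic distances preserved by the rooting
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(
                    t.find(labels[i]).distance(t.find(labels[j])) - d[i, j]
                ) < 1e-9

    def test_duplicate_labels_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="duplicate"):
            structure.neighbor_joining(
                structure.DistanceMatrix(labels=["a", "a", "b"], values=d))

    def test_fewer_than_three_taxa_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="at least 3"):
            structure.neighbor_joining(
                structure.DistanceMatrix(labels=["a", "b"], values=d))


class TestFstHclust:
    def test_planted_two_block_structure(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.full((6, 6), 0.2)
        d[:3, :3] = 0.01
        d[3:, 3:] = 0.01
        np.fill_diagonal(d, 0.0)
        res = structure.fst_hclust(
            structure.DistanceMatrix(labels=labels, values=d))
        clusters = res["clusters"]
        assert len({clusters[l] for l in labels[:3]}) == 1
        assert len({clusters[l] for l in labels[3:]}) == 1
        assert clusters["a1"] != clusters["b1"]
        assert res["newick"].count("(") >= 2

    def test_single_pair_one_merge(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        res = structure.fst_hclust(
            structure.DistanceMatrix(labels=["x", "y"], values=d))
        assert len(res["linkage"]) == 1

    def test_nan_cells_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            structure.fst_hclust(
                structure.DistanceMatrix(labels=["a", "b", "c"], values=d))


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        structure.DistanceMatrix(labels=["a", "b"],
                                 values=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        structure.DistanceMatrix(labels=["a", "b"],
                                 values=np.array([[1.0, 1.0], [1.0, 0.0]]))
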