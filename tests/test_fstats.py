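import itertools

import numpy as np
import pytest

from paleopop import fstats, simulate
from paleopop.genotypes import AlleleCountTable, assign_blocks_equal


def hand_f2(xa, na, xb, nb):
    """Independent per-SNP arithmetic oracle for bias-corrected f2."""
    vals = []
    for i in range(len(xa)):
        pa, pb = xa[i] / na[i], xb[i] / nb[i]
        ha = pa * (1 - pa) * na[i] / (na[i] - 1)
        hb = pb * (1 - pb) * nb[i] / (nb[i] - 1)
        vals.append((pa - pb) ** 2 - ha / na[i] - hb / nb[i])
    return vals


class TestF2:
    def test_self_f2_is_exactly_zero(self, toy_counts):
        r = fstats.f2(toy_counts, "A", "A")
        assert r.estimate == 0.0 and r.se == 0.0

    def test_toy_counts_match_hand_formula(self, toy_counts):
        r = fstats.f2(toy_counts, "A", "B")
        vals = hand_f2(toy_counts.x[0], toy_counts.n[0],
                       toy_counts.x[1], toy_counts.n[1])
        # equal block sizes: jackknife estimate equals the plain mean
        assert r.estimate == pytest.approx(np.mean(vals), abs=1e-12)

    def test_null_f2_unbiased_between_samples_of_one_population(self):
        # two samples from the same population: corrected f2 centered on 0
        rng = np.random.default_rng(11)
        zs = []
        for rep in range(60):
            p = rng.uniform(0.05, 0.95, 4000)
            x = np.stack([rng.binomial(10, p), rng.binomial(10, p)]).astype(float)
            n = np.full((2, 4000), 10.0)
            t = AlleleCountTable(groups=["A", "B"], x=x, n=n,
                                 blocks=assign_blocks_equal(4000, 20).block_of,
                                 n_blocks=20)
            zs.append(fstats.f2(t, "A", "B").z)
        assert abs(np.mean(zs)) < 3 / np.sqrt(len(zs)) * 3


class TestF3:
    def test_f3_of_duplicate_pair_equals_f2(self, toy_counts):
        # identical corrections on both sides: outgroup-mode f3 (no h_A term)
        # against uncorrected f2
        a = fstats.f3(toy_counts, "A", "B", "B", outgroup_mode=True)
        b = fstats.f2(toy_counts, "A", "B", corrected=False)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)

    def test_f3_decomposes_into_f2s(self, toy_counts):
        f3 = fstats.f3(toy_counts, "A", "B", "C").estimate
        f2ab = fstats.f2(toy_counts, "A", "B").estimate
        f2ac = fstats.f2(toy_counts, "A", "C").estimate
        f2bc = fstats.f2(toy_counts, "B", "C").estimate
        assert f3 == pytest.approx((f2ab + f2ac - f2bc) / 2, abs=1e-12)

    def test_admixed_target_gives_negative_f3(self, admixed_counts):
        r = fstats.f3(admixed_counts, "T", "S1", "S2")
        assert r.estimate < 0 and r.z < -3


class TestF4:
    def test_duplicate_right_pair_is_zero(self, toy_counts):
        r = fstats.f4(toy_counts, "A", "B", "C", "C")
        assert r.estimate == pytest.approx(0.0, abs=1e-15)

    def test_antisymmetry(self, toy_counts):
        a = fstats.f4(toy_counts, "A", "B", "C", "D")
        b = fstats.f4(toy_counts, "A", "B", "D", "C")
        assert a.estimate == pytest.approx(-b.estimate, abs=1e-15)

    def test_toy_product_mean(self, toy_counts):
        # distinct populations: f4 equals the plain frequency product mean
        p = toy_counts.x / toy_counts.n
        prod = (p[0] - p[1]) * (p[2] - p[3])
        r = fstats.f4(toy_counts, "A", "B", "C", "D")
        assert r.estimate == pytest.approx(prod.mean(), abs=1e-12)

    def test_f4_many_matches_single_calls(self, toy_counts):
        quads = [("A", "B", "C", "D"), ("A", "C", "B", "E")]
        batch = fstats.f4_many(toy_counts, quads)
        for q, r in zip(quads, batch):
            single = fstats.f4(toy_counts, *q)
            assert r.estimate == pytest.approx(single.estimate, abs=1e-15)
            assert r.se == pytest.approx(single.se, abs=1e-15)


class TestHudsonFst:
    def test_same_population_samples_give_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 6000)
        x = np.stack([rng.binomial(20, p), rng.binomial(20, p)]).astype(float)
        t = AlleleCountTable(
            groups=["A", "B"], x=x, n=np.full((2, 6000), 20.0),
            blocks=assign_blocks_equal(6000, 20).block_of, n_blocks=20,
        )
        r = fstats.hudson_fst(t, "A", "B")
        assert abs(r.estimate) < 0.01 and abs(r.z) < 3

    def test_fixed_opposite_alleles_give_one(self):
        s = 6000
        x = np.zeros((2, s))
        x[0] = 20.0
        t = AlleleCountTable(groups=["A", "B"], x=x, n=np.full((2, s), 20.0),
                             blocks=assign_blocks_equal(s, 10).block_of,
                             n_blocks=10)
        r = fstats.hudson_fst(t, "A", "B")
        assert r.estimate == pytest.approx(1.0, abs=1e-9)

    def test_snp_floor_enforced(self, toy_counts):
        with pytest.raises(ValueError, match="below the 5000-SNP floor"):
            fstats.hudson_fst(toy_counts, "A", "B")

    def test_balding_nichols_moment_oracle(self):
        # two populations drifted F each from a uniform ancestral frequency:
        # E[fst] = 2F E[p(1-p)] / (2 E[p(1-p)]) = F (numerical moments below)
        f = 0.05
        cfg = simulate.SimulationConfig(n_snps=100_000, samples_per_pop=20,
                                        n_blocks=50, seed=9)
        freqs = simulate.simulate_frequencies(simulate.two_population_model(f), cfg)
        counts = simulate.simulate_counts(freqs, cfg)
        grid = np.linspace(0.05, 0.95, 4001)
        oracle = np.mean(2 * f * grid * (1 - grid)) / np.mean(2 * grid * (1 - grid))
        r = fstats.hudson_fst(counts, "P1", "P2")
        assert r.estimate == pytest.approx(oracle, rel=0.10)


class TestByCorrect:
    def test_single_test_unchanged(self):
        res = fstats.by_correct([2.0])
        assert res["p_adj"][0] == pytest.approx(
            min(1.0, res["p"][0]), abs=1e-12
        )

    def test_reference_step_up_values(self):
        from scipy import stats as sps
        z = [sps.norm.isf(p / 2) for p in (0.01, 0.02, 0.5)]
        res = fstats.by_correct(z)
        assert np.round(res["p_adj"], 3).tolist() == [0.055, 0.055, 0.917]

    def test_z_by_matches_adjusted_p(self):
        from scipy import stats as sps
        res = fstats.by_correct([3.0, -2.5, 0.3, 1.1])
        back = 2 * sps.norm.sf(np.abs(res["z_by"]))
        assert np.allclose(back, np.minimum(res["p_adj"], 1.0), atol=1e-10)
        # a fully adjusted-away p (p_adj = 1) maps to z_by = 0
        assert np.sign(res["z_by"]).tolist() == [1, -1, 0, 1]

    def test_empty_input(self):
        res = fstats.by_correct([])
        assert len(res["p"]) == 0


class TestIdentities:
    """Exact linear identities of the f-statistic algebra."""

    def test_f4_additivity_and_permutation(self, toy_counts):
        f4 = lambda *q: fstats.f4(toy_counts, *q).estimate
        assert f4("A", "B", "C", "D") + f4("A", "B", "D", "E") == pytest.approx(
            f4("A", "B", "C", "E"), abs=1e-12
        )
        assert f4("A", "B", "C", "D") == pytest.approx(
            f4("C", "D", "A", "B"), abs=1e-12
        )

    def test_f4_from_f2_decomposition(self, toy_counts):
        f2 = lambda a, b: fstats.f2(toy_counts, a, b).estimate
        f4 = fstats.f4(toy_counts, "A", "B", "C", "D").estimate
        assert f4 == pytest.approx(
            0.5 * (f2("A", "D") + f2("B", "C") - f2("A", "C") - f2("B", "D")),
            abs=1e-12,
        )


class TestExtractF2:
    def test_blocks_average_to_estimate(self, toy_counts):
        tab = fstats.extract_f2(toy_counts)
        mean = tab.f2_mean()
        for a, b in itertools.combinations(range(len(tab.pops)), 2):
            direct = fstats.f2(toy_counts, tab.pops[a], tab.pops[b])
            w = tab.weights / tab.weights.sum()
            assert float(np.sum(w * tab.values[:, a, b])) == pytest.approx(
                np.sum(direct.block_values * direct.block_weights)
                / direct.block_weights.sum(),
                abs=1e-12,
            )
            assert mean[a, b] == mean[b, a]

    def test_f4_blocks_match_direct_f4(self, toy_counts):
        tab = fstats.extract_f2(toy_counts)
        bv = tab.f4_blocks("A", "B", "C", "D")
        direct = fstats.f4(toy_counts, "A", "B", "C", "D")
        assert np.allclose(bv, direct.block_values, atol=1e-12)
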