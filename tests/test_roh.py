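import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from paleopop import roh, simulate


def make_rohset(rows, meta_rows):
    segments = pd.DataFrame(
        rows, columns=["individual", "chrom", "start_cM", "end_cM", "length_cM"]
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=["individual", "group", "mean_date_bp", "covered_snps", "weight"],
    )
    return roh.ROHSet(segments=segments, meta=meta)


class TestEligibility:
    def test_snp_floor_is_strict_at_400k(self):
        rs = make_rohset(
            [], [("a", "g", 1000, 399_999, 1.0), ("b", "g", 1000, 400_000, 1.0)]
        )
        out = roh.eligibility_filter(rs)
        assert out.meta["individual"].tolist() == ["b"]

    def test_sum_gt20_boundary_is_strict(self):
        rows = [("a", 1, 0.0, 50.0, 50.0), ("b", 1, 0.0, 49.0, 49.0)]
        rs = make_rohset(rows, [("a", "g", 1000, 500_000, 1.0),
                                ("b", "g", 1000, 500_000, 1.0)])
        out = roh.eligibility_filter(rs)
        assert out.meta["individual"].tolist() == ["b"]

    def test_toy_cohort_hand_checked(self):
        meta = [
            ("a", "g", 1000, 500_000, 1.0),   # keep
            ("b", "g", 3500, 500_000, 1.0),   # too old
            ("c", "g", 1000, 100_000, 1.0),   # too few SNPs
            ("d", "g", 2999, 400_000, 1.0),   # keep
            ("e", "g", 1000, 500_000, 1.0),   # inbred (sum > 20cM = 60)
        ]
        rows = [("e", 1, 0.0, 30.0, 30.0), ("e", 2, 0.0, 30.0, 30.0)]
        out = roh.eligibility_filter(make_rohset(rows, meta))
        assert out.meta["individual"].tolist() == ["a", "d"]


class TestNeMLE:
    def test_recovery_at_moderate_ne(self):
        points, covered = [], 0
        for rep in range(8):
            rs = simulate.simulate_roh(500, roh.DEFAULT_CHROMOSOME_MORGANS,
                                       40, seed=110 + rep)
            est = roh.ne_mle(rs)
            points.append(est.point)
            covered += est.ci_low <= 500 <= est.ci_high
        assert np.mean(points) == pytest.approx(500, rel=0.15)
        assert covered >= 6

    def test_no_segments_flags_unbounded(self):
        rs = make_rohset([], [("a", "g", 1000, 500_000, 1.0)])
        est = roh.ne_mle(rs)
        assert est.unbounded and est.ci_high == np.inf

    def test_more_individuals_tighten_the_ci(self):
        widths = []
        for n in (20, 80):
            rs = simulate.simulate_roh(500, roh.DEFAULT_CHROMOSOME_MORGANS, n,
                                       seed=13)
            est = roh.ne_mle(rs)
            widths.append(np.log(est.ci_high) - np.log(est.ci_low))
        # quadrupling individuals roughly halves the log-CI width
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.35)

    def test_fractional_weights_scale_information(self):
        rs = simulate.simulate_roh(500, roh.DEFAULT_CHROMOSOME_MORGANS, 30,
                                   seed=17)
        est_full = roh.ne_mle(rs)
        rs.meta["weight"] = 0.5
        est_half = roh.ne_mle(rs)
        assert est_half.n_individuals == pytest.approx(15.0)
        w_full = np.log(est_full.ci_high) - np.log(est_full.ci_low)
        w_half = np.log(est_half.ci_high) - np.log(est_half.ci_low)
        assert w_half > w_full


class TestGroupTests:
    def sample_sets(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, meta = [], []
        for gi, grp in enumerate(("g1", "g2", "g3")):
            for i in range(8):
                ind = f"{grp}_{i}"
                total = rng.gamma(2.0, 15.0) + (shift if grp == "g3" else 0.0)
                rows.append((ind, 1, 0.0, 20.0 + total, 20.0 + total))
                meta.append((ind, grp, 1000, 500_000, 1.0))
        return make_rohset(rows, meta)

    def test_h_matches_scipy_kruskal(self):
        rs = self.sample_sets(seed=1)
        res = roh.roh_group_tests(rs)
        samples = [
            rs.sum_over(20.0)[(rs.meta["group"] == g).to_numpy()].to_numpy()
            for g in ("g1", "g2", "g3")
        ]
        kw = sps.kruskal(*samples)
        assert res["h"] == pytest.approx(kw.statistic)
        assert res["p"] == pytest.approx(kw.pvalue)

    def test_conover_against_independent_implementation(self):
        rs = self.sample_sets(seed=2)
        res = roh.roh_group_tests(rs)
        # independent computation using pandas ranking
        values = rs.sum_over(20.0).to_numpy()
        grp = rs.meta["group"].to_numpy()
        df = pd.DataFrame({"v": values, "g": grp})
        df["r"] = df["v"].rank()
        n, k = len(df), 3
        h = sps.kruskal(*[df.loc[df.g == g, "v"] for g in ("g1", "g2", "g3")]
                        ).statistic
        s2 = (np.sum(df.r**2) - n * (n + 1) ** 2 / 4) / (n - 1)
        rbar = df.groupby("g")["r"].mean()
        sizes = df.groupby("g").size()
        t12 = (rbar["g1"] - rbar["g2"]) / np.sqrt(
            s2 * (n - 1 - h) / (n - k) * (1 / sizes["g1"] + 1 / sizes["g2"]))
        row = res["pairwise"]
        got = row[(row.group_a == "g1") & (row.group_b == "g2")]["t"].iloc[0]
        assert got == pytest.approx(t12, abs=1e-10)

    def test_shifted_group_detected(self):
        rs = self.sample_sets(shift=60.0, seed=3)
        res = roh.roh_group_tests(rs)
        assert res["p"] < 0.01
        sig = res["pairwise"][res["pairwise"]["significant"]]
        assert set(sig["group_b"]) == {"g3"} or set(sig["group_a"]) == {"g3"}

    def test_all_tied_data_h_zero_p_one(self):
        rows = [(f"i{j}", 1, 0.0, 25.0, 25.0) for j in range(8)]
        meta = [(f"i{j}", f"g{j % 2}", 1000, 500_000, 1.0) for j in range(8)]
        res = roh.roh_group_tests(make_rohset(rows, meta))
        assert res["h"] == 0.0 and res["p"] == 1.0

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = [rng.gamma(2, 10, 8) for _ in range(3)]
        h1 = sps.kruskal(*groups).statistic
        h2 = sps.kruskal(*[np.log1p(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)
        t1, _ = roh.conover_test(groups)
        t2, _ = roh.conover_test([np.log1p(g) for g in groups])
        assert np.allclose(t1, t2)


class TestTimeRegression:
    def meta_with_dates(self, dates, sums):
        rows = [(f"i{j}", 1, 0.0, 4.0 + s, 4.0 + s) for j, s in enumerate(sums)]
        meta = [(f"i{j}", "g", d, 500_000, 1.0) for j, d in enumerate(dates)]
        return make_rohset(rows, meta)

    def test_exact_line_recovered(self):
        # one segment per individual inside the 4-12 cM window, exactly linear
        dates = np.array([500.0, 1000.0, 1500.0, 2000.0])
        rs = self.meta_with_dates(dates, 0.002 * dates)
        res = roh.roh_time_regression(rs)
        assert res["slope"] == pytest.approx(0.002, abs=1e-12)
        assert res["p"] < 1e-8

    def test_constant_response_degenerate(self):
        rs = self.meta_with_dates([500, 1000, 1500], [3.0, 3.0, 3.0])
        res = roh.roh_time_regression(rs)
        assert res["degenerate"] and res["slope"] == 0.0 and res["p"] == 1.0

    def test_date_window_enforced(self):
        rs = self.meta_with_dates([3000, 3200, 3400], [1, 2, 3])
        with pytest.raises(ValueError, match="date window"):
            roh.roh_time_regression(rs, max_date_bp=2500)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(100):
            dates = rng.uniform(200, 2400, 12)
            rs = self.meta_with_dates(dates, rng.gamma(2, 3, 12))
            ps.append(roh.roh_time_regression(rs)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_segments_below_call_floor_rejected():
    with pytest.raises(ValueError, match="calling floor"):
        make_rohset([("a", 1, 0.0, 2.0, 2.0)],
                    [("a", "g", 1000, 500_000, 1.0)])
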