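import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hrvkit.study_stats import (
    TABLE_TEST_OVERRIDES,
    build_study_table,
    describe,
    levene_test,
    mann_whitney_u,
    paired_t,
    route_test,
    simes_adjust,
    study_table_frame,
    wilcoxon_signed_rank,
)


def signflip_p(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist)
    extreme = np.abs(dist - mu) >= abs(v_obs - mu) - 1e-9
    return extreme.mean()


class TestWilcoxonFixtureValues:
    def test_hr_statistic(self, hrv_table):
        off, on = hrv_table.paired("hr")
        assert wilcoxon_signed_rank(off, on, "hr").statistic == 222.0

    def test_mean_ibi_statistic(self, hrv_table):
        off, on = hrv_table.paired("mean_ibi")
        assert wilcoxon_signed_rank(off, on, "mean_ibi").statistic == 32.0

    def test_rlfhf_statistic(self, hrv_table):
        off, on = hrv_table.paired("rlfhf")
        assert wilcoxon_signed_rank(off, on, "rlfhf").statistic == 190.0

    def test_back_vas_statistic(self, patient_table):
        off, on = patient_table.paired("vas_back")
        r = wilcoxon_signed_rank(off, on, "vas_back")
        assert r.statistic == 203.0
        assert r.p_value < 0.001

    def test_leg_vas_statistic(self, patient_table):
        off, on = patient_table.paired("vas_leg")
        r = wilcoxon_signed_rank(off, on, "vas_leg")
        assert r.statistic == 190.0
        assert r.n_eff == 21  # one subject reports identical leg pain

    def test_hr_direction_and_significance(self, hrv_table):
        off, on = hrv_table.paired("hr")
        r = wilcoxon_signed_rank(off, on, "hr")
        assert r.direction > 0  # heart rate falls with stimulation on
        assert r.p_value < 0.01


class TestWilcoxonProperties:
    def test_exact_p_matches_signflip_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 11))
            d = rng.normal(0.3, 1.0, n)
            x = rng.uniform(10, 20, n)
            r = wilcoxon_signed_rank(x, x - d)
            assert r.p_value == pytest.approx(signflip_p(d), abs=1e-12)

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 15)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        n = 15
        assert a.statistic + b.statistic == n * (n + 1) / 2
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank(x, x)

    def test_minimum_pairs(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank([1.0, 2, 3, 4], [0.5, 1, 2, 3])


class TestPairedT:
    def test_nlf_fixture_value(self, hrv_table):
        off, on = hrv_table.paired("nlf")
        r = paired_t(off, on, "nlf")
        assert r.statistic == pytest.approx(3.04, abs=0.005)
        assert r.df == 21
        assert r.p_value < 0.01

    def test_nhf_mirrors_nlf(self, hrv_table):
        off, on = hrv_table.paired("nhf")
        r = paired_t(off, on, "nhf")
        assert r.statistic == pytest.approx(-3.04, abs=0.005)

    def test_power_matches_noncentral_t(self, rng):
        # empirical rejection rate vs the noncentral-t prediction
        n, delta, sd, alpha, reps = 20, 0.5, 1.0, 0.05, 4000
        d = rng.normal(delta, sd, (reps, n))
        t = d.mean(1) / (d.std(1, ddof=1) / math.sqrt(n))
        crit = stats.t.ppf(1 - alpha / 2, n - 1)
        power_emp = np.mean(np.abs(t) > crit)
        nc = delta / (sd / math.sqrt(n))
        power_true = 1 - stats.nct.cdf(crit, n - 1, nc) + stats.nct.cdf(-crit, n - 1, nc)
        assert power_emp == pytest.approx(power_true, abs=0.03)

    def test_zero_variance_rejected(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(x, x + 1.0)


class TestRouting:
    def test_normal_differences_route_to_t(self, rng):
        hits = 0
        for _ in range(20):
            x = rng.normal(10, 1, 22)
            y = x - rng.normal(0.3, 0.5, 22)
            hits += route_test(x, y).method == "paired_t"
        assert hits >= 17  # Shapiro rejects ~5% of truly normal samples

    def test_heavy_tailed_differences_route_to_wilcoxon(self, rng):
        hits = 0
        for _ in range(20):
            x = rng.normal(10, 1, 22)
            y = x - rng.standard_cauchy(22)
            hits += route_test(x, y).method == "wilcoxon_signed_rank"
        assert hits >= 15

    def test_overrides_bypass_shapiro(self, rng):
        x = rng.normal(10, 1, 22)
        y = x - rng.normal(0.3, 0.5, 22)  # normal: would route to t
        r = route_test(x, y, "v", overrides={"v": "wilcoxon_signed_rank"})
        assert r.method == "wilcoxon_signed_rank"

    def test_unknown_override(self, rng):
        x = rng.normal(0, 1, 10)
        with pytest.raises(ValueError, match="unknown test"):
            route_test(x, x + 1, "v", overrides={"v": "anova"})


class TestDescribe:
    def test_printed_descriptives_reproduce(self, hrv_table):
        # published summary values, at half-unit-in-last-place tolerance
        hr_off, hr_on = (describe(v) for v in hrv_table.paired("hr"))
        assert hr_off.median == pytest.approx(65.9, abs=0.005)
        assert hr_off.q1 == pytest.approx(60.33, abs=0.0051)
        assert hr_off.q3 == pytest.approx(70.88, abs=0.005)
        assert hr_on.median == pytest.approx(61.55, abs=0.005)
        ibi_off, ibi_on = (describe(v) for v in hrv_table.paired("mean_ibi"))
        assert ibi_off.median == pytest.approx(913.8, abs=0.05)
        assert ibi_on.median == pytest.approx(976, abs=0.5)
        nlf_off = describe(hrv_table.paired("nlf")[0])
        assert nlf_off.mean == pytest.approx(0.61, abs=0.005)

    def test_quantile_oracle(self, rng):
        # h = (n - 1) p linear interpolation of order statistics
        v = rng.uniform(0, 100, 37)
        s = np.sort(v)
        for p, attr in ((0.25, "q1"), (0.5, "median"), (0.75, "q3")):
            h = (v.size - 1) * p
            lo = int(math.floor(h))
            expected = s[lo] + (h - lo) * (s[min(lo + 1, v.size - 1)] - s[lo])
            assert getattr(describe(v), attr) == pytest.approx(expected, abs=1e-12)

    def test_nan_dropped(self):
        d = describe([1.0, 2.0, np.nan, 3.0])
        assert d.mean == 2.0

    def test_formatted_styles(self):
        d = describe([1.0, 2.0, 3.0], presentation="mean_sd")
        assert "±" in d.formatted()
        d2 = describe([1.0, 2.0, 3.0])
        assert "(" in d2.formatted()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            describe([np.nan])


class TestMannWhitney:
    def test_complete_separation(self):
        vals = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        grp = np.array(["a"] * 4 + ["b"] * 4)
        w, p = mann_whitney_u(vals, grp)
        assert w == 0.0  # first group entirely below the second
        assert p == pytest.approx(2 / math.comb(8, 4), abs=1e-12)

    def test_exact_p_matches_permutation_oracle(self, rng):
        vals = rng.normal(0, 1, 8)
        grp = np.array(["a"] * 4 + ["b"] * 4)
        w_obs, p = mann_whitney_u(vals, grp)
        # enumerate all assignments of 4 of 8 values to group a
        ranks = stats.rankdata(vals)
        stats_all = []
        for idx in itertools.combinations(range(8), 4):
            r1 = ranks[list(idx)].sum()
            stats_all.append(r1 - 4 * 5 / 2)  # U of the chosen group
        stats_all = np.asarray(stats_all)
        mu = 4 * 4 / 2
        extreme = np.abs(stats_all - mu) >= abs(w_obs - mu) - 1e-9
        assert p == pytest.approx(extreme.mean(), abs=1e-12)

    def test_group_validation(self):
        with pytest.raises(ValueError, match="2 groups"):
            mann_whitney_u([1.0, 2.0, 3.0], ["a", "b", "c"])


class TestLevene:
    def test_type_i_error_calibrated(self, rng):
        rejects = 0
        reps = 400
        for _ in range(reps):
            _, p = levene_test(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
            rejects += p < 0.05
        assert rejects / reps == pytest.approx(0.05, abs=0.03)

    def test_detects_variance_ratio(self, rng):
        rejects = 0
        for _ in range(100):
            _, p = levene_test(rng.normal(0, 1, 30), rng.normal(0, 3, 30))
            rejects += p < 0.05
        assert rejects >= 80

    def test_degenerate_groups(self):
        with pytest.raises(ValueError):
            levene_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestSimes:
    def test_step_up_example(self):
        # p_(2) = 0.02 <= 2*0.05/4: ranks 1-2 rejected even though
        # p_(1) alone also passes; p_(3), p_(4) fail their thresholds
        p = [0.01, 0.02, 0.2, 0.9]
        assert simes_adjust(p, 0.05).tolist() == [True, True, False, False]

    def test_all_significant_via_largest(self):
        # the largest p passes its own threshold: everything rejected
        p = [0.04, 0.045, 0.049]
        assert simes_adjust(p, 0.05).all()

    def test_none_significant(self):
        assert not simes_adjust([0.3, 0.5, 0.9], 0.05).any()

    def test_fwer_under_global_null(self, rng):
        # independent uniform p-values: familywise error ~ alpha
        errors = 0
        reps = 2000
        for _ in range(reps):
            errors += simes_adjust(rng.uniform(0, 1, 10), 0.05).any()
        assert errors / reps == pytest.approx(0.05, abs=0.02)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            simes_adjust([0.5, 1.2])


class TestStudyTable:
    def test_fixture_table_reproduces_statistics(self, hrv_table):
        rows = {r.variable: r for r in build_study_table(hrv_table)}
        assert rows["hr"].test.statistic == 222.0
        assert rows["mean_ibi"].test.statistic == 32.0
        assert rows["rlfhf"].test.statistic == 190.0
        assert rows["nlf"].test.method == "paired_t"
        assert rows["nlf"].test.statistic == pytest.approx(3.04, abs=0.005)
        assert rows["nlf"].off.presentation == "mean_sd"
        assert rows["hr"].off.presentation == "median_iqr"

    def test_pairwise_exclusion(self, hrv_table):
        df = hrv_table.data.copy()
        df.loc[df.index[0], "hr_on"] = np.nan
        rows = {r.variable: r for r in build_study_table(df.reset_index())}
        assert rows["hr"].test.n_eff == 21
        assert rows["mean_ibi"].test.n_eff == 22

    def test_frame_with_simes(self, hrv_table):
        frame = study_table_frame(build_study_table(hrv_table), simes_alpha=0.05)
        assert "simes_significant" in frame.columns
        sig = frame.set_index("variable")["simes_significant"]
        assert sig["hr"] and sig["mean_ibi"] and sig["nlf"]

    def test_overrides_constant(self):
        assert TABLE_TEST_OVERRIDES["nlf"] == "paired_t"
        assert TABLE_TEST_OVERRIDES["hr"] == "wilcoxon_signed_rank"
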