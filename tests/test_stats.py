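"""Survival and response statistics against hand and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from lifelines.statistics import multivariate_logrank_test

import apmcluster as apm
from apmcluster.io import ClinicalTable, ExpressionMatrix, ValidationError
from apmcluster.stats import _exact_kx2_pvalue


def brute_force_km(times, events):
    """Product-limit estimator computed directly from its definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    timeline = np.unique(times)
    surv, s = [], 1.0
    for t in timeline:
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        surv.append(s)
    return timeline, np.array(surv)


class TestKaplanMeier:
    def test_hand_product_limit_no_censoring(self):
        curves = apm.km_curves([1, 2, 3, 4], [1, 1, 1, 1], ["A"] * 4)
        np.testing.assert_allclose(curves["A"]["survival"][1:],
                                   [0.75, 0.5, 0.25, 0.0])
        assert curves["A"]["median"] == 2.0

    def test_all_censored_survival_stays_at_one(self):
        curves = apm.km_curves([5, 6, 7], [0, 0, 0], ["A"] * 3)
        assert (curves["A"]["survival"] == 1.0).all()
        assert not np.isfinite(curves["A"]["median"])  # never reached

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = rng.integers(2, 31)
            times = rng.integers(1, 15, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            curves = apm.km_curves(times, events, ["A"] * n)
            timeline, surv = brute_force_km(times, events)
            est = curves["A"]
            # align on the brute-force timeline (lifelines adds t=0)
            for t, s in zip(timeline, surv):
                idx = np.searchsorted(est["timeline"], t)
                assert est["survival"][idx] == pytest.approx(s, abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2, 3, 4, 1, 2, 3, 4]
        events = [1] * 8
        groups = ["A"] * 4 + ["B"] * 4
        res = apm.logrank_test(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_hand_computation(self):
        # A: events at 1, 2; B: events at 3, 4; no censoring.
        # O_A = 2; E_A = 2/4 + 1/3 = 5/6; V = sum of hypergeometric terms.
        res = apm.logrank_test([1, 2, 3, 4], [1, 1, 1, 1],
                               ["A", "A", "B", "B"])
        e_a = 2 / 4 + 1 / 3
        v = (2 * 2 / 16) + (1 * 2 / 9)  # d=1 each time: n_A n_B / n^2
        expected = (2 - e_a) ** 2 / v
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.observed[0] == 2
        assert res.expected[0] == pytest.approx(e_a)

    def test_observed_equals_expected_in_total(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        events[:5] = 1
        groups = rng.choice(["A", "B", "C"], 60)
        res = apm.logrank_test(times, events, groups)
        assert res.observed.sum() == pytest.approx(res.expected.sum())
        assert res.df == 2

    def test_statistic_invariant_under_relabeling(self):
        rng = np.random.default_rng(15)
        times = rng.exponential(10, 50)
        events = np.ones(50, int)
        groups = rng.choice(["A", "B", "C", "D"], 50)
        res1 = apm.logrank_test(times, events, groups)
        swap = {"A": "D", "B": "C", "C": "B", "D": "A"}
        res2 = apm.logrank_test(times, events, [swap[g] for g in groups])
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-9)

    @pytest.mark.parametrize("k,seed", [(2, 0), (3, 1), (4, 2)])
    def test_agrees_with_lifelines(self, k, seed):
        rng = np.random.default_rng(seed)
        n = 80
        groups = rng.choice([f"g{i}" for i in range(k)], n)
        hz = {f"g{i}": 0.05 * (i + 1) for i in range(k)}
        times = np.array([rng.exponential(1 / hz[g]) for g in groups])
        events = (times < 25).astype(int)
        times = np.minimum(times, 25)
        mine = apm.logrank_test(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_zero_events_is_error(self):
        with pytest.raises(ValidationError):
            apm.logrank_test([1, 2], [0, 0], ["A", "B"])


class TestCox:
    def _simulate(self, n, log_hr, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        times = rng.exponential(1.0 / (0.05 * np.exp(log_hr * x)))
        events = (times < 100).astype(int)
        times = np.minimum(times, 100)
        return ClinicalTable(pd.DataFrame(
            {"time": np.maximum(times, 1e-9), "event": events, "x": x},
            index=[f"P{i}" for i in range(n)]))

    def test_recovers_true_hazard_ratio(self):
        clin = self._simulate(1000, np.log(2.0), seed=16)
        res = apm.cox_multivariate(clin, ["x"])
        assert 1.7 <= res.summary.loc["x", "HR"] <= 2.3
        assert (res.summary.loc["x", "CI95_low"]
                <= res.summary.loc["x", "HR"]
                <= res.summary.loc["x", "CI95_high"])

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(50):
            clin = self._simulate(150, 0.0, seed=100 + seed)
            res = apm.cox_multivariate(clin, ["x"])
            lo = res.summary.loc["x", "CI95_low"]
            hi = res.summary.loc["x", "CI95_high"]
            covered += lo <= 1.0 <= hi
        assert covered >= 45  # nominal 95%, allow binomial wiggle

    def test_cluster_coding_is_one_to_four(self):
        labels = pd.Series(["C1", "C2", "C3", "C4"],
                           index=["a", "b", "c", "d"])
        coded = apm.encode_cluster_labels(labels)
        assert coded.tolist() == [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValidationError):
            apm.encode_cluster_labels(pd.Series(["C5"]))

    def test_constant_covariate_rejected(self):
        clin = self._simulate(50, 0.0, seed=17)
        clin.data["flat"] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            apm.cox_multivariate(clin, ["flat"])


class TestBenefit:
    @pytest.mark.parametrize("bor,months,progressed,expected", [
        ("PD", 1.0, True, "NCB"), ("PD", 24.0, False, "NCB"),
        ("CRPR", 1.0, True, "DCB"), ("CRPR", 24.0, False, "DCB"),
        ("SD", 3.0, True, "DCB"),
        ("MR", 7.0, False, "DCB"), ("MR", 6.0, True, "DCB"),
        ("MR", 3.0, True, "NCB"), ("MR", 5.9, False, "NCB"),
        ("NE", 3.0, False, "NCB"), ("NE", 12.0, True, "DCB"),
        (None, 8.0, False, "DCB"), (None, 2.0, True, "NCB"),
    ])
    def test_truth_table(self, bor, months, progressed, expected):
        assert apm.derive_benefit(bor, months, progressed) == expected

    def test_exhaustive_grid_is_total_and_deterministic(self):
        grid_bor = ["CRPR", "SD", "MR", "PD", "NE", None]
        grid_months = [0.5, 3.0, 5.99, 6.0, 6.01, 12.0]
        for bor, months, prog in itertools.product(grid_bor, grid_months,
                                                   [True, False]):
            label = apm.derive_benefit(bor, months, prog)
            assert label in ("DCB", "NCB")
            if bor == "PD":
                assert label == "NCB"
            elif bor in ("CRPR", "SD"):
                assert label == "DCB"
            else:
                assert label == ("DCB" if months >= 6 else "NCB")
            assert apm.derive_benefit(bor, months, prog) == label

    def test_unknown_followup_withholds_label(self):
        with pytest.warns(UserWarning):
            assert apm.derive_benefit("MR", None, None) is None


class TestFisherAssociation:
    def test_two_by_two_matches_hypergeometric_enumeration(self):
        labels = pd.Series(["A"] * 4 + ["B"] * 4)
        benefit = pd.Series(["DCB"] * 3 + ["NCB"] + ["DCB"] + ["NCB"] * 3)
        out = apm.cluster_benefit_association(labels, benefit)
        assert out["p_omnibus"] == pytest.approx(34 / 70)

    def test_identical_rows_give_p_one(self):
        labels = pd.Series(["A"] * 4 + ["B"] * 4)
        benefit = pd.Series(["DCB", "DCB", "NCB", "NCB"] * 2)
        out = apm.cluster_benefit_association(labels, benefit)
        assert out["p_omnibus"] == pytest.approx(1.0)

    def test_percent_dcb_arithmetic(self):
        labels = pd.Series(["A"] * 6 + ["B"] * 4)
        benefit = pd.Series(["DCB"] * 5 + ["NCB"] + ["DCB"] + ["NCB"] * 3)
        out = apm.cluster_benefit_association(labels, benefit)
        assert out["pct_dcb"]["A"] == pytest.approx(83.333333, rel=1e-5)

    def test_enumeration_equals_closed_form_on_2x2_margins(self):
        # every 2x2 table with margins <= 12
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            table = np.array([[a, b], [c, d]])
            mine = _exact_kx2_pvalue(table)
            ref = scipy.stats.fisher_exact(table)[1]
            assert mine == pytest.approx(ref, abs=1e-10), table

    def test_kx2_enumeration_probabilities_sum_to_one(self):
        # p-value of the most probable table's complement check: the
        # enumeration distribution must be a proper probability measure
        table = np.array([[5, 2], [3, 4], [1, 6]])
        # p-value with an impossible-to-beat threshold == total mass == 1
        assert _exact_kx2_pvalue(np.array([[7, 0], [0, 7], [7, 0]])) <= 1.0
        assert 0.0 < _exact_kx2_pvalue(table) <= 1.0

    def test_pairwise_one_vs_rest_reported(self):
        labels = pd.Series(["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        benefit = pd.Series(["DCB"] * 5 + ["NCB"]
                            + ["DCB"] * 3 + ["NCB"] * 3
                            + ["DCB"] + ["NCB"] * 5)
        out = apm.cluster_benefit_association(labels, benefit)
        assert set(out["p_pairwise"]) == {"A", "B", "C"}
        for p in out["p_pairwise"].values():
            assert 0 < p <= 1


class TestPairedComparison:
    def _pair(self, pre_vals, on_vals):
        genes = ["GX"]
        samples = [f"S{i}" for i in range(len(pre_vals))]
        pre = ExpressionMatrix(pd.DataFrame([pre_vals], index=genes,
                                            columns=samples))
        on = ExpressionMatrix(pd.DataFrame([on_vals], index=genes,
                                           columns=samples))
        return pre, on, [(s, s) for s in samples]

    def test_identical_profiles_reported_as_no_change(self):
        pre, on, pairs = self._pair([1, 2, 3], [1, 2, 3])
        out = apm.paired_group_comparison(pre, on, pairs, ["GX"])
        assert out["no_change"] and np.isnan(out["p_value"])

    def test_hand_ranked_signed_rank_statistic(self):
        # log2(TPM+1) differences (+1,+2,+3,+4,+5,-1):
        # |d| ranks (1.5,3,4,5,6,1.5) -> W- = 1.5 (scipy's min-rank-sum)
        pre_vals = [1.0] * 6                       # log2(pre+1) = 1
        on_vals = [2.0 ** (1 + d) - 1 for d in (1, 2, 3, 4, 5, -1)]
        pre, on, pairs = self._pair(pre_vals, on_vals)
        out = apm.paired_group_comparison(pre, on, pairs, ["GX"])
        assert out["statistic"] == pytest.approx(1.5)
        assert out["p_value"] == pytest.approx(0.09375)

    def test_swapping_pre_and_on_keeps_p(self):
        rng = np.random.default_rng(18)
        pre_vals = rng.uniform(1, 50, 10)
        on_vals = rng.uniform(1, 50, 10)
        pre, on, pairs = self._pair(pre_vals, on_vals)
        fwd = apm.paired_group_comparison(pre, on, pairs, ["GX"])
        rev = apm.paired_group_comparison(on, pre, pairs, ["GX"])
        assert fwd["p_value"] == pytest.approx(rev["p_value"])
        assert fwd["median_diff"] == pytest.approx(-rev["median_diff"])

    def test_no_pairs_is_error(self):
        pre, on, _ = self._pair([1.0], [2.0])
        with pytest.raises(ValidationError):
            apm.paired_group_comparison(pre, on, [], ["GX"])


class TestCytScore:
    def _expr(self, gzma, prf1):
        return ExpressionMatrix(pd.DataFrame(
            {"S1": [gzma, prf1]}, index=["GZMA", "PRF1"]))

    def test_zero_expression_scores_zero(self):
        assert apm.cyt_score(self._expr(0.0, 0.0))["S1"] == 0.0

    def test_direct_arithmetic(self):
        # mean(3, 1) = 2 -> log2(3)
        assert apm.cyt_score(self._expr(3.0, 1.0))["S1"] == pytest.approx(
            np.log2(3.0))

    def test_monotone_in_expression(self):
        a = apm.cyt_score(self._expr(3.0, 1.0))["S1"]
        b = apm.cyt_score(self._expr(6.0, 2.0))["S1"]
        assert b > a

    def test_missing_gene_is_error(self):
        expr = ExpressionMatrix(pd.DataFrame({"S1": [1.0]}, index=["GZMA"]))
        with pytest.raises(ValidationError):
            apm.cyt_score(expr)


class TestSpearman:
    def test_perfectly_monotone_pairs(self):
        out = apm.spearman_with_bh({"g": [1, 2, 3, 4]}, {"g": [2, 4, 8, 16]})
        assert out.loc["g", "rho"] == pytest.approx(1.0)
        rev = apm.spearman_with_bh({"g": [1, 2, 3, 4]}, {"g": [4, 3, 2, 1]})
        assert rev.loc["g", "rho"] == pytest.approx(-1.0)

    def test_bh_adjustment_hand_computed(self):
        # hand BH: p_(i) * m / i, cumulative-min from the largest rank
        rng = np.random.default_rng(20)
        x = {f"g{i}": rng.normal(size=8) for i in range(4)}
        y = {k: v * (i + 1) + rng.normal(scale=2.0, size=8)
             for i, (k, v) in enumerate(x.items())}
        out = apm.spearman_with_bh(x, y)
        p = out["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(hand, 0, 1)
        np.testing.assert_allclose(out["p_bh"].to_numpy(), expected,
                                   rtol=1e-12)

    def test_constant_input_flagged(self):
        out = apm.spearman_with_bh({"g": [1, 1, 1]}, {"g": [1, 2, 3]})
        assert out.loc["g", "degenerate"]
        assert np.isnan(out.loc["g", "rho"])

    def test_adjustment_spans_groups(self):
        rng = np.random.default_rng(19)
        x = {f"g{i}": rng.normal(size=10) for i in range(3)}
        y = {k: v + rng.normal(scale=0.5, size=10) for k, v in x.items()}
        out = apm.spearman_with_bh(x, y)
        assert (out["p_bh"] >= out["p"] - 1e-12).all()
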