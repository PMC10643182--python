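"""KM curves, log-rank, chi-square, rank tests and BH against oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metabosubtype as ms
from conftest import toy_clinical


def km_by_definition(time, event):
    """Direct product-limit recomputation from the definition."""
    s, out = 1.0, {}
    for t in sorted(np.unique(time[event == 1])):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_three_deaths_analytic(self):
        curve = ms.km_estimate(toy_clinical([1, 2, 3], [1, 1, 1]))
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(curve.event_times, [1, 2, 3])
        assert curve.median == 2  # first time S <= 0.5

    def test_all_censored_flat(self):
        curve = ms.km_estimate(toy_clinical([1, 2, 3], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert np.isinf(curve.median)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(12)
        time = np.ceil(rng.exponential(5, size=120) * 2) / 2  # forces ties
        event = rng.integers(0, 2, size=120)
        event[0] = 1
        curve = ms.km_estimate(toy_clinical(time, event))
        oracle = km_by_definition(time, event)
        assert len(curve.event_times) == len(oracle)
        for t, s in zip(curve.event_times, curve.survival):
            assert abs(s - oracle[t]) < 1e-12

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(13)
        time = rng.exponential(3, size=60)
        curve = ms.km_estimate(toy_clinical(time, np.ones(60, dtype=int)))
        for t, s in zip(curve.event_times, curve.survival):
            assert abs(s - (time > t).mean()) < 1e-12


class TestLogrank:
    def test_identical_groups_null(self):
        time = [1, 2, 3, 4, 5]
        clin = toy_clinical(time + time, [1] * 10)
        res = ms.logrank_test(clin, np.array(["a"] * 5 + ["b"] * 5))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_toy_term_by_term(self):
        # alternating groups, all events: accumulate O-E and hypergeometric
        # variance terms by hand
        time = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        event = np.ones(6, dtype=int)
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        o_minus_e, var = 0.0, 0.0
        for t in time:
            at_risk = time >= t
            n, n_a = at_risk.sum(), (at_risk & (groups == "a")).sum()
            d = 1
            o_a = 1.0 if groups[time == t][0] == "a" else 0.0
            e_a = d * n_a / n
            o_minus_e += o_a - e_a
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e**2 / var
        res = ms.logrank_test(toy_clinical(time, event), groups)
        assert res.statistic == pytest.approx(expected_stat, rel=1e-10)

    def test_group_relabeling_invariant(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(2, size=40)
        event = rng.integers(0, 2, size=40)
        event[:2] = 1
        groups = np.array(["x"] * 20 + ["y"] * 20)
        clin = toy_clinical(time, event)
        p1 = ms.logrank_test(clin, groups).p
        p2 = ms.logrank_test(clin, np.where(groups == "x", "y", "x")).p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_planted_hazard_ratio_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(800 + seed)
            g = np.array(["hi"] * 100 + ["lo"] * 100)
            scale = np.where(g == "hi", 1 / 3.0, 1.0)  # hazard ratio 3
            time = rng.exponential(scale)
            clin = toy_clinical(time, np.ones(200, dtype=int))
            if ms.logrank_test(clin, g).p < 0.001:
                hits += 1
        assert hits >= 9

    def test_needs_two_groups(self):
        clin = toy_clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            ms.logrank_test(clin, np.array(["a", "a", "a"]))


class TestChiSquare:
    @pytest.mark.parametrize("table,expected_p", [
        ([[61, 25], [29, 7]], 0.270),   # diabetes history by subtype
        ([[37, 60], [13, 23]], 0.830),  # alcohol history by subtype
    ])
    def test_reproduces_printed_cohort_pvalues(self, table, expected_p):
        res = ms.chisq_test(table)
        assert round(res.p, 3) == expected_p

    def test_homogeneous_table_null(self):
        res = ms.chisq_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize("bad", [[[1, -2], [3, 4]], [[0, 0], [1, 2]],
                                     [[1.5, 2], [3, 4]]])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            ms.chisq_test(bad)


class TestPercentagesAndCharacteristics:
    @pytest.mark.parametrize("a,n,expected", [
        (54, 219, 24.7), (2, 28, 7.1), (25, 86, 29.1), (38, 142, 26.8),
        (0, 50, 0.0), (0, 0, 0.0),
    ])
    def test_column_percentage_rounding(self, a, n, expected):
        assert ms.percentage(a, n) == expected

    def test_characteristics_table(self):
        rng = np.random.default_rng(17)
        n = 120
        clin = toy_clinical(rng.exponential(10, n) + 0.1,
                            rng.integers(0, 2, n),
                            sex=rng.choice(["F", "M"], n),
                            age=rng.normal(65, 9, n))
        labels = pd.Series(rng.choice(["M1", "M2"], n, p=[0.7, 0.3]),
                           index=clin.sample_ids)
        table = ms.cohort_characteristics(labels, clin)
        assert set(table["characteristic"]) == {"sex", "age"}
        sex_rows = table[table["characteristic"] == "sex"]
        assert (sex_rows["test"] == "chi-square").all()
        # chi-square p equals a direct recomputation from the crosstab
        ct = pd.crosstab(clin.covariates["sex"], labels)
        assert sex_rows["p_value"].iloc[0] == pytest.approx(
            ms.chisq_test(ct.to_numpy().T).p)
        age_rows = table[table["characteristic"] == "age"]
        assert (age_rows["test"] == "t-test").all()


class TestRankCompareAndBH:
    def test_identical_groups_p_one(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        out = ms.rank_compare_aac({"d1": vals}, {"d1": vals.copy()})
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_disjoint_groups_match_exhaustive_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        out = ms.rank_compare_aac({"d": a}, {"d": b})
        # exact null: enumerate all C(10,5) assignments of ranks to group A
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        u_obs = ranks[:5].sum() - 5 * 6 / 2
        u_all = [sum(c) - 15 for c in combinations(ranks, 5)]
        u_all = np.array(u_all)
        p_exact = (np.minimum((u_all <= u_obs).mean(),
                              (u_all >= u_obs).mean()) * 2)
        assert out["p"].iloc[0] == pytest.approx(p_exact, rel=1e-12)

    def test_bh_step_up_worked_example(self):
        adj = ms.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_bounds_and_oracle(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(size=25)
        adj = ms.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # direct step-up: adj[i] = min over j with p_(j) >= p_(i) of m p_(j)/j
        order = np.argsort(p)
        m = len(p)
        expected = np.empty(m)
        running = np.inf
        for rank in range(m - 1, -1, -1):
            running = min(running, m * p[order[rank]] / (rank + 1))
            expected[order[rank]] = min(running, 1.0)
        assert np.allclose(adj, expected)

    def test_single_p_unchanged(self):
        assert ms.bh_adjust([0.037])[0] == pytest.approx(0.037)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bh_properties_hold_for_any_input(self, p):
        adj = ms.bh_adjust(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        # step-up adjustment preserves the significance ordering
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
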