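import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ranksexplained as rx
from helpers import eq_weighted_re, eq_weighted_re_terms, km_censoring_at_minus
from conftest import random_survival_data


class TestRankComponents:
    def test_singleton_risk_set_contributes_nothing(self):
        rc = rx.rank_components([0.4], 0)
        assert (rc.r_null, rc.r_model, rc.r_perfect) == (1.0, 1.0, 1.0)

    def test_best_ranked_failure(self):
        rc = rx.rank_components([0.5, 0.1, 0.2, 0.3, 0.4], 0)
        assert rc.r_model == 1.0 and rc.r_null == 3.0

    def test_all_tied_hazards_give_mean_rank(self):
        rc = rx.rank_components([0.2] * 5, 2)
        assert rc.r_model == 3.0 == rc.r_null  # zero explained variation

    def test_empty_risk_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rx.rank_components([], 0)

    @given(st.lists(st.sampled_from([0.1, 0.25, 0.5, 0.7, 1.3]), min_size=1, max_size=50),
           st.integers(0, 49))
    def test_matches_descending_sort_with_midrank_ties(self, lams, i):
        if i >= len(lams):
            return
        lam = np.asarray(lams)
        rc = rx.rank_components(lam, i)
        order = np.argsort(-lam, kind="stable")
        pos = np.nonzero(order == i)[0][0] + 1  # 1-based position in descending sort
        ties = np.sum(lam == lam[i])
        first = 1 + np.sum(lam > lam[i])
        midrank = first + (ties - 1) / 2.0  # average position over the tie block
        assert rc.r_model == pytest.approx(midrank)
        assert first <= pos <= first + ties - 1


class TestReverseKM:
    def test_no_censoring_means_unit_weights(self):
        G = rx.reverse_km([1.0, 2.0, 3.0], [1, 1, 1])
        assert G.at_minus(2.5) == 1.0 and G.at_minus(100.0) == 1.0

    def test_hand_computed_three_record_example(self):
        G = rx.reverse_km([1.0, 2.0, 3.0], [1, 0, 1])
        assert G.at_minus(1.5) == 1.0
        assert G.at_minus(2.0) == 1.0  # left-continuous at the censoring time
        assert G.at_minus(3.0) == 0.5  # the death at 3 gets weight 2

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0.1, 5.0, 40)
        d = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        g1 = rx.reverse_km(t, d)
        g2 = rx.reverse_km(t[perm], d[perm])
        pts = np.linspace(0, 6, 30)
        np.testing.assert_allclose(g1.at_minus(pts), g2.at_minus(pts))

    def test_matches_lifelines_censoring_distribution(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        t = np.round(rng.uniform(0.1, 5.0, 120), 1)  # induce ties
        d = rng.integers(0, 2, 120)
        G = rx.reverse_km(t, d)
        kmf = KaplanMeierFitter().fit(t, event_observed=1 - d)
        for tt in np.unique(t):
            assert G.at(tt) == pytest.approx(
                float(kmf.survival_function_at_times(tt).iloc[0]), abs=1e-12)

    def test_matches_literal_product_oracle(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.uniform(0.1, 4.0, 60), 1)
        d = rng.integers(0, 2, 60)
        G = rx.reverse_km(t, d)
        for tt in rng.uniform(0, 5, 50):
            assert G.at_minus(tt) == pytest.approx(km_censoring_at_minus(t, d, tt), abs=1e-12)


class TestCancerWeight:
    def test_symmetry_equal_hazards(self):
        assert rx.cancer_weight(0.05, 0.05) == 0.5

    def test_cause_specific_limit(self):
        assert rx.cancer_weight(0.2, 0.0) == 1.0

    def test_arithmetic(self):
        assert rx.cancer_weight(0.09, 0.01) == pytest.approx(0.9)

    def test_double_zero_yields_zero(self):
        assert rx.cancer_weight(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rx.cancer_weight(-0.1, 0.2)


def simple_data(times, d, cause=None):
    df = pd.DataFrame({"time": times, "status": d})
    if cause is not None:
        df["cause"] = cause
    return rx.SurvivalDataset(df, cause_col="cause" if cause is not None else None)


class TestComputeRE:
    def test_perfect_model_scores_one_at_every_tau(self):
        # later failure <-> smaller hazard: each death tops its own risk set
        n = 12
        times = np.arange(1.0, n + 1)
        scores = -times  # strictly decreasing in failure time
        ds = simple_data(times, np.ones(n, dtype=int))
        for tau in (3.0, 7.0, 12.0):
            res = rx.compute_re(ds, scores - scores.min() + 1.0, "overall", tau=tau)
            assert res.overall == pytest.approx(1.0)
        assert np.allclose(res.grid_values[~np.isnan(res.grid_values)], 1.0)

    def test_reversed_perfect_model_scores_minus_one(self):
        n = 12
        times = np.arange(1.0, n + 1)
        ds = simple_data(times, np.ones(n, dtype=int))
        res = rx.compute_re(ds, times.copy(), "overall")  # worst subject ranked first
        assert res.overall == pytest.approx(-1.0)

    def test_constant_hazard_model_scores_zero(self):
        n = 15
        rng = np.random.default_rng(6)
        ds = simple_data(rng.uniform(0.5, 5, n), np.ones(n, dtype=int))
        res = rx.compute_re(ds, np.full(n, 0.7), "overall", jitter=False)
        assert res.overall == pytest.approx(0.0)

    def test_weighted_with_indicator_weights_equals_cause_specific(self):
        rng = np.random.default_rng(7)
        ds = random_survival_data(rng, 80)
        scores = rng.uniform(0.1, 2.0, 80)
        is_cancer = (ds.cause == "cancer").astype(float)
        # lam_E = score for cancer deaths, 0 otherwise; lam_P = 0 -> w = indicator
        hz = scores * is_cancer
        r_w = rx.compute_re(ds, hz, "weighted", expected=np.zeros(80), jitter=False)
        r_c = rx.compute_re(ds, hz, "cause_specific", jitter=False)
        assert r_w.overall == r_c.overall
        np.testing.assert_array_equal(r_w.grid_values, r_c.grid_values)
        assert r_w.sum_weights == r_c.sum_weights

    @pytest.mark.parametrize("mode", ["overall", "cause_specific", "weighted"])
    @pytest.mark.parametrize("cens", [0.0, 0.35])
    def test_matches_literal_double_loop(self, mode, cens):
        rng = np.random.default_rng(8)
        for _ in range(8):
            n = int(rng.integers(10, 100))
            ds = random_survival_data(rng, n, cens_frac=cens)
            M = rng.uniform(0.01, 1.0, (n, ds.n_deaths))
            lam_p = rng.uniform(0.0, 0.2, n)
            res = rx.compute_re(ds, M, mode, expected=lam_p, jitter=False)
            death_order = np.argsort(ds.time[ds.status == 1], kind="stable")
            rows = np.nonzero(ds.status == 1)[0][death_order]
            if mode == "overall":
                m = np.ones(rows.size)
            elif mode == "cause_specific":
                m = (ds.cause[rows] == "cancer").astype(float)
            else:
                lam_e = M[rows, np.arange(rows.size)]
                m = lam_e / (lam_e + lam_p[rows])
            oracle = eq_weighted_re(ds.time, ds.status, M, m, tau=res.tau)
            assert res.overall == pytest.approx(oracle, abs=1e-12)

    def test_sum_of_weights_band_warning(self):
        rng = np.random.default_rng(9)
        ds = random_survival_data(rng, 60, cens_frac=0.1)
        n = ds.n
        lam_p = np.full(n, 5.0)        # background dominates -> tiny weights
        hz = rng.uniform(0.01, 0.05, n)
        res = rx.compute_re(ds, hz, "weighted", expected=lam_p, jitter=False)
        assert any("30%" in w for w in res.warnings)

    def test_zero_denominator_flagged(self):
        ds = simple_data([1.0, 2.0, 3.0], [1, 1, 1], ["other", "other", "other"])
        with pytest.warns(UserWarning, match="undefined"):
            res = rx.compute_re(ds, np.array([3.0, 2.0, 1.0]), "cause_specific")
        assert np.isnan(res.overall)

    def test_every_emitted_value_within_bounds(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            n = int(rng.integers(4, 40))
            ds = random_survival_data(rng, n, cens_frac=float(rng.uniform(0, 0.5)))
            hz = rng.uniform(0.0, 1.0, n)
            mode = ["overall", "cause_specific", "weighted"][int(rng.integers(3))]
            res = rx.compute_re(ds, hz, mode, expected=rng.uniform(0, 0.5, n),
                                jitter=False)
            vals = np.concatenate([[res.overall], res.grid_values])
            vals = vals[np.isfinite(vals)]
            assert np.all(vals >= -1 - 1e-12) and np.all(vals <= 1 + 1e-12)


class TestLocalRE:
    def test_perfect_model_locally_perfect(self):
        n = 30
        times = np.arange(1.0, n + 1)
        ds = simple_data(times, np.ones(n, dtype=int))
        t, v = rx.local_re(ds, (n - times) + 1.0, "overall", window=6)
        assert np.allclose(v, 1.0)

    def test_window_saturation_recovers_overall(self):
        rng = np.random.default_rng(11)
        ds = random_survival_data(rng, 40, cens_frac=0.2)
        hz = rng.uniform(0.1, 1.0, 40)
        D = ds.n_deaths
        t, v = rx.local_re(ds, hz, "overall", window=2 * D + 2, jitter=False)
        overall = rx.compute_re(ds, hz, "overall", tau=float(ds.time[ds.status == 1].max()),
                                jitter=False).overall
        assert np.allclose(v, overall)

    def test_matches_window_restricted_double_loop(self):
        rng = np.random.default_rng(12)
        ds = random_survival_data(rng, 60, cens_frac=0.25)
        D = ds.n_deaths
        M = rng.uniform(0.05, 1.0, (60, D))
        t, v = rx.local_re(ds, M, "overall", window=8, jitter=False)
        terms = eq_weighted_re_terms(ds.time, ds.status, M, np.ones(D))
        for j in rng.integers(0, D, 20):
            lo, hi = max(0, j - 4), min(D - 1, j + 4)
            num = sum(terms[k][1] for k in range(lo, hi + 1))
            den = sum(terms[k][2] for k in range(lo, hi + 1))
            assert v[j] == pytest.approx(num / den, abs=1e-12)

    def test_odd_or_tiny_window_rejected(self):
        ds = simple_data([1.0, 2.0, 3.0], [1, 1, 1])
        for bad in (5, 0, -2):
            with pytest.raises(ValueError):
                rx.local_re(ds, np.ones(3), "overall", window=bad)

    def test_fewer_than_two_deaths_rejected(self):
        ds = simple_data([1.0, 2.0], [1, 0])
        with pytest.raises(ValueError, match="2 deaths"):
            rx.local_re(ds, np.ones(2), "overall", window=2)


class TestSmoothSeries:
    def test_constant_series_unchanged(self):
        v = np.full(25, 0.4)
        np.testing.assert_allclose(rx.smooth_series(v, 0.3), v)

    def test_full_span_returns_mean_in_interior(self):
        v = np.sin(np.linspace(0, 3, 51))
        out = rx.smooth_series(v, 2.0)
        assert out[25] == pytest.approx(v.mean())

    def test_matches_direct_sliding_mean(self):
        rng = np.random.default_rng(13)
        v = rng.uniform(-1, 1, 50)
        out = rx.smooth_series(v, 0.2)
        k = round(0.2 * 50)
        h = k // 2
        for j in range(50):
            lo, hi = max(0, j - h), min(49, j + h)
            assert out[j] == pytest.approx(np.mean(v[lo:hi + 1]))

    def test_output_clipped_to_unit_interval(self):
        out = rx.smooth_series(np.array([5.0, 5.0, 5.0]), 1.0)
        assert np.all(out <= 1.0)


class TestJitterTies:
    def test_no_ties_returned_unchanged(self):
        t = np.array([1.0, 2.0, 3.5])
        np.testing.assert_array_equal(rx.jitter_ties(t), t)

    def test_hundred_identical_times_become_distinct(self):
        t = np.full(100, 2.0)
        out = rx.jitter_ties(t, eps_rel=1e-6, seed=1)
        assert np.unique(out).size == 100
        assert np.all(np.abs(out - 2.0) <= 2.0 * 1e-6 * 2.0)

    def test_order_of_distinct_times_preserved(self):
        rng = np.random.default_rng(14)
        t = np.concatenate([rng.uniform(1, 5, 50), np.full(30, 2.5)])
        out = rx.jitter_ties(t, seed=2)
        distinct = np.unique(t, return_counts=True)
        singles = np.isin(t, distinct[0][distinct[1] == 1])
        # untied records keep both value and relative order
        np.testing.assert_array_equal(out[singles], t[singles])
        assert np.array_equal(np.argsort(out[singles]), np.argsort(t[singles]))

    def test_determinism_by_seed(self):
        t = np.full(20, 1.0)
        np.testing.assert_array_equal(rx.jitter_ties(t, seed=3), rx.jitter_ties(t, seed=3))
        assert not np.array_equal(rx.jitter_ties(t, seed=3), rx.jitter_ties(t, seed=4))

    def test_reordering_epsilon_rejected(self):
        t = np.array([1.0, 1.0, 1.0 + 1e-9, 5.0])
        with pytest.raises(ValueError, match="reorder"):
            rx.jitter_ties(t, eps_rel=1e-3)


class TestBootstrap:
    def test_perfectly_separated_data_gives_near_unit_interval(self):
        # resampling duplicates subjects; duplicated hazards tie and take
        # mid-rank credit, so resample values sit just below 1
        n = 10
        times = np.arange(1.0, n + 1)
        ds = simple_data(times, np.ones(n, dtype=int))
        scores = (n - times) + 1.0
        lo, hi = rx.bootstrap_ci(ds, scores, "overall", B=25, seed=0)
        assert 0.6 < lo <= hi <= 1.0

    def test_same_seed_reproduces_interval(self, s1_small, s1_model):
        spec, ds = s1_small
        kw = dict(mode="weighted", tau=5.0, B=30, seed=7, expected=spec.rate_table)
        ci1 = rx.bootstrap_ci(ds, s1_model, **kw)
        ci2 = rx.bootstrap_ci(ds, s1_model, **kw)
        assert ci1 == ci2
        assert ci1[0] < ci1[1]

    def test_interval_covers_point_estimate(self, s1_small, s1_model):
        spec, ds = s1_small
        point = rx.compute_re(ds, s1_model, "weighted", tau=5.0,
                              expected=spec.rate_table).overall
        lo, hi = rx.bootstrap_ci(ds, s1_model, "weighted", tau=5.0, B=60, seed=8,
                                 expected=spec.rate_table)
        assert lo <= point <= hi

    def test_too_few_replicates_rejected(self, s1_small, s1_model):
        spec, ds = s1_small
        with pytest.raises(ValueError):
            rx.bootstrap_ci(ds, s1_model, "weighted", B=1, expected=spec.rate_table)


def test_default_tau_stops_before_administrative_atom():
    times = np.array([1.0, 2.0, 3.0, 8.0, 8.0, 8.0])
    d = np.array([1, 1, 1, 0, 0, 0])
    assert rx.default_tau(times, d) == 3.0
    # no atom: simply the last death
    assert rx.default_tau(np.array([1.0, 2.0, 5.0]), np.array([1, 0, 1])) == 5.0
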