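import subprocess

import numpy as np
import pandas as pd
import pytest

import ranksexplained as rx
from ranksexplained.excess import ExcessDesign, ExcessLikelihood, FittedExcessModel
from ranksexplained.splines import SplineSpec, rcs_basis


def make_model(theta, baseline=SplineSpec((-8.0, 8.0)), terms=()):
    """Hand-built fitted model with prescribed coefficients."""
    spec = rx.ExcessModelSpec(baseline, terms)
    import pandas as pd

    df = pd.DataFrame({t.name: [0.0, 1.0] for t in terms} or {"_": [0.0, 1.0]})
    ds = rx.SurvivalDataset(pd.DataFrame({"time": [0.5, 2.0], "status": [1, 1], **df}))
    design = ExcessDesign.resolve(spec, ds)
    return FittedExcessModel(design, np.asarray(theta, float), None, 0.0, True, 0)


class TestClosedForms:
    def test_log_cumulative_hazard_at_t_one_and_e(self):
        m = make_model([-2.0, 1.0])
        assert rx.log_cumulative_excess_hazard(m, {}, 1.0) == pytest.approx(-2.0)
        assert rx.log_cumulative_excess_hazard(m, {}, np.e) == pytest.approx(-1.0)

    def test_exponential_model_has_constant_hazard(self):
        m = make_model([np.log(0.3), 1.0])
        for t in (0.1, 1.0, 4.0, 20.0):
            assert rx.excess_hazard(m, {}, t) == pytest.approx(0.3)

    def test_weibull_hazard(self):
        # ln H = ln(0.5) + 2 ln t  ->  hazard 0.5 * 2 * t
        m = make_model([np.log(0.5), 2.0])
        assert rx.excess_hazard(m, {}, 2.0) == pytest.approx(2.0)

    def test_nonpositive_time_rejected(self):
        m = make_model([0.0, 1.0])
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                rx.excess_hazard(m, {}, bad)
            with pytest.raises(ValueError):
                rx.log_cumulative_excess_hazard(m, {}, bad)


def s2_shaped_model():
    terms = (rx.CovariateTerm("agez", tvc_df=1),
             rx.CovariateTerm("stage", transform="categorical", levels=(1, 2, 3), tvc_df=1))
    baseline = SplineSpec((np.log(0.02), np.log(8.0)), (np.log(0.5),))
    rng = np.random.default_rng(5)
    theta = rng.normal(0, 0.3, 1 + 2 + 1 + 1 + 2 + 2)
    theta[3] *= 0.01  # cubic basis column has large scale
    spec = rx.ExcessModelSpec(baseline, terms)
    df = pd.DataFrame({"time": [0.5, 1.0, 2.0], "status": [1, 1, 1],
                       "agez": [0.0, 1.0, -1.0], "stage": [1, 2, 3]})
    ds = rx.SurvivalDataset(df)
    design = ExcessDesign.resolve(spec, ds)
    return FittedExcessModel(design, theta, None, 0.0, True, 0)


def test_linear_predictor_matches_manual_term_assembly():
    m = s2_shaped_model()
    th = m.theta
    bl = m.design.baseline
    tvc = m.design.terms[0].tvc_spline
    rng = np.random.default_rng(6)
    for _ in range(50):
        x = {"agez": rng.normal(), "stage": int(rng.integers(1, 4))}
        t = float(rng.uniform(0.05, 10.0))
        z = np.log(t)
        b, _ = rcs_basis(z, bl)
        tz, _ = rcs_basis(z, tvc)
        s2 = float(x["stage"] == 2)
        s3 = float(x["stage"] == 3)
        manual = (th[0] + b @ th[1:3]
                  + th[3] * x["agez"] + th[4] * x["agez"] * tz[0]
                  + th[5] * s2 + th[6] * s3
                  + th[7] * s2 * tz[0] + th[8] * s3 * tz[0])
        assert rx.log_cumulative_excess_hazard(m, x, t) == pytest.approx(manual, abs=1e-10)


def test_hazard_matches_numerical_differentiation_of_H():
    m = s2_shaped_model()
    rng = np.random.default_rng(7)
    for _ in range(30):
        x = {"agez": rng.normal(), "stage": int(rng.integers(1, 4))}
        t = float(rng.uniform(0.1, 8.0))
        h = 1e-5 * t
        Hp = np.exp(rx.log_cumulative_excess_hazard(m, x, t + h))
        Hm = np.exp(rx.log_cumulative_excess_hazard(m, x, t - h))
        fd = (Hp - Hm) / (2 * h)
        assert rx.excess_hazard(m, x, t) == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestLikelihood:
    def test_single_subject_exponential_mle(self):
        df = pd.DataFrame({"time": [2.0], "status": [1]})
        ds = rx.SurvivalDataset(df)
        design = ExcessDesign.resolve(
            rx.ExcessModelSpec(SplineSpec((-8.0, 8.0))), ds)
        # exponential with rate lam: theta = (ln lam, 1)
        def nll(lam):
            return rx.neg_log_likelihood([np.log(lam), 1.0], design, ds,
                                         np.zeros(1))
        assert nll(0.7) == pytest.approx(-(np.log(0.7) - 0.7 * 2.0))
        lams = np.linspace(0.05, 3.0, 400)
        best = lams[np.argmin([nll(l) for l in lams])]
        assert best == pytest.approx(1 / 2.0, abs=0.01)  # MLE = 1/t

    def test_censored_only_value_is_sum_H_independent_of_lambda_p(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "status": [0, 0, 0]})
        ds = rx.SurvivalDataset(df)
        design = ExcessDesign.resolve(rx.ExcessModelSpec(SplineSpec((-8.0, 8.0))), ds)
        theta = [np.log(0.4), 1.0]
        expect = 0.4 * (1 + 2 + 3)
        v0 = rx.neg_log_likelihood(theta, design, ds, np.zeros(3))
        v1 = rx.neg_log_likelihood(theta, design, ds, np.full(3, 0.5))
        assert v0 == pytest.approx(expect)
        assert v1 == pytest.approx(expect)

    def test_matches_naive_per_subject_loop(self):
        rng = np.random.default_rng(8)
        n = 20
        df = pd.DataFrame({"time": rng.uniform(0.2, 5.0, n),
                           "status": rng.integers(0, 2, n),
                           "agez": rng.normal(0, 1, n)})
        ds = rx.SurvivalDataset(df, covariate_cols=("agez",))
        spec = rx.ExcessModelSpec(SplineSpec((np.log(0.1), np.log(6.0)), (0.0,)),
                                  (rx.CovariateTerm("agez"),))
        design = ExcessDesign.resolve(spec, ds)
        theta = np.array([-0.5, 0.9, 0.01, 0.3])
        lam_p = rng.uniform(0.0, 0.1, n)
        model = FittedExcessModel(design, theta, None, 0.0, True, 0)
        loop = 0.0
        for i in range(n):
            x = {"agez": df.agez[i]}
            t = df.time[i]
            H = np.exp(rx.log_cumulative_excess_hazard(model, x, t))
            if df.status[i] == 1:
                loop -= np.log(lam_p[i] + rx.excess_hazard(model, x, t))
            loop += H
        assert rx.neg_log_likelihood(theta, design, ds, lam_p) == pytest.approx(loop, abs=1e-10)

    def test_infeasible_event_hazard_gives_infinity(self):
        df = pd.DataFrame({"time": [1.0], "status": [1]})
        ds = rx.SurvivalDataset(df)
        design = ExcessDesign.resolve(rx.ExcessModelSpec(SplineSpec((-8.0, 8.0))), ds)
        # negative d lnH / d lnt at the event -> negative hazard, lambda_p = 0
        assert rx.neg_log_likelihood([0.0, -1.0], design, ds, np.zeros(1)) == np.inf

    def test_likelihood_invariant_to_subject_order(self):
        rng = np.random.default_rng(9)
        n = 30
        df = pd.DataFrame({"time": rng.uniform(0.2, 5.0, n),
                           "status": rng.integers(0, 2, n),
                           "agez": rng.normal(0, 1, n)})
        lam_p = rng.uniform(0, 0.1, n)
        spec = rx.ExcessModelSpec(SplineSpec((np.log(0.1), np.log(6.0))),
                                  (rx.CovariateTerm("agez"),))
        theta = [-0.5, 0.9, 0.3]
        perm = rng.permutation(n)
        v1 = rx.neg_log_likelihood(
            theta, ExcessDesign.resolve(spec, rx.SurvivalDataset(df, covariate_cols=("agez",))),
            rx.SurvivalDataset(df, covariate_cols=("agez",)), lam_p)
        dfp = df.iloc[perm].reset_index(drop=True)
        v2 = rx.neg_log_likelihood(
            theta, ExcessDesign.resolve(spec, rx.SurvivalDataset(dfp, covariate_cols=("agez",))),
            rx.SurvivalDataset(dfp, covariate_cols=("agez",)), lam_p[perm])
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestFit:
    def test_exponential_rate_recovery_without_background(self):
        rng = np.random.default_rng(10)
        n = 5000
        t = rng.exponential(1 / 0.4, n)
        df = pd.DataFrame({"time": t, "status": np.ones(n, dtype=int)})
        ds = rx.SurvivalDataset(df)
        m = rx.fit(ds, None, rx.ExcessModelSpec(SplineSpec((np.log(t.min()), np.log(t.max())))))
        rate = np.exp(m.theta[0])
        se = rate * np.sqrt(m.cov[0, 0])  # delta method on ln rate
        assert m.theta[1] == pytest.approx(1.0, abs=0.05)
        assert abs(rate - 0.4) < 3 * se

    def test_refit_is_bitwise_deterministic(self, s1_small):
        spec, ds = s1_small
        mspec = rx.ExcessModelSpec(3, (rx.CovariateTerm("agez"),))
        m1 = rx.fit(ds, spec.rate_table, mspec)
        m2 = rx.fit(ds, spec.rate_table, mspec)
        np.testing.assert_array_equal(m1.theta, m2.theta)

    def test_fewer_events_than_parameters_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "status": [1, 0, 0],
                           "agez": [0.0, 1.0, -1.0]})
        ds = rx.SurvivalDataset(df, covariate_cols=("agez",))
        with pytest.raises(ValueError, match="fewer events"):
            rx.fit(ds, None, rx.ExcessModelSpec(SplineSpec((-1.0, 1.1)),
                                                (rx.CovariateTerm("agez"),)))

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "status": [0, 0]})
        with pytest.raises(ValueError, match="at least one event"):
            rx.fit(rx.SurvivalDataset(df), None, rx.ExcessModelSpec(2))

    def test_serialization_round_trip(self, s1_model):
        back = FittedExcessModel.from_json(s1_model.to_json())
        np.testing.assert_array_equal(back.theta, s1_model.theta)
        t = np.array([0.5, 2.0, 7.0])
        x = {"agez": 0.7}
        np.testing.assert_allclose(back.excess_hazard(x, t), s1_model.excess_hazard(x, t))


class TestHazardMatrix:
    def test_proportional_model_preserves_subject_ordering(self, s1_small, s1_model):
        _, ds = s1_small
        lam = rx.hazard_matrix(s1_model, ds, np.array([0.5, 1.0, 3.0, 7.0]))
        orders = [np.argsort(lam[:, j], kind="stable") for j in range(lam.shape[1])]
        for o in orders[1:]:
            np.testing.assert_array_equal(o, orders[0])

    def test_degenerate_single_entry_equals_excess_hazard(self, s1_small, s1_model):
        _, ds = s1_small
        one = ds.subset([3])
        lam = rx.hazard_matrix(s1_model, one, np.array([1.5]))
        expect = rx.excess_hazard(s1_model, ds.df.iloc[[3]], 1.5)
        assert lam[0, 0] == pytest.approx(expect)

    def test_spot_check_against_pointwise_hazard(self, s1_small, s1_model):
        _, ds = s1_small
        times = np.linspace(0.3, 7.5, 20)
        lam = rx.hazard_matrix(s1_model, ds, times)
        rng = np.random.default_rng(11)
        for _ in range(100):
            i = int(rng.integers(ds.n))
            j = int(rng.integers(times.size))
            expect = rx.excess_hazard(s1_model, ds.df.iloc[[i]], times[j])
            assert lam[i, j] == pytest.approx(max(expect, 0.0), abs=1e-12)


def test_cause_specific_special_case_matches_flexsurv_loglik(s1_small):
    """With lambda_P = 0 the model is an ordinary Royston-Parmar model;
    R's flexsurv evaluates the same likelihood at our fitted parameters."""
    spec, ds = s1_small
    df = ds.df.copy()
    df["status_cs"] = (df.cause == "cancer").astype(int)
    ds_cs = rx.SurvivalDataset(df, time_col="time", status_col="status_cs",
                               covariate_cols=("agez",))
    m = rx.fit(ds_cs, None, rx.ExcessModelSpec(3, (rx.CovariateTerm("agez"),)))
    bk = m.design.baseline.boundary_knots
    ik = m.design.baseline.interior_knots
    import tempfile, os
    with tempfile.TemporaryDirectory() as tmp:
        csv = os.path.join(tmp, "d.csv")
        df[["time", "status_cs", "agez"]].to_csv(csv, index=False)
        rscript = os.path.join(tmp, "ll.R")
        with open(rscript, "w") as fh:
            fh.write(
                'suppressMessages(library(flexsurv))\n'
                f'd <- read.csv("{csv}")\n'
                'fs <- flexsurvspline(Surv(time, status_cs) ~ agez, data=d, scale="hazard",\n'
                f'  knots=c({",".join(f"{float(k):.17g}" for k in ik)}), '
                f'bknots=c({float(bk[0]):.17g}, {float(bk[1]):.17g}),\n'
                f'  inits=c({",".join(f"{float(v):.17g}" for v in m.theta)}), fixedpars=TRUE)\n'
                'cat(sprintf("%.12f", fs$loglik))\n')
        out = subprocess.run(["Rscript", rscript], capture_output=True, text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    assert float(out.stdout) == pytest.approx(m.loglik, abs=1e-8)
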