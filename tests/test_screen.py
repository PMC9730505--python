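"""AFT fitting, hazard-ratio conversion, diagnostics and the per-core screen."""

import numpy as np
import pandas as pd
import pytest

from tcemm.cohort import CohortConfig, simulate_survival
from tcemm.screen import (
    AFTScreener,
    aft_to_hr,
    aic_compare,
    bh_adjust,
    fit_aft,
    frequency_compare,
    ph_test,
    score_association,
)


def weibull_data(n, seed, beta=(0.3, -0.2), sigma=0.8, mu=2.0, censor_mean=25.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    logT = mu + X @ np.array(beta) + sigma * np.log(rng.exponential(size=n))
    T = np.exp(logT)
    C = rng.exponential(censor_mean, n)
    t = np.minimum(T, C)
    d = (T <= C).astype(int)
    return t, d, pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])


class TestFitAFT:
    def test_matches_lifelines_weibull(self):
        from lifelines import WeibullAFTFitter

        t, d, X = weibull_data(2000, 1)
        fit = fit_aft(t, d, X, "weibull")
        df = X.copy()
        df["time"], df["event"] = t, d
        wf = WeibullAFTFitter().fit(df, "time", "event")
        for c in X.columns:
            assert fit.coefficients[c][0] == pytest.approx(
                wf.params_[("lambda_", c)], abs=1e-4
            )
        assert fit.sigma == pytest.approx(1 / np.exp(wf.params_[("rho_", "Intercept")]), abs=1e-4)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, abs=1e-4)

    def test_exponential_sample_sigma_one(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5.0, 5000)
        d = np.ones(5000, int)
        fit = fit_aft(t, d, pd.DataFrame(index=range(5000)), "weibull")
        assert fit.sigma == pytest.approx(1.0, abs=0.05)

    def test_aic_identity(self):
        t, d, X = weibull_data(800, 3)
        for dist in ("weibull", "lognormal", "loglogistic", "exponential"):
            f = fit_aft(t, d, X, dist)
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik, abs=1e-9)

    def test_all_censored_rejected(self):
        t = np.ones(50)
        with pytest.raises(ValueError, match="event"):
            fit_aft(t, np.zeros(50), pd.DataFrame(index=range(50)))

    def test_null_covariate_ci_coverage(self):
        # independent covariate: the 95% CI for its coefficient covers 0
        # in about 95% of replicates
        cover = 0
        reps = 120
        for r in range(reps):
            t, d, X = weibull_data(400, 100 + r, beta=(0.3, 0.0))
            f = fit_aft(t, d, X, "weibull")
            est, se = f.coefficients["x1"]
            cover += abs(est) <= 1.959964 * se
        assert 0.90 <= cover / reps <= 0.99


class TestHRConversion:
    def test_closed_forms(self):
        t, d, X = weibull_data(1500, 4)
        fit = fit_aft(t, d, X, "weibull")
        hr, _, _ = aft_to_hr(fit, "x0")
        beta = fit.coefficients["x0"][0]
        assert hr == pytest.approx(np.exp(-beta / fit.sigma), rel=1e-12)

    def test_agrees_with_cox_under_ph(self):
        from lifelines import CoxPHFitter

        t, d, X = weibull_data(5000, 5, beta=(-0.2, 0.25))
        fit = fit_aft(t, d, X, "weibull")
        hr, _, _ = aft_to_hr(fit, "x0")
        df = X.copy()
        df["time"], df["event"] = t, d
        cox_hr = float(np.exp(CoxPHFitter().fit(df, "time", "event").params_["x0"]))
        assert hr == pytest.approx(cox_hr, rel=0.10)

    def test_non_weibull_rejected(self):
        t, d, X = weibull_data(300, 6)
        fit = fit_aft(t, d, X, "lognormal")
        with pytest.raises(ValueError, match="Weibull"):
            aft_to_hr(fit, "x0")


class TestPHAndAIC:
    def test_ph_type_one_error_moderate(self):
        rejections = 0
        reps = 60
        for r in range(reps):
            t, d, X = weibull_data(300, 200 + r)
            rejections += ph_test(t, d, X, "x0") < 0.05
        assert rejections / reps < 0.15

    def test_crossing_hazards_detected(self):
        # two groups with strongly different Weibull shapes -> PH violated
        rng = np.random.default_rng(7)
        n = 4000
        g = np.repeat([0.0, 1.0], n // 2)
        t = np.where(
            g == 0,
            np.exp(0.7 + 0.25 * np.log(rng.exponential(size=n))),
            np.exp(0.5 + 2.2 * np.log(rng.exponential(size=n))),
        )
        C = rng.exponential(15, n)
        obs, d = np.minimum(t, C), (t <= C).astype(int)
        p = ph_test(obs, d, pd.DataFrame({"g": g}), "g")
        assert p < 0.01

    def test_constant_covariate_returns_nan(self):
        t, d, X = weibull_data(300, 8)
        X["const"] = 1.0
        assert np.isnan(ph_test(t, d, X, "const"))

    def test_weibull_wins_aic_on_weibull_data(self):
        wins = 0
        reps = 20
        for r in range(reps):
            t, d, X = weibull_data(800, 300 + r, sigma=0.7)
            aics = aic_compare(t, d, X)
            aft = {k: v for k, v in aics.items() if k != "cox"}
            wins += min(aft, key=aft.get) == "weibull"
        assert wins >= reps * 0.75

    def test_exponential_nested_in_weibull(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(4.0, 2000)
        d = np.ones(2000, int)
        aics = aic_compare(t, d, pd.DataFrame(index=range(2000)))
        assert aics["exponential"] <= aics["weibull"] + 2.0


class TestBH:
    def test_hand_enumerated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_cases(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.2]))

    def test_matches_exhaustive_threshold_oracle(self, rng):
        # q_i = min_{t >= rank(i)} p_(t) * m / t  -- check by enumeration
        for _ in range(25):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            q = bh_adjust(p)
            order = np.argsort(p)
            expected = np.empty(m)
            sorted_p = p[order]
            running = 1.0
            for i in range(m - 1, -1, -1):
                running = min(running, sorted_p[i] * m / (i + 1))
                expected[order[i]] = running
            np.testing.assert_allclose(q, expected, atol=1e-12)


class TestScreen:
    @staticmethod
    def _cohort_with_cores(n, seed, planted_beta=0.0, n_cores=5):
        rng = np.random.default_rng(seed)
        cores = {f"CORE{j:02d}AAA": rng.binomial(1, 0.25, n).astype(float)
                 for j in range(n_cores)}
        X = pd.DataFrame(cores)
        X["age"] = rng.normal(0, 1, n)
        design = X.copy()
        cfg = CohortConfig(
            n_pairs=n, seed=seed, covariate_betas={"age": -0.1},
            planted_effects={"CORE00AAA": planted_beta} if planted_beta else {},
        )
        t, e, _ = simulate_survival(design, cfg)
        return t, e, X

    def test_planted_signal_recovered(self):
        import sksurv.util

        t, e, X = self._cohort_with_cores(3000, 11, planted_beta=-0.5)
        y = sksurv.util.Surv.from_arrays(event=e.astype(bool), time=t)
        scr = AFTScreener(covariate_cols=["age"], min_support=50).fit(X, y)
        res = scr.results_.set_index("tcemm")
        assert res.loc["CORE00AAA", "hr"] > 1
        assert res.loc["CORE00AAA", "q"] < 0.05

    def test_min_support_excludes_without_fitting(self):
        import sksurv.util

        t, e, X = self._cohort_with_cores(200, 12)
        X["RARECORE9"] = 0.0
        X.loc[:30, "RARECORE9"] = 1.0
        y = sksurv.util.Surv.from_arrays(event=e.astype(bool), time=t)
        scr = AFTScreener(covariate_cols=["age"], min_support=49).fit(X, y)
        row = scr.results_.set_index("tcemm").loc["RARECORE9"]
        assert not row["included"]
        assert np.isnan(row["hr"])

    def test_min_support_monotone(self):
        import sksurv.util

        t, e, X = self._cohort_with_cores(400, 13)
        y = sksurv.util.Surv.from_arrays(event=e.astype(bool), time=t)
        inc = {}
        for ms in (20, 80, 120):
            scr = AFTScreener(covariate_cols=["age"], min_support=ms).fit(X, y)
            inc[ms] = set(scr.results_.loc[scr.results_["included"], "tcemm"])
        assert inc[120] <= inc[80] <= inc[20]


class TestScoreAssociation:
    def test_zero_score_maps_to_zero_exposure(self):
        assert np.log1p(0) == 0.0  # the transform contract: log(score + 1)

    def test_recovers_log_score_effect(self):
        rng = np.random.default_rng(14)
        n = 10_000
        # dispersed mismatch loads so the per-unit log-score effect is estimable
        scores = rng.poisson(rng.lognormal(3.0, 0.9, n))
        expo = np.log1p(scores)
        cfg = CohortConfig(n_pairs=n, seed=14, covariate_betas={"log_score": -0.1},
                           weibull_sigma=0.7)
        t, e, _ = simulate_survival(pd.DataFrame({"log_score": expo}), cfg)
        res = score_association(t, e, scores)
        assert res["univariable"]["hr"] == pytest.approx(np.exp(0.1 / 0.7), rel=0.10)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            score_association(np.ones(10), np.ones(10, int), np.array([-1] * 10))


def test_frequency_compare_groups():
    screen = pd.DataFrame(
        {
            "tcemm": list("abcdef"),
            "frequency": [0.1, 0.2, 0.3, 0.15, 0.25, 0.05],
            "q": [0.01, 0.2, 0.03, 0.6, 0.9, 0.04],
        }
    )
    out = frequency_compare(screen, alpha=0.05)
    assert out["significant"]["n"] == 3
    assert out["significant"]["median"] == pytest.approx(np.median([0.1, 0.3, 0.05]))
    all_sig = screen.assign(q=0.001)
    assert "not_significant" not in frequency_compare(all_sig)
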