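"""Clinical layer: carrier D', matching, OLS oracle, Cox partial
likelihood against brute-force enumeration, Andersen-Gill reduction,
Schoenfeld sums, Kaplan-Meier hand computation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from garep.clinical import (
    CarrierTable,
    carrier_dprime,
    exact_match,
    fit_cox,
    fit_cox_ag,
    fit_linear_interaction,
    kaplan_meier,
    schoenfeld_residuals,
)

# carrier counts (n, nA, nB, nAB) of six published MS cohorts and the
# normalized D' printed for each
PRINTED_CARRIER_TABLES = {
    "ACP": ((309, 101, 136, 60), 0.27),
    "BIONAT": ((1255, 359, 564, 212), 0.26),
    "EPIC": ((178, 57, 98, 35), 0.14),
    "FinBB": ((1049, 515, 489, 265), 0.10),
    "NationMS": ((405, 125, 193, 80), 0.31),
    "CombiRx": ((699, 216, 341, 146), 0.37),
}


class TestCarrierDprime:
    @pytest.mark.parametrize("name", sorted(PRINTED_CARRIER_TABLES))
    def test_reproduces_printed_values_to_two_decimals(self, name):
        (n, na, nb, nab), expected = PRINTED_CARRIER_TABLES[name]
        assert round(carrier_dprime(CarrierTable(n, na, nb, nab)), 2) == expected

    def test_independence_gives_zero(self):
        # nAB = nA*nB/n exactly
        assert carrier_dprime(CarrierTable(100, 40, 50, 20)) == 0.0

    def test_complete_association_gives_one(self):
        assert carrier_dprime(CarrierTable(100, 30, 50, 30)) == pytest.approx(1.0)

    def test_negative_association_uses_other_bound(self):
        d = carrier_dprime(CarrierTable(100, 50, 50, 10))
        assert 0 < d <= 1

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            carrier_dprime(CarrierTable(100, 0, 50, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CarrierTable(100, 10, 10, 20)
        with pytest.raises(ValueError):
            CarrierTable(50, 40, 40, 10)


class TestExactMatch:
    def _groups(self, rng, n=200, shift=0.0):
        def grp(n, shift):
            return pd.DataFrame(
                {
                    "age": rng.normal(40 + shift, 8, n),
                    "sex": rng.choice(["f", "m"], n),
                    "a03": rng.random(n) < 0.3 + shift / 50,
                    "dr15": rng.random(n) < 0.5,
                }
            )
        return grp(n, shift), grp(n, 0.0)

    def test_identical_groups_fully_retained(self):
        df = pd.DataFrame(
            {"age": [40, 50], "sex": ["f", "m"], "a03": [True, False], "dr15": [False, True]}
        )
        matched, report = exact_match(df, df.copy())
        assert len(matched) == 4

    def test_case_only_stratum_dropped(self):
        cases = pd.DataFrame({"age": [40, 41], "sex": ["f", "f"], "a03": [True, False],
                              "dr15": [False, False]})
        controls = pd.DataFrame({"age": [40], "sex": ["f"], "a03": [True], "dr15": [False]})
        matched, report = exact_match(cases, controls, n_age_bins=1)
        assert set(matched["a03"]) == {True}

    def test_matching_balances_covariates_within_strata(self, rng):
        cases, controls = self._groups(rng, shift=6.0)
        matched, report = exact_match(cases, controls)
        # categorical matching variables are exactly balanced within strata
        for _, stratum in matched.groupby("_stratum"):
            for var in ("a03", "dr15", "sex"):
                assert stratum[var].nunique() == 1
        # weighted (per-stratum reweighted) group difference vanishes for
        # the categoricals: reweight controls to the case stratum sizes
        case_w = matched[matched.group == "case"].groupby("_stratum").size()
        ctrl = matched[matched.group == "control"]
        w = ctrl["_stratum"].map(case_w / ctrl.groupby("_stratum").size())
        for var in ("a03", "dr15"):
            case_mean = matched[matched.group == "case"][var].mean()
            ctrl_mean = np.average(ctrl[var], weights=w)
            assert abs(case_mean - ctrl_mean) < 1e-12

    def test_no_overlap_warns_and_returns_empty(self):
        cases = pd.DataFrame({"age": [40], "sex": ["f"], "a03": [True], "dr15": [False]})
        controls = pd.DataFrame({"age": [41], "sex": ["m"], "a03": [False], "dr15": [True]})
        with pytest.warns(UserWarning, match="no overlapping"):
            matched, _ = exact_match(cases, controls, n_age_bins=1)
        assert matched.empty


class TestLinearInteraction:
    def test_equals_normal_equation_oracle_on_small_fixture(self, rng):
        n = 10
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x1": rng.normal(size=n),
                "x2": rng.random(n) < 0.5,
            }
        ).astype(float)
        fit = fit_linear_interaction(df, "y", ["x1", "x2"], scale_columns=())
        X = np.column_stack([np.ones(n), df["x1"], df["x2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"])
        np.testing.assert_allclose(fit.summary["coef"].to_numpy(), beta, rtol=1e-10)

    def test_null_interaction_estimates_center_at_zero(self, rng):
        ests = []
        for _ in range(25):
            n = 200
            df = pd.DataFrame(
                {
                    "ga": np.repeat([0, 1], n // 2),
                    "a03": rng.random(n) < 0.4,
                }
            ).astype(float)
            df["ga_x_a03"] = df["ga"] * df["a03"]
            df["y"] = rng.normal(size=n)
            fit = fit_linear_interaction(df, "y", ["ga", "a03", "ga_x_a03"], scale_columns=())
            ests.append(fit.coef("ga_x_a03"))
        assert abs(np.mean(ests)) < 3 * np.std(ests) / np.sqrt(len(ests))

    def test_collinear_design_names_columns(self, rng):
        n = 30
        df = pd.DataFrame({"y": rng.normal(size=n), "x1": rng.normal(size=n)})
        df["x2"] = 2 * df["x1"]
        with pytest.raises(ValueError, match="x2"):
            fit_linear_interaction(df, "y", ["x1", "x2"], scale_columns=())


def brute_force_cox_loglik(beta, times, events, x):
    """Breslow-free partial log-likelihood by direct risk-set enumeration
    (distinct event times, no ties)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestCox:
    def test_six_subject_fixture_matches_brute_force_enumeration(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = fit_cox(df, "time", "event", ["x"])
        res = minimize_scalar(
            lambda b: -brute_force_cox_loglik(b, times, events, x), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coef("x") == pytest.approx(res.x, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(
            brute_force_cox_loglik(fit.coef("x"), times, events, x), abs=1e-6
        )

    def test_two_group_exponential_recovers_rate_ratio(self, rng):
        n = 4000
        group = np.repeat([0, 1], n // 2)
        rate = np.where(group == 1, 2.0, 1.0)
        df = pd.DataFrame({"time": rng.exponential(1 / rate), "event": 1, "x": group})
        fit = fit_cox(df, "time", "event", ["x"])
        assert fit.hr("x") == pytest.approx(2.0, rel=0.1)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, "time", "event", ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, "time", "event", ["x"])


class TestAndersenGill:
    def _single_interval_data(self, rng, n=300):
        x = rng.random(n) < 0.5
        t = rng.exponential(np.where(x, 0.5, 1.0))
        cens = np.minimum(t, 2.0)
        event = (t <= 2.0).astype(int)
        return pd.DataFrame(
            {
                "subject_id": [f"p{i}" for i in range(n)],
                "start": 0.0,
                "stop": cens,
                "time": cens,
                "event": event,
                "x": x.astype(float),
            }
        )

    def test_single_interval_reduces_to_cox(self, rng):
        df = self._single_interval_data(rng)
        ag = fit_cox_ag(df, "start", "stop", "event", ["x"])
        cox = fit_cox(df, "time", "event", ["x"])
        assert ag.coef("x") == pytest.approx(cox.coef("x"), abs=1e-6)

    def test_overlapping_intervals_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": ["p0", "p0"],
                "start": [0.0, 0.5],
                "stop": [1.0, 2.0],
                "event": [1, 0],
                "x": [1.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            fit_cox_ag(df, "start", "stop", "event", ["x"])

    def test_robust_se_exceeds_naive_under_within_subject_correlation(self, rng):
        from garep.simulate import ClinicalConfig, simulate_trial

        cc = ClinicalConfig(frailty_sd=0.8, hr_ga_x_a03=1.0, hr_gaifn_x_a03=1.0)
        data = simulate_trial([("IFN", 150, 50), ("GA", 150, 50)], cc, rng)
        df = data["recurrent"].merge(data["subjects"], on="subject_id")
        ag = fit_cox_ag(df, "start", "stop", "event", ["ga"])
        cox_naive = fit_cox(
            df.assign(time=df["stop"] - df["start"]), "time", "event", ["ga"]
        )
        assert ag.summary.loc["ga", "se"] > cox_naive.summary.loc["ga", "se"]


class TestSchoenfeld:
    def test_residual_columns_sum_to_zero_at_mple(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "time": rng.exponential(1, n),
                "event": rng.random(n) < 0.8,
                "x": rng.normal(size=n),
                "z": rng.random(n) < 0.5,
            }
        ).astype(float)
        fit = fit_cox(df, "time", "event", ["x", "z"])
        res = schoenfeld_residuals(fit)
        assert np.allclose(res.sum(axis=0), 0.0, atol=1e-6)

    def test_proportional_hazards_gives_flat_residual_trend(self, rng):
        n = 500
        df = pd.DataFrame(
            {"time": rng.exponential(1, n), "event": 1.0, "x": rng.normal(size=n)}
        )
        df["time"] *= np.exp(-0.5 * df["x"])
        fit = fit_cox(df, "time", "event", ["x"])
        res = schoenfeld_residuals(fit).sort_index()
        times = np.asarray(res.index, dtype=float)
        slope = np.polyfit(times, res["x"], 1)[0]
        resid_sd = res["x"].std()
        assert abs(slope) * (times.max() - times.min()) < resid_sd


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        (curve,) = kaplan_meier(df, "time", "event").values()
        assert (curve["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]})
        (curve,) = kaplan_meier(df, "time", "event").values()
        assert curve.loc[2.0, "survival"] == pytest.approx(0.5)
        assert curve.loc[4.0, "survival"] == pytest.approx(0.0)

    def test_hand_computed_with_one_censoring(self):
        # events at 1, 3, 4; censored at 2:
        # S(1) = 4/5... n=5: t=1 event (5 at risk) -> 4/5; t=2 censored;
        # t=3 event (3 at risk) -> 4/5 * 2/3; t=4 event (2 at risk) -> * 1/2
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0], "event": [1, 0, 1, 1, 0]}
        )
        (curve,) = kaplan_meier(df, "time", "event").values()
        assert curve.loc[1.0, "survival"] == pytest.approx(4 / 5)
        assert curve.loc[3.0, "survival"] == pytest.approx(4 / 5 * 2 / 3)
        assert curve.loc[4.0, "survival"] == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)

    def test_grouped_curves(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 1.5, 2.5], "event": [1, 1, 0, 1], "g": ["a", "a", "b", "b"]}
        )
        curves = kaplan_meier(df, "time", "event", "g")
        assert set(curves) == {"a", "b"}
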