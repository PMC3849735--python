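"""Kaplan–Meier, log-rank, Cox partial likelihood, risk stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histohet import (
    CohortSpec,
    assign_risk_groups,
    cox_fit,
    cox_score_residual,
    generate_cohort,
    km_estimate,
    logrank_test,
    univariate_screen,
)
from histohet.survival import RISK_GROUP_LABELS, _efron_loglik


def km_oracle(times, events):
    """Brute-force product-limit: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert km(10.0) == pytest.approx(1.0)

    def test_two_patients_closed_form(self):
        km = km_estimate([1.0, 2.0], [1, 1])
        assert km(0.5) == pytest.approx(1.0)
        assert km(1.5) == pytest.approx(0.5)
        assert km(2.5) == pytest.approx(0.0)

    def test_mixed_censoring_matches_product_limit_oracle(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0, 8.0, 9.0]
        events = [1, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        km = km_estimate(times, events)
        for t, s in km_oracle(times, events).items():
            assert km(t) == pytest.approx(s, abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 0, 1, 1, 0]
        stat, p = logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            t0 = rng.exponential(1.0, 200)
            t1 = rng.exponential(1.0 / 3.0, 200)
            t = np.concatenate([t0, t1])
            g = np.repeat([0, 1], 200)
            _, p = logrank_test(t, np.ones_like(t, int), g)
            rejections += p < 0.01
        assert rejections >= 95

    def test_single_event_time_reduces_to_contingency_chi_square(self):
        # all events at t=1, groups differ only in event count; the
        # log-rank statistic equals the 2×2 chi-square without continuity
        # correction (hypergeometric variance form)
        times = [1.0] * 6 + [2.0] * 6  # events at t=1, censored later
        events = [1, 1, 1, 0, 0, 0] + [0] * 6
        groups = [0, 0, 1, 0, 1, 1] + [0, 0, 0, 1, 1, 1]
        stat, _ = logrank_test(times, events, groups)
        obs = np.array([[2, 4], [1, 5]])  # events/non-events per group at t=1
        n, d = 12, 3
        n1 = 6
        expected1 = d * n1 / n
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2 = (obs[0, 0] - expected1) ** 2 / var
        assert stat == pytest.approx(chi2, rel=1e-6)


class TestCoxFit:
    def test_null_covariate_recovers_zero(self):
        hits = 0
        for s in range(20):
            c = generate_cohort(
                CohortSpec(n=1000, log_hr={"mitotic_index": 0, "node_pos": 0, "cp2": 0}), s
            )
            fit = cox_fit(c, ["cp2"])
            hits += abs(fit.coef[0]) < 0.1
        assert hits >= 18

    def test_three_patient_brute_force_partial_likelihood_oracle(self):
        # 3 patients, events at t=1,2, censored at 3; one covariate.
        # the written-out partial likelihood is
        #   L(β) = e^{βx₁}/(e^{βx₁}+e^{βx₂}+e^{βx₃}) × e^{βx₂}/(e^{βx₂}+e^{βx₃})
        df = pd.DataFrame(
            {"dfs_time": [1.0, 2.0, 3.0], "event": [1, 1, 0], "x": [1.0, 2.0, 0.0]}
        )
        grid = np.linspace(-3, 3, 600_001)
        x = df["x"].to_numpy()

        def logpl(b):
            num = b * x[0] - np.logaddexp.reduce([b * x[0], b * x[1], b * x[2]])
            num += b * x[1] - np.logaddexp(b * x[1], b * x[2])
            return num

        beta_oracle = grid[np.argmax([logpl(b) for b in grid])]
        fit = cox_fit(df, ["x"])
        assert fit.coef[0] == pytest.approx(beta_oracle, abs=1e-4)
        assert fit.log_likelihood == pytest.approx(logpl(fit.coef[0]), abs=1e-9)

    def test_score_equation_residual_vanishes_at_fit(self):
        c = generate_cohort(CohortSpec(n=500), 7)
        fit = cox_fit(c, ["mitotic_index_std", "node_pos", "cp2"])
        assert cox_score_residual(c, fit) < 1e-6

    def test_hazard_ratio_is_exp_of_coefficient(self):
        c = generate_cohort(CohortSpec(n=300), 1)
        fit = cox_fit(c, ["cp2"])
        assert fit.hazard_ratios[0] == np.exp(fit.coef[0])

    def test_collinear_covariates_rejected(self):
        c = generate_cohort(CohortSpec(n=100), 1)
        c["cp2_twice"] = 2 * c["cp2"]
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(c, ["cp2", "cp2_twice"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"dfs_time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])

    def test_efron_loglik_handles_ties_consistently(self):
        # tied event times: our Efron log-likelihood at lifelines' beta
        # equals lifelines' reported log-likelihood
        df = pd.DataFrame(
            {
                "dfs_time": [1.0, 1.0, 2.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 0, 1, 0],
                "x": [0.5, 1.0, -0.3, 0.2, 0.0, -1.0],
            }
        )
        fit = cox_fit(df, ["x"])
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(df, "dfs_time", "event")
        assert fit.log_likelihood == pytest.approx(float(cph.log_likelihood_), abs=1e-6)
        assert fit.coef[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)


class TestRiskGroups:
    def _cohort(self, mi, node):
        return pd.DataFrame({"mitotic_index": mi, "node_pos": node})

    def test_three_factor_patient(self):
        g = assign_risk_groups(self._cohort([12.0], [1]), [True])
        assert g.factor_count[0] == 3
        assert g.group[0] == "3 factors"

    def test_boundary_mitotic_index_is_strict(self):
        # mitotic index exactly 10 does NOT count as a poor factor
        g = assign_risk_groups(self._cohort([10.0], [0]), [False])
        assert g.factor_count[0] == 0
        assert g.group[0] == "0 factor"

    def test_single_factor_patient(self):
        g = assign_risk_groups(self._cohort([25.0], [0]), [False])
        assert g.factor_count[0] == 1
        assert g.group[0] == "1 or 2 factors"

    def test_groups_partition_the_cohort(self):
        c = generate_cohort(CohortSpec(n=368), 5)
        from histohet import upper_tercile_flag

        g = assign_risk_groups(c, upper_tercile_flag(c["cp2"]))
        assert sum(g.counts().values()) == 368

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            assign_risk_groups(pd.DataFrame({"mitotic_index": [1.0]}), [True])

    def test_km_curves_ordered_when_all_factors_harmful(self):
        # at n=2000 with true HRs 1.71/2.20/1.46 the three risk groups'
        # survival curves should be correctly ordered at event times
        from histohet import km_estimate, upper_tercile_flag

        ordered = 0
        n_seeds = 20
        for s in range(n_seeds):
            c = generate_cohort(CohortSpec(n=2000), 300 + s)
            g = assign_risk_groups(c, upper_tercile_flag(c["cp2"]))
            kms = {}
            for lab in RISK_GROUP_LABELS:
                sel = g.group == lab
                kms[lab] = km_estimate(c.loc[sel, "dfs_time"], c.loc[sel, "event"])
            grid = np.quantile(c.loc[c.event == 1, "dfs_time"], np.linspace(0.05, 0.9, 30))
            s0, s12, s3 = (kms[lab](grid) for lab in RISK_GROUP_LABELS)
            ordered += bool(np.all(s0 >= s12 - 1e-12) and np.all(s12 >= s3 - 1e-12))
        assert ordered >= int(0.95 * n_seeds)


class TestUnivariateScreen:
    def test_one_row_per_feature_including_constant(self):
        c = generate_cohort(CohortSpec(n=100), 3)
        c["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = univariate_screen(c, ["mitotic_index", "node_pos", "cp2", "flat"])
        assert list(out["feature"]) == ["mitotic_index", "node_pos", "cp2", "flat"]
        assert out.loc[out.feature == "flat", "p"].isna().all()
        assert (out.loc[out.feature == "node_pos", "method"] == "logrank").all()
        assert (out.loc[out.feature == "cp2", "method"] == "cox_wald").all()

    def test_power_on_generating_feature(self):
        hits = 0
        for s in range(50):
            c = generate_cohort(
                CohortSpec(n=500, log_hr={"mitotic_index": 0, "node_pos": np.log(2.0), "cp2": 0}),
                s,
            )
            out = univariate_screen(c, ["node_pos"])
            hits += float(out["p"].iloc[0]) < 0.05
        assert hits >= 45

    def test_null_p_values_approximately_uniform(self):
        ps = []
        spec = CohortSpec(n=80, log_hr={"mitotic_index": 0, "node_pos": 0, "cp2": 0})
        for s in range(200):
            c = generate_cohort(spec, 1000 + s)
            out = univariate_screen(c, ["cp2"])
            ps.append(float(out["p"].iloc[0]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01
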