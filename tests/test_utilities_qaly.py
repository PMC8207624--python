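"""Utility-to-QALY stage: mapping hook, dropout rules, chained
imputation, trapezoidal QALYs, and the random-intercept mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricea.synthetic_trial import TrialConfig, UtilityTrajectory, generate_trial
from nutricea.utilities_qaly import (
    MAX_QALY_5_MONTHS,
    MappingSpec,
    assign_dropout_utility,
    fit_random_intercept_lmm,
    impute_chained,
    map_scores_to_utility,
    pool_rubin,
    qaly_auc,
    qaly_table,
)

VISITS = np.array([0.0, 2.0, 3.0, 5.0])


def traj(values, reason="none", time=None):
    return UtilityTrajectory(VISITS.copy(), np.asarray(values, float), reason, time)


class TestMapping:
    def test_constant_model(self):
        spec = MappingSpec(("global_health",), (0.0,), intercept=0.5)
        assert map_scores_to_utility({"global_health": 57.0}, spec) == 0.5

    def test_boundary_clamp(self):
        spec = MappingSpec(("global_health",), (0.01,), intercept=0.5)
        assert map_scores_to_utility({"global_health": 100.0}, spec) == 1.0

    def test_logit_inverse_hand_computed(self):
        spec = MappingSpec(
            ("global_health", "pain"), (0.02, -0.01), intercept=-0.3, link="logit-inverse"
        )
        eta = -0.3 + 0.02 * 70 - 0.01 * 25
        expected = 1 / (1 + np.exp(-eta))
        got = map_scores_to_utility({"global_health": 70.0, "pain": 25.0}, spec)
        assert got == pytest.approx(expected)

    def test_missing_scale_named(self):
        spec = MappingSpec(("global_health", "pain"), (0.1, 0.1))
        with pytest.raises(KeyError, match="pain"):
            map_scores_to_utility({"global_health": 50.0}, spec)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            MappingSpec(("a", "b"), (0.1,))


class TestDropoutRule:
    def test_hospitalization_at_month_one(self):
        t = traj([0.7, np.nan, np.nan, np.nan], "hospitalization", 1.0)
        out = assign_dropout_utility(t, end_of_rt_month=2.0)
        np.testing.assert_allclose(out.values, [0.7, 0.35, 0.30, 0.30])

    def test_death_zeroes_from_death_time(self):
        t = traj([0.7, 0.6, np.nan, np.nan], "death", 3.0)
        out = assign_dropout_utility(t)
        np.testing.assert_allclose(out.values, [0.7, 0.6, 0.0, 0.0])
        # segments: (0.7+0.6)/2*2 + (0.6+0)/2*1 + 0 = 1.6 month-utils
        assert qaly_auc(out) == pytest.approx(1.6 / 12)

    def test_no_dropout_identity(self):
        t = traj([0.8, 0.7, 0.7, 0.8])
        out = assign_dropout_utility(t)
        np.testing.assert_allclose(out.values, t.values)

    def test_observed_values_never_overwritten(self):
        t = traj([0.7, 0.55, np.nan, np.nan], "artificial_nutrition", 1.5)
        out = assign_dropout_utility(t)
        assert out.values[1] == 0.55  # observed at month 2 stays
        np.testing.assert_allclose(out.values[2:], [0.30, 0.30])

    def test_dropout_after_last_visit_noop(self):
        t = traj([0.7, 0.6, 0.6, 0.7], "hospitalization", 6.0)
        out = assign_dropout_utility(t)
        np.testing.assert_allclose(out.values, t.values)


class TestQalyAuc:
    def test_maximum_attainable(self):
        assert qaly_auc(traj([1, 1, 1, 1])) == pytest.approx(5 / 12, abs=1e-12)
        assert MAX_QALY_5_MONTHS == pytest.approx(0.417, abs=5e-4)

    def test_zero_utilities(self):
        assert qaly_auc(traj([0, 0, 0, 0])) == 0.0

    def test_hand_trapezoid(self):
        assert qaly_auc(traj([0.8, 0.6, 0.6, 0.8])) == pytest.approx(
            (1.4 + 0.6 + 1.4) / 12
        )

    def test_missing_raises(self):
        with pytest.raises(ValueError, match="impute"):
            qaly_auc(traj([0.8, np.nan, 0.6, 0.8]))

    @given(
        u=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        bump=st.floats(0.0, 0.5),
        idx=st.integers(0, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_utility(self, u, bump, idx):
        base = qaly_auc(traj(u))
        raised = list(u)
        raised[idx] = min(1.0, raised[idx] + bump)
        assert qaly_auc(traj(raised)) >= base - 1e-12

    @given(
        u=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_invariant_to_interpolated_point(self, u, frac):
        base = qaly_auc(traj(u))
        # insert a linearly interpolated point inside the month 0-2 segment
        t_new = 2.0 * frac
        u_new = u[0] + (u[1] - u[0]) * frac
        t2 = UtilityTrajectory(
            np.array([0.0, t_new, 2.0, 3.0, 5.0]),
            np.array([u[0], u_new, u[1], u[2], u[3]]),
        )
        assert qaly_auc(t2) == pytest.approx(base, abs=1e-12)


def _small_trial(seed=3, n=60, mcar=0.0):
    cfg = TrialConfig(n_treatment=n, n_control=n, seed=seed, mcar_missing_rate=mcar)
    patients = generate_trial(cfg)
    for p in patients:
        p.utilities = assign_dropout_utility(p.utilities, cfg.end_of_rt_month)
    return cfg, patients


class TestImputation:
    def test_complete_data_identity(self):
        cfg = TrialConfig(
            n_treatment=20,
            n_control=20,
            seed=1,
            mcar_missing_rate=0.0,
            dropout_hazards={
                "treatment": {"hospitalization": 0, "artificial_nutrition": 0, "lost": 0},
                "control": {"hospitalization": 0, "artificial_nutrition": 0, "lost": 0},
            },
        )
        patients = generate_trial(cfg)
        alive = [p for p in patients if p.utilities.dropout_reason == "none"]
        imps = impute_chained(alive, m=3, seed=0)
        assert len(imps) == 3
        for trajs in imps:
            for p, t in zip(alive, trajs):
                np.testing.assert_allclose(t.values, p.utilities.values)

    def test_observed_values_preserved_and_in_range(self):
        _, patients = _small_trial(mcar=0.2)
        imps = impute_chained(patients, m=3, seed=11, n_iter=4)
        for trajs in imps:
            for p, t in zip(patients, trajs):
                assert not np.isnan(t.values).any()
                obs = ~np.isnan(p.utilities.values)
                np.testing.assert_allclose(t.values[obs], p.utilities.values[obs])
                assert np.all((t.values >= 0) & (t.values <= 1))

    def test_mcar_pooled_means_recover_complete_data(self):
        """With 20% MCAR missingness the pooled per-visit means stay
        within 3 SE of the complete-data means."""
        cfg = TrialConfig(n_treatment=150, n_control=150, seed=21, mcar_missing_rate=0.0)
        complete = generate_trial(cfg)
        for p in complete:
            p.utilities = assign_dropout_utility(p.utilities, cfg.end_of_rt_month)
        full = np.array(
            [p.utilities.values for p in complete if p.utilities.complete]
        )
        # punch MCAR holes into non-baseline visits of the complete subset
        rng = np.random.default_rng(5)
        holed = [p for p in complete if p.utilities.complete]
        mask = rng.random((len(holed), 4)) < 0.2
        mask[:, 0] = False
        for i, p in enumerate(holed):
            vals = p.utilities.values.copy()
            vals[mask[i]] = np.nan
            p.utilities.values = vals
        imps = impute_chained(holed, m=5, seed=17, n_iter=5)
        pooled = np.mean([[t.values for t in trajs] for trajs in imps], axis=(0, 1))
        se = full.std(axis=0, ddof=1) / np.sqrt(full.shape[0])
        assert np.all(np.abs(pooled - full.mean(axis=0)) < 3 * se)

    def test_all_missing_visit_errors(self):
        _, patients = _small_trial(n=15)
        for p in patients:
            p.utilities.values[2] = np.nan
        with pytest.raises(ValueError, match="unidentifiable"):
            impute_chained(patients, m=2, seed=0)

    def test_m_below_two_errors(self):
        _, patients = _small_trial(n=15)
        with pytest.raises(ValueError, match="m must be"):
            impute_chained(patients, m=1, seed=0)

    def test_deterministic_given_seed(self):
        _, patients = _small_trial(mcar=0.15)
        a = impute_chained(patients, m=2, seed=9, n_iter=3)
        b = impute_chained(patients, m=2, seed=9, n_iter=3)
        for ta, tb in zip(a, b):
            for x, y in zip(ta, tb):
                np.testing.assert_array_equal(x.values, y.values)

    def test_qaly_table_pools_across_imputations(self):
        _, patients = _small_trial(mcar=0.1, n=25)
        imps = impute_chained(patients, m=4, seed=2, n_iter=3)
        qdf = qaly_table(imps, patients)
        per_imp = np.array([[qaly_auc(t) for t in trajs] for trajs in imps])
        np.testing.assert_allclose(qdf["qaly"].to_numpy(), per_imp.mean(axis=0))
        assert (qdf["n_imputations"] == 4).all()


class TestRubinPooling:
    def test_pooled_estimate_is_mean_and_variance_decomposes(self):
        est, var = [0.1, 0.2, 0.3], [0.01, 0.01, 0.01]
        out = pool_rubin(est, var)
        assert out["estimate"] == pytest.approx(0.2)
        b = np.var(est, ddof=1)
        assert out["variance"] == pytest.approx(0.01 + (1 + 1 / 3) * b)


def _lmm_long(n_per_arm, means, sd_b, sd_e, rng):
    rows = []
    for arm, shift in (("treatment", means["treatment"]), ("control", means["control"])):
        for i in range(n_per_arm):
            b = rng.normal(0, sd_b)
            for j, v in enumerate(VISITS):
                rows.append(
                    {
                        "id": f"{arm}{i}",
                        "arm": arm,
                        "visit_month": v,
                        "utility": shift[j] + b + rng.normal(0, sd_e),
                    }
                )
    return pd.DataFrame(rows)


class TestLMM:
    def test_noise_free_arm_effect_exact(self, rng):
        d = 0.07
        means = {"control": np.full(4, 0.6), "treatment": np.full(4, 0.6 + d)}
        df = _lmm_long(12, means, 0.0, 0.0, rng)
        fit = fit_random_intercept_lmm(df)
        arm_key = [k for k in fit["fixed_effects"] if "arm" in k and ":" not in k][0]
        assert fit["fixed_effects"][arm_key] == pytest.approx(d, abs=1e-6)
        inter = [v for k, v in fit["fixed_effects"].items() if ":" in k]
        np.testing.assert_allclose(inter, 0.0, atol=1e-6)

    def test_variance_components_recovered(self, rng):
        sd_b, sd_e = 0.10, 0.05
        means = {"control": np.full(4, 0.6), "treatment": np.full(4, 0.63)}
        ests_b, ests_e = [], []
        for _ in range(8):
            df = _lmm_long(100, means, sd_b, sd_e, rng)
            fit = fit_random_intercept_lmm(df)
            ests_b.append(fit["random_intercept_var"])
            ests_e.append(fit["residual_var"])
        # mean of REML estimates close to truth (replicate SE is tiny here)
        assert np.mean(ests_b) == pytest.approx(sd_b**2, rel=0.15)
        assert np.mean(ests_e) == pytest.approx(sd_e**2, rel=0.10)

    def test_interaction_lrt_null_rejection_rate(self, rng):
        """No true arm-by-time interaction: the 5%-level LRT rejects in
        about 5% of simulated trials (binomial 95% band)."""
        means = {"control": np.array([0.6, 0.55, 0.57, 0.6]),
                 "treatment": np.array([0.63, 0.58, 0.60, 0.63])}
        n_sims, rejections = 120, 0
        for _ in range(n_sims):
            df = _lmm_long(40, means, 0.08, 0.05, rng)
            fit = fit_random_intercept_lmm(df)
            rejections += fit["lrt_interaction"]["p_value"] < 0.05
        rate = rejections / n_sims
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < band + 1e-9

    def test_single_arm_errors(self, rng):
        means = {"control": np.full(4, 0.6), "treatment": np.full(4, 0.6)}
        df = _lmm_long(10, means, 0.05, 0.05, rng)
        with pytest.raises(ValueError, match="both arms"):
            fit_random_intercept_lmm(df[df["arm"] == "control"])

    def test_mixed_loglik_not_below_ols(self, rng):
        means = {"control": np.full(4, 0.6), "treatment": np.full(4, 0.65)}
        df = _lmm_long(40, means, 0.1, 0.05, rng)
        fit = fit_random_intercept_lmm(df)
        import statsmodels.formula.api as smf

        df2 = df.copy()
        df2["visit"] = pd.Categorical(df2["visit_month"])
        ols = smf.ols("utility ~ C(arm) * C(visit)", df2).fit()
        # the mixed model nests OLS (zero random-intercept variance)
        assert fit["loglike_ml"] >= ols.llf - 1e-6
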