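"""Survival stage: product-limit estimator vs brute force and lifelines,
reverse-KM follow-up, RMST vs closed forms, the Fleming–Harrington
family vs the textbook log-rank, max-combo behaviour, and the discounted
life-years-gained table."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from conftest import make_small_survival
from nutricea.survival import (
    DAYS_PER_YEAR,
    SurvivalCurve,
    discounted_lyg_icer,
    km_fit,
    maxcombo,
    reverse_km_median,
    rmst,
    rmst_difference,
    weighted_logrank,
)


def brute_force_km(times, events, t):
    """S(t) as the exhaustive product over event times <= t."""
    s = 1.0
    for tt in sorted(set(np.asarray(times)[np.asarray(events) == 1])):
        if tt > t:
            break
        n = sum(x >= tt for x in times)
        d = sum((x == tt) and e for x, e in zip(times, events))
        s *= 1 - d / n
    return s


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        c = km_fit([10.0, 20.0, 30.0], [0, 0, 0])
        assert c.event_times.size == 0
        assert np.all(c.evaluate([0.0, 15.0, 30.0]) == 1.0)

    def test_all_events_hand_product(self):
        c = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_fit([], [])

    def test_matches_brute_force_on_random_small_data(self, rng):
        for _ in range(50):
            t, e, _ = make_small_survival(rng, n_per_arm=10)
            c = km_fit(t, e)
            for tt in np.linspace(0, t.max(), 7):
                assert c.evaluate(tt) == pytest.approx(brute_force_km(t, e, tt))

    def test_matches_lifelines(self, rng):
        t, e, _ = make_small_survival(rng, n_per_arm=40)
        c = km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        np.testing.assert_allclose(
            c.survival,
            kmf.survival_function_at_times(c.event_times).to_numpy(),
            atol=1e-10,
        )
        assert np.all(c.greenwood_var >= 0)

    def test_tied_events_before_censorings(self):
        # one event and one censoring at t=5: both at risk at 5
        c = km_fit([5.0, 5.0, 8.0], [1, 0, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])
        assert c.at_risk[0] == 3


class TestReverseKM:
    def test_point_mass_all_censored(self):
        out = reverse_km_median([2200.0] * 12, [0] * 12)
        assert out["median_days"] == 2200.0

    def test_no_censoring_undefined(self):
        out = reverse_km_median([10.0, 20.0, 30.0], [1, 1, 1])
        assert not out["defined"]
        assert np.isnan(out["median_days"])

    def test_staggered_accrual_bounds(self, default_trial):
        t = [p.survival_days for p in default_trial]
        e = [p.event for p in default_trial]
        out = reverse_km_median(t, e)
        assert 1343 <= out["median_days"] <= 2742  # potential follow-up range
        assert out["ci_low_days"] <= out["median_days"] <= out["ci_high_days"]


class TestRmst:
    def test_flat_curve_equals_tau(self):
        c = km_fit([500.0, 600.0], [0, 0])
        out = rmst(c, 365.25)
        assert out["rmst_years"] == pytest.approx(1.0)
        assert out["variance_years2"] == 0.0

    def test_hand_step_area(self):
        # S = 1 on [0,100), 0.5 on [100,365): one death among two at t=100
        c = km_fit([100.0, 365.0], [1, 0])
        out = rmst(c, 365.0)
        assert out["rmst_years"] * DAYS_PER_YEAR == pytest.approx(100 + 0.5 * 265)

    def test_exponential_closed_form(self, rng):
        h = 1 / 700.0
        n = 2000
        t = rng.exponential(1 / h, n)
        cens = np.full(n, 1500.0)
        times, events = np.minimum(t, cens), (t <= cens).astype(int)
        c = km_fit(times, events)
        tau = 1200.0
        out = rmst(c, tau)
        truth = (1 - np.exp(-h * tau)) / h / DAYS_PER_YEAR
        assert abs(out["rmst_years"] - truth) < 3 * np.sqrt(out["variance_years2"])

    def test_monotone_and_bounded(self, rng):
        t, e, _ = make_small_survival(rng, n_per_arm=30)
        c = km_fit(t, e)
        taus = np.linspace(10, c.max_time, 8)
        vals = [rmst(c, x)["rmst_years"] for x in taus]
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all(np.asarray(vals) <= taus / DAYS_PER_YEAR + 1e-12)

    def test_tau_beyond_followup_errors(self):
        c = km_fit([100.0, 200.0], [1, 1])
        with pytest.raises(ValueError, match="exceeds"):
            rmst(c, 300.0)

    def test_difference_z_test_symmetric(self, rng):
        t, e, _ = make_small_survival(rng, n_per_arm=40)
        c = km_fit(t, e)
        out = rmst_difference(c, c, 300.0)
        assert out["difference_years"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)


class TestWeightedLogrank:
    def test_pq00_equals_lifelines_logrank(self, rng):
        for _ in range(30):
            t, e, arm = make_small_survival(rng, n_per_arm=12)
            ours = weighted_logrank(t, e, arm, 0, 0)
            ll = logrank_test(
                t[arm == "treatment"], t[arm == "control"],
                e[arm == "treatment"], e[arm == "control"],
            )
            assert ours.z**2 == pytest.approx(ll.test_statistic, rel=1e-6)
            assert ours.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_identical_arms_zero_statistic(self):
        t = np.array([50.0, 120.0, 300.0, 50.0, 120.0, 300.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        arm = np.array(["treatment"] * 3 + ["control"] * 3)
        out = weighted_logrank(t, e, arm, 0, 2)
        assert out.statistic == pytest.approx(0.0, abs=1e-12)

    def test_one_arm_errors(self):
        with pytest.raises(ValueError, match="both arms"):
            weighted_logrank([1.0, 2.0], [1, 1], ["treatment", "treatment"])

    def test_late_weight_power_ordering(self):
        """Late-separation design: the (0,2) late-emphasis test rejects
        more often than the plain log-rank over replicates."""
        from nutricea.synthetic_trial import TrialConfig, generate_trial

        reps, rej_late, rej_plain = 60, 0, 0
        for s in range(reps):
            cfg = TrialConfig(n_treatment=80, n_control=80, seed=3000 + s)
            pts = generate_trial(cfg)
            t = np.array([p.survival_days for p in pts])
            e = np.array([int(p.event) for p in pts])
            a = np.array([p.arm for p in pts])
            rej_late += weighted_logrank(t, e, a, 0, 2).p_value < 0.05
            rej_plain += weighted_logrank(t, e, a, 0, 0).p_value < 0.05
        assert rej_late > rej_plain

    def test_variance_positive_with_events(self, rng):
        t, e, arm = make_small_survival(rng, n_per_arm=15)
        out = weighted_logrank(t, e, arm, 0, 0)
        assert out.variance > 0
        assert out.z == pytest.approx(out.statistic / np.sqrt(out.variance))


class TestMaxCombo:
    def test_statistic_is_max_component_z(self, rng):
        t, e, arm = make_small_survival(rng, n_per_arm=25)
        out = maxcombo(t, e, arm, n_perm=1000, seed=1)
        zs = [abs(weighted_logrank(t, e, arm, p, q).z) for p, q in out["combos"]]
        assert out["statistic"] == pytest.approx(max(zs), rel=1e-9)
        assert 0.0 < out["p_value"] <= 1.0
        assert out["mc_se"] > 0

    def test_identical_arms_p_near_one(self):
        t = np.tile([30.0, 90.0, 200.0, 400.0, 800.0], 2)
        e = np.tile([1, 1, 1, 0, 1], 2)
        arm = np.array(["treatment"] * 5 + ["control"] * 5)
        out = maxcombo(t, e, arm, n_perm=1000, seed=2)
        assert out["p_value"] > 0.5

    def test_single_combo_matches_logrank_permutation(self, rng):
        t, e, arm = make_small_survival(rng, n_per_arm=20)
        out = maxcombo(t, e, arm, combos=((0, 0),), n_perm=4000, seed=3)
        # independent permutation reference for the plain log-rank |z|
        z_obs = abs(weighted_logrank(t, e, arm, 0, 0).z)
        rng2 = np.random.default_rng(99)
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng2.permutation(arm)
            count += abs(weighted_logrank(t, e, perm, 0, 0).z) >= z_obs - 1e-12
        p_ref = (1 + count) / (1 + n_perm)
        se = np.sqrt(p_ref * (1 - p_ref) / n_perm)
        assert abs(out["p_value"] - p_ref) < 4 * se + 1e-9

    def test_deterministic(self, rng):
        t, e, arm = make_small_survival(rng, n_per_arm=15)
        a = maxcombo(t, e, arm, n_perm=1000, seed=5)
        b = maxcombo(t, e, arm, n_perm=1000, seed=5)
        assert a["p_value"] == b["p_value"]


class TestDiscountedLyg:
    @staticmethod
    def _flat_vs_drop():
        # treatment: no events to 3y; control: half die at day 1
        ct = km_fit([3 * DAYS_PER_YEAR] * 10, [0] * 10)
        cc = km_fit([1.0] * 5 + [3 * DAYS_PER_YEAR] * 5, [1] * 5 + [0] * 5)
        return ct, cc

    def test_year1_undiscounted_matches_hand_icer(self):
        ct, cc = self._flat_vs_drop()
        tab = discounted_lyg_icer(ct, cc, delta_cost=-8.96, taus_years=(1,), discount_rate=0.035)
        row = tab.iloc[0]
        # year-1 LYG is undiscounted, so ICER = dC / dRMST exactly
        assert row["discounted_lyg"] == pytest.approx(row["difference_years"])
        assert row["icer_eur_per_lyg"] == pytest.approx(-8.96 / row["difference_years"])

    def test_printed_year1_arithmetic(self):
        from nutricea.cea import icer

        assert icer(-8.96, -0.022)["icer"] == pytest.approx(407.27, abs=0.01)

    def test_zero_difference_flagged(self):
        c = km_fit([800.0] * 8, [0] * 8)
        tab = discounted_lyg_icer(c, c, delta_cost=-8.96, taus_years=(1, 2), discount_rate=0.035)
        assert not tab["icer_defined"].any()

    def test_discounting_against_quadrature(self):
        """Discounted LYG at 6 years matches direct numerical integration
        of the configured survival difference with annual discounting."""
        from scipy import integrate

        from nutricea.synthetic_trial import TrialConfig, generate_trial, true_survival

        cfg = TrialConfig(n_treatment=3000, n_control=3000, seed=11)
        pts = generate_trial(cfg)
        curves = {}
        for arm in ("treatment", "control"):
            sel = [p for p in pts if p.arm == arm]
            curves[arm] = km_fit([p.survival_days for p in sel], [p.event for p in sel])
        r = 0.035
        tab = discounted_lyg_icer(
            curves["treatment"], curves["control"], -8.96, taus_years=(3,), discount_rate=r
        )

        def integrand(t_days):
            year = int(t_days // DAYS_PER_YEAR)
            disc = (1 + r) ** (-year)
            return (
                true_survival(cfg, "treatment", t_days) - true_survival(cfg, "control", t_days)
            ) * disc

        truth, _ = integrate.quad(integrand, 0, 3 * DAYS_PER_YEAR, limit=500)
        truth /= DAYS_PER_YEAR
        assert tab["discounted_lyg"].iloc[0] == pytest.approx(truth, abs=0.03)
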