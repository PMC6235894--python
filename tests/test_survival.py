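import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from crossig.io import ClinicalTable
from crossig.survival import (
    cox_fit,
    cox_score_chi2,
    km_fit,
    logrank,
    subgroup_survival,
)


class TestKaplanMeier:
    def test_three_event_hand_oracle(self):
        km = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival_at(0.5) == pytest.approx(1.0)
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = km_fit([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km.survival == 1.0).all()

    def test_no_censoring_matches_empirical_survivor(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 40)
        km = km_fit(t, np.ones(40, dtype=int))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_ordered_event_identity(self):
        """Without ties/censoring S at the k-th event time is (n-k)/n."""
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        km = km_fit(t, np.ones(5, dtype=int))
        for k, tk in enumerate(sorted(t), start=1):
            assert km.survival_at(tk) == pytest.approx((5 - k) / 5)

    def test_step_function_invariants(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3, 50).round(1)  # forces ties
        e = rng.integers(0, 2, 50)
        km = km_fit(t, e)
        assert km.survival[0] == 1.0 and km.timeline[0] == 0.0
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            km_fit([], [])
        with pytest.raises(ValueError):
            km_fit([-1.0], [1])
        with pytest.raises(ValueError):
            km_fit([1.0], [2])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        chi2, p = logrank(t + t, e + e, [0] * 4 + [1] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_riskset_enumeration_oracle(self):
        """group0 events at (1,2), group1 at (3,4): hand-enumerated O-E/V."""
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        group = np.array([0, 0, 1, 1])
        # t=1: n=4,n1=2,e=2/4; t=2: n=3,n1=2,e=2/3; t=3: n=2,n1=2,e=1; t=4: n=1,e=1
        o_minus_e = (0 - 0.5) + (0 - 2 / 3) + (1 - 1.0) + (1 - 1.0)
        v = (0.5 * 0.5) + (2 / 3 * 1 / 3) + 0.0 + 0.0
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(o_minus_e**2 / v, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 50
            g = rng.integers(0, 2, n)
            t = rng.exponential(10 * (1 + g), n).round(1)
            e = (rng.random(n) < 0.7).astype(int)
            if e.sum() == 0:
                continue
            chi2, p = logrank(t, e, g)
            ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_group_swap_and_time_rescale_invariance(self):
        rng = np.random.default_rng(3)
        n = 30
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        g = rng.integers(0, 2, n)
        g[:2] = [0, 1]
        chi2, p = logrank(t, e, g)
        chi2s, ps = logrank(t, e, 1 - g)
        chi2r, pr = logrank(7.3 * t, e, g)
        assert chi2 == pytest.approx(chi2s, abs=1e-12)
        assert chi2 == pytest.approx(chi2r, abs=1e-12)

    def test_zero_events_error(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank([1.0, 2.0], [0, 0], [0, 1])

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank([1.0, 2.0], [1, 1], [1, 1])


class TestCox:
    def _sim(self, seed, n=300, hr=2.0, censor_scale=None):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        lam = 0.05 * hr**x
        t = rng.exponential(1 / lam)
        if censor_scale:
            c = rng.exponential(censor_scale, n)
            return np.minimum(t, c), (t <= c).astype(int), x
        return t, np.ones(n, dtype=int), x

    def test_recovers_true_hazard_ratio(self):
        t, e, x = self._sim(0, n=2000)
        df = pd.DataFrame({"os_months": t, "os_event": e, "x": x})
        fit = cox_fit(df, ["x"])
        assert fit.hr("x") == pytest.approx(2.0, rel=0.15)
        lo, hi = fit.summary.loc["x", ["ci_low", "ci_high"]]
        assert lo < fit.hr("x") < hi and lo > 0

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(5)
        t, e, _ = self._sim(5, n=800, hr=1.0)
        df = pd.DataFrame({"os_months": t, "os_event": e, "x": rng.normal(size=800)})
        fit = cox_fit(df, ["x"])
        beta = fit.summary.loc["x", "beta"]
        se = (np.log(fit.summary.loc["x", "ci_high"]) - np.log(fit.hr("x"))) / 1.96
        assert abs(beta) < 3 * se

    def test_score_test_equals_logrank_untied(self):
        """Classical identity for a binary covariate with no tied events."""
        for seed in range(4):
            t, e, x = self._sim(seed, n=120, censor_scale=30.0)
            assert len(np.unique(t[e == 1])) == e.sum()  # untied
            chi2, _ = logrank(t, e, x)
            assert cox_score_chi2(t, e, x) == pytest.approx(chi2, abs=1e-6)

    def test_listwise_deletion_reported(self, clinical_table):
        df = clinical_table.data.copy()
        df.loc[df.index[:5], "tumor_size"] = np.nan
        df["os_event"] = 1
        fit = cox_fit(ClinicalTable(data=df), ["tumor_size"])
        assert fit.n_dropped == 5 and fit.n == len(df) - 5

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"os_months": [1.0, 2, 3, 4], "os_event": [1, 1, 1, 1], "x": [1.0] * 4}
        )
        with pytest.raises(ValueError, match="constant covariate"):
            cox_fit(df, ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"os_months": [1.0, 2.0], "os_event": [0, 0], "x": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["x"])


class TestSubgroup:
    def _clin(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        call = rng.integers(0, 2, n)
        lam = 0.05 * 3.0**call
        t = rng.exponential(1 / lam)
        data = pd.DataFrame(
            {
                "os_months": t,
                "os_event": np.ones(n, dtype=int),
                "stage": rng.choice(["I", "II", "III"], n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        calls = pd.Series(np.where(call == 1, "ASS_present", "ASS_absent"),
                          index=data.index)
        return ClinicalTable(data=data), calls

    def test_within_early_stage_effect_detected(self):
        clin, calls = self._clin()
        res = subgroup_survival(clin, calls, strata=["I", "II"])
        assert res["logrank"]["p"] < 0.05

    def test_single_patient_stratum_no_test(self):
        clin, calls = self._clin(n=200)
        clin.data.loc[clin.data.index[0], "stage"] = "IV"
        res = subgroup_survival(clin, calls, strata=["IV"])
        assert res["logrank"] is None

    def test_single_stratum_equals_pooled(self):
        clin, calls = self._clin(seed=1)
        clin.data["stage"] = "II"
        pooled = subgroup_survival(clin, calls, strata=None)
        sub = subgroup_survival(clin, calls, strata=["II"])
        assert pooled["logrank"]["chi2"] == pytest.approx(sub["logrank"]["chi2"])

    def test_one_call_group_empty_skipped(self):
        clin, calls = self._clin(seed=2)
        calls[:] = "ASS_present"
        res = subgroup_survival(clin, calls, strata=["I", "II"])
        assert res["logrank"] is None
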