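import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import endotdm as e
from endotdm.errors import CoverageError, DataError, DomainError, FitError
from endotdm.survival import km_from_counts

DFS_LOW = e.LognormalCurve.from_intercept_log_scale(3.28, 0.61)


class TestLognormalSurvival:
    def test_median(self):
        assert e.lognormal_survival(DFS_LOW, math.exp(3.28)) == pytest.approx(0.5)

    def test_at_zero(self):
        assert e.lognormal_survival(DFS_LOW, 0.0) == 1.0

    def test_value_against_normal_cdf(self):
        # independent high-precision evaluation of S(15)
        z = (math.log(15) - 3.28) / math.exp(0.61)
        expected = 1.0 - stats.norm.cdf(z)
        assert e.lognormal_survival(DFS_LOW, 15.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.622, abs=5e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            e.lognormal_survival(DFS_LOW, -1.0)

    @given(st.floats(0.01, 80), st.floats(0.01, 80))
    def test_monotone_decreasing(self, t1, t2):
        lo, hi = sorted([t1, t2])
        assert (e.lognormal_survival(DFS_LOW, lo)
                >= e.lognormal_survival(DFS_LOW, hi))


class TestHazardRatio:
    def test_identity_at_one(self):
        assert e.apply_hazard_ratio(0.5, 1.0) == 0.5

    def test_boundary_one(self):
        assert e.apply_hazard_ratio(1.0, 0.3) == 1.0

    def test_table_value(self):
        assert e.apply_hazard_ratio(0.5, 0.74) == pytest.approx(
            math.exp(0.74 * math.log(0.5)))

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(DomainError):
            e.apply_hazard_ratio(0.5, 0.0)

    @given(s=st.floats(0.01, 0.99), hr1=st.floats(0.1, 3), hr2=st.floats(0.1, 3))
    def test_monotone_decreasing_in_hr(self, s, hr1, hr2):
        lo, hi = sorted([hr1, hr2])
        assert e.apply_hazard_ratio(s, lo) >= e.apply_hazard_ratio(s, hi)


class TestBackgroundSurvival:
    def test_zero_horizon(self, life_table):
        assert e.background_survival(life_table, 53, 0.0) == 1.0

    def test_immortal_table(self, flat_life_table):
        assert e.background_survival(flat_life_table, 53, 30.0) == 1.0

    def test_constant_hazard_closed_form(self):
        lt = e.LifeTable(ages=np.arange(50, 60), qx=np.full(10, 0.1))
        assert e.background_survival(lt, 50, 2.0) == pytest.approx(0.81)
        # fractional years use constant hazard within the year
        assert e.background_survival(lt, 50, 0.5) == pytest.approx(
            math.exp(0.5 * math.log(0.9)))

    def test_coverage_error(self, life_table):
        with pytest.raises(CoverageError):
            e.background_survival(life_table, 53, 60.0)

    def test_overall_survival_product(self, life_table, flat_life_table):
        bc = e.LognormalCurve.from_intercept_log_scale(3.71, 0.40)
        t = 15.0
        s_bc = e.lognormal_survival(bc, t)
        s_bg = e.background_survival(life_table, 53, t)
        assert e.overall_survival(bc, life_table, 53, t) == pytest.approx(
            s_bc * s_bg)
        assert e.overall_survival(bc, flat_life_table, 53, t) == pytest.approx(s_bc)
        # dominated by both marginal survivals
        assert e.overall_survival(bc, life_table, 53, t) <= min(s_bc, s_bg)


class TestSwitchedSurvival:
    def test_switch_at_zero_is_high_curve(self):
        sc = e.SwitchCurve(DFS_LOW, hr=0.74, switch_time=0.0)
        t = np.linspace(0.1, 40, 50)
        np.testing.assert_allclose(
            e.switched_survival(sc, t),
            e.lognormal_survival(DFS_LOW, t) ** 0.74)

    def test_never_switch_is_low_curve(self):
        sc = e.SwitchCurve(DFS_LOW, hr=0.74, switch_time=math.inf)
        t = np.linspace(0.0, 40, 50)
        np.testing.assert_allclose(e.switched_survival(sc, t),
                                   e.lognormal_survival(DFS_LOW, t))

    def test_continuity_at_switch(self):
        sc = e.SwitchCurve(DFS_LOW, hr=0.74, switch_time=0.25)
        below = e.switched_survival(sc, 0.25 - 1e-9)
        at = e.switched_survival(sc, 0.25)
        above = e.switched_survival(sc, 0.25 + 1e-9)
        assert below == pytest.approx(at, rel=1e-6)
        assert above == pytest.approx(at, rel=1e-6)

    @given(st.floats(0.05, 45))
    def test_bracketed_by_pure_curves(self, t):
        sc = e.SwitchCurve(DFS_LOW, hr=0.74, switch_time=0.5)
        s = e.switched_survival(sc, t)
        lo = e.lognormal_survival(DFS_LOW, t)
        assert lo - 1e-12 <= s <= lo ** 0.74 + 1e-12


class TestLifeTableIO:
    def test_csv_roundtrip(self, tmp_path, life_table):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        again = e.LifeTable.from_csv(path)
        np.testing.assert_array_equal(again.ages, life_table.ages)
        np.testing.assert_allclose(again.qx, life_table.qx)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("edad,qx\n50,0.1\n")
        with pytest.raises(DataError):
            e.LifeTable.from_csv(path)

    def test_invalid_qx_rejected(self):
        with pytest.raises(DataError):
            e.LifeTable(ages=np.array([50, 51]), qx=np.array([0.5, 1.0]))


class TestKMReconstruction:
    def test_hand_arithmetic(self):
        km = e.KMDataset(times=np.array([0.0, 1.0, 2.0]),
                         survival=np.array([1.0, 0.9, 0.8]),
                         n_risk=np.array([100.0, 90.0, 80.0]))
        counts = e.reconstruct_event_counts(km)
        assert list(counts["events"]) == [10, 10]
        assert list(counts["censored"]) == [0, 0]

    def test_flat_survival_all_censorings(self):
        km = e.KMDataset(times=np.array([0.0, 1.0, 2.0]),
                         survival=np.array([1.0, 1.0, 1.0]),
                         n_risk=np.array([50.0, 40.0, 30.0]))
        counts = e.reconstruct_event_counts(km)
        assert list(counts["events"]) == [0, 0]
        assert list(counts["censored"]) == [10, 10]

    def test_increasing_survival_rejected(self):
        with pytest.raises(DataError):
            e.KMDataset(times=np.array([0.0, 1.0]),
                        survival=np.array([1.0, 1.1]),
                        n_risk=np.array([10.0, 10.0]))

    def test_roundtrip_within_one_patient(self):
        rng = np.random.default_rng(11)
        t = np.sort(np.exp(rng.normal(1.0, 0.8, 400)))
        bounds = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
        surv, n_risk = [1.0], [400.0]
        alive = np.ones_like(t, dtype=bool)
        for b in bounds[1:]:
            alive = t > b
            n_risk.append(alive.sum())
            surv.append(alive.mean())
        km = e.KMDataset(times=bounds, survival=np.array(surv),
                         n_risk=np.array(n_risk))
        counts = e.reconstruct_event_counts(km)
        s_back = km_from_counts(counts)
        np.testing.assert_allclose(s_back, surv, atol=1.0 / 400 + 1e-12)


class TestParametricFitting:
    def test_lognormal_recovery_within_3se(self):
        rng = np.random.default_rng(7)
        times = np.exp(rng.normal(3.28, math.exp(0.61), 5000))
        fit = e.fit_parametric(times, "lognormal")
        assert abs(fit.params["mu"] - 3.28) < 3 * fit.se("mu_")
        assert abs(fit.params["log_scale"] - 0.61) < 3 * (
            fit.se("sigma_") / fit.params["sigma"])
        # closed-form MLE of a lognormal: mean/sd of the log times
        assert fit.params["mu"] == pytest.approx(np.log(times).mean(), rel=1e-3)
        assert fit.params["sigma"] == pytest.approx(np.log(times).std(), rel=1e-2)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(4.0, 2000)
        fit = e.fit_parametric(times, "exponential")
        assert fit.params["rate"] == pytest.approx(1.0 / times.mean(), rel=1e-6)

    def test_aic_identity_and_covariance_psd(self):
        rng = np.random.default_rng(9)
        times = np.exp(rng.normal(1.0, 0.5, 500))
        fit = e.fit_parametric(times, "weibull")
        k = len(fit.param_names)
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(k * math.log(fit.n)
                                        - 2 * fit.log_likelihood)
        assert np.all(np.linalg.eigvalsh(fit.param_covariance) > -1e-9)

    def test_empty_events_rejected(self):
        with pytest.raises(FitError):
            e.fit_parametric(np.array([]), "lognormal")

    def test_interval_censored_fit_recovers_location(self):
        rng = np.random.default_rng(10)
        t = np.exp(rng.normal(1.2, 0.6, 2000))
        bounds = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 15.0, 40.0])
        surv = [1.0] + [float((t > b).mean()) for b in bounds[1:]]
        n_risk = [2000.0] + [float((t > b).sum()) for b in bounds[1:]]
        km = e.KMDataset(times=bounds, survival=np.array(surv),
                         n_risk=np.array(n_risk))
        fit = e.fit_parametric(e.reconstruct_event_counts(km), "lognormal")
        assert fit.params["mu"] == pytest.approx(1.2, abs=0.1)

    def test_wald_coverage_of_mu(self):
        # 20 independent replicates: the 95% Wald interval for the lognormal
        # location should cover the truth in at least 16 (binomial slack)
        rng = np.random.default_rng(12)
        covered = 0
        for _ in range(20):
            times = np.exp(rng.normal(3.28, math.exp(0.61), 2000))
            fit = e.fit_parametric(times, "lognormal")
            half = 1.96 * fit.se("mu_")
            covered += abs(fit.params["mu"] - 3.28) <= half
        assert covered >= 16


class TestModelSelection:
    def test_lognormal_recovered_among_families(self):
        rng = np.random.default_rng(13)
        times = np.exp(rng.normal(3.28, math.exp(0.61), 4000))
        fits = [e.fit_parametric(times, fam)
                for fam in ("exponential", "weibull", "lognormal",
                            "loglogistic")]
        assert e.select_best(fits).family == "lognormal"

    def test_single_fit(self):
        rng = np.random.default_rng(14)
        fit = e.fit_parametric(rng.exponential(2.0, 100), "exponential")
        assert e.select_best([fit]) is fit

    def test_tie_broken_by_bic(self):
        import dataclasses
        rng = np.random.default_rng(15)
        f1 = e.fit_parametric(rng.exponential(2.0, 100), "exponential")
        f2 = dataclasses.replace(f1, family="weibull", bic=f1.bic - 1.0)
        assert e.select_best([f1, f2]).family == "weibull"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            e.select_best([])
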