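import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import endotdm as e
from endotdm.errors import DomainError
from endotdm.sensitivity import ZERO_QALY_TOL


@pytest.fixture(scope="module")
def small_psa(default_params, table1, life_table):
    draws = e.sample_psa(table1, 800, seed=21)
    result = e.run_psa(default_params, draws, life_table,
                       wtp_grid=[0.0, 20_000.0, 80_000.0])
    return draws, result


@pytest.fixture(scope="module")
def entries(default_params, table1, life_table):
    return e.one_way_dsa(default_params, table1, life_table)


class TestOneWayDSA:
    def test_every_scalar_has_low_and_high(self, entries, table1):
        seen = {(x.parameter, x.direction) for x in entries}
        for name, *_ in e.iter_scalar_ranges(table1):
            assert (name, "low") in seen and (name, "high") in seen

    def test_sorted_by_cost_swing(self, entries):
        by_param = {}
        order = []
        for x in entries:
            if x.parameter not in by_param:
                order.append(x.parameter)
            by_param.setdefault(x.parameter, {})[x.direction] = x
        swings = [abs(by_param[p]["high"].delta_cost
                      - by_param[p]["low"].delta_cost) for p in order]
        assert swings == sorted(swings, reverse=True)

    def test_hr_at_upper_bound_kills_benefit(self, entries):
        x = next(x for x in entries
                 if (x.parameter, x.direction) == ("hr_high_vs_low", "high"))
        assert x.value == 1.0
        assert abs(x.delta_qalys) <= ZERO_QALY_TOL and x.icer is None
        assert x.delta_cost > 0  # testing still costs money

    def test_equal_utilities_kill_benefit(self, entries):
        x = next(x for x in entries
                 if (x.parameter, x.direction) == ("utility_rd", "high"))
        assert x.value == 0.80
        assert abs(x.delta_qalys) <= ZERO_QALY_TOL

    def test_no_conversion_kills_benefit_but_keeps_test_costs(self, entries):
        x = next(x for x in entries if (x.parameter, x.direction)
                 == ("p_high_after_escalation", "low"))
        assert abs(x.delta_qalys) <= ZERO_QALY_TOL
        assert x.delta_cost > 0


class TestSamplePSA:
    def test_deterministic_given_seed(self, table1):
        a = e.sample_psa(table1, 50, seed=3).frame
        b = e.sample_psa(table1, 50, seed=3).frame
        pd.testing.assert_frame_equal(a, b)

    def test_beta_moment(self, table1):
        draws = e.sample_psa(table1, 10_000, seed=4).frame
        mean, n = 14.8 / 19.5, 10_000
        se = math.sqrt(stats.beta.var(14.8, 4.7) / n)
        assert abs(draws["p_high_start"].mean() - mean) < 3 * se

    def test_hr_point_mass_at_one(self, table1):
        draws = e.sample_psa(table1, 10_000, seed=5).frame
        p_clip = stats.norm.sf(0.301 / 0.153)
        se = math.sqrt(p_clip * (1 - p_clip) / 10_000)
        frac = (draws["hr_high_vs_low"] == 1.0).mean()
        assert abs(frac - p_clip) < 3 * se

    def test_proportion_coupling_keeps_escalation_monotone(self, table1):
        draws = e.sample_psa(table1, 10_000, seed=6).frame
        assert (draws["p_high_after_escalation"]
                >= draws["p_high_start"]).all()

    def test_utility_ordering_after_clipping(self, table1):
        draws = e.sample_psa(table1, 5_000, seed=7).frame
        assert (draws["utility_rd"] <= draws["utility_dfs"]).all()
        assert draws["utility_rd_clipped"].mean() > 0.02

    def test_survival_pair_moments_and_correlation_hook(self, table1):
        n = 20_000
        ind = e.sample_psa(table1, n, seed=8).frame
        se_int = (3.37 - 3.20) / 3.92
        assert ind["dfs_low_intercept"].mean() == pytest.approx(
            3.28, abs=3 * se_int / math.sqrt(n))
        r = np.corrcoef(ind["dfs_low_intercept"], ind["dfs_low_log_scale"])[0, 1]
        assert abs(r) < 0.05
        cor = e.sample_psa(table1, n, seed=8, survival_correlation=0.7).frame
        r2 = np.corrcoef(cor["dfs_low_intercept"], cor["dfs_low_log_scale"])[0, 1]
        assert r2 == pytest.approx(0.7, abs=0.05)

    def test_invalid_correlation_matrix_rejected(self, table1):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(DomainError):
            e.sample_psa(table1, 10, seed=1, survival_correlation=bad)


class TestRunPSA:
    def test_seed_reproducibility_end_to_end(self, default_params, table1,
                                             life_table):
        r1 = e.run_psa(default_params, e.sample_psa(table1, 60, seed=9),
                       life_table, [0.0, 20_000.0])
        r2 = e.run_psa(default_params, e.sample_psa(table1, 60, seed=9),
                       life_table, [0.0, 20_000.0])
        np.testing.assert_array_equal(r1.delta_cost, r2.delta_cost)
        pd.testing.assert_frame_equal(r1.ceac, r2.ceac)

    def test_no_benefit_trials_match_clipping_events(self, small_psa):
        draws, result = small_psa
        clipped = (draws.frame["hr_high_vs_low_clipped"]
                   | draws.frame["utility_rd_clipped"]).to_numpy()
        no_benefit = np.abs(result.delta_qalys) <= ZERO_QALY_TOL
        np.testing.assert_array_equal(no_benefit, clipped)

    def test_qaly_gains_never_negative(self, small_psa):
        _, result = small_psa
        assert (result.delta_qalys >= -ZERO_QALY_TOL).all()

    def test_ceac_definitions(self, default_params, table1, life_table,
                              small_psa):
        draws, strict = small_psa
        benefit = result_benefit = strict.delta_qalys > ZERO_QALY_TOL
        # default curve: cost-saving *and* beneficial trials at WTP 0
        expected0 = ((strict.delta_cost < 0) & benefit).mean()
        assert strict.ceac["probability_cost_effective"].iloc[0] == \
            pytest.approx(expected0)
        # plateau deficit equals the no-benefit mass at a high WTP
        plateau = strict.ceac["probability_cost_effective"].iloc[-1]
        assert plateau <= benefit.mean() + 1e-12
        # literal NMB>0 definition counts the cost-saving clipped trials too
        loose = e.run_psa(default_params, draws, life_table, [0.0],
                          require_benefit=False)
        assert (loose.ceac["probability_cost_effective"].iloc[0]
                == pytest.approx((strict.delta_cost < 0).mean()))

    def test_nmb_summary_consistent_with_cloud(self, small_psa):
        _, result = small_psa
        row = result.nmb[result.nmb["wtp"] == 20_000.0].iloc[0]
        nmb = 20_000.0 * result.delta_qalys - result.delta_cost
        assert row["mean"] == pytest.approx(nmb.mean())
        assert row["ci_low"] == pytest.approx(np.percentile(nmb, 2.5))
        assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_empty_wtp_grid_rejected(self, default_params, table1, life_table):
        with pytest.raises(DomainError):
            e.run_psa(default_params, e.sample_psa(table1, 5, seed=1),
                      life_table, [])
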