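"""Wilson intervals, one-way ranges/tornado, PSA sampling and CEAC."""

import numpy as np
import pytest

from tremor_cea.economics import compare, evaluate_all
from tremor_cea.parameters import StrategyName, ValidationError, get_param
from tremor_cea.sensitivity import (
    PsaSpec,
    build_ranges,
    ceac,
    run_dsa,
    run_psa,
    sample_inputs,
    wilson_interval,
)
from tremor_cea.synthetic import degenerate_psa_spec


class TestWilsonInterval:
    def test_zero_successes_low_bound_is_zero(self):
        low, high = wilson_interval(0, 10)
        assert low == 0.0 and 0.0 < high < 1.0

    def test_all_successes_interval_shape(self):
        # at k = n the upper bound is exactly 1 and the lower bound is the
        # shrunk score bound, well below the point estimate
        low, high = wilson_interval(10, 10)
        assert high == 1.0 and 0.5 < low < 1.0

    def test_matches_independent_implementation(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(8, 9), (5, 10), (1, 30), (29, 30)]:
            expected = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert wilson_interval(k, n) == pytest.approx(expected, abs=1e-12)

    def test_contains_point_estimate_and_stays_in_unit_interval(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            low, high = wilson_interval(k, n)
            assert 0.0 <= low <= k / n <= high <= 1.0

    def test_collapses_to_point_estimate_at_large_n(self):
        n = 1_000_000
        low, high = wilson_interval(int(0.3 * n), n)
        assert abs(low - 0.3) < 1e-3 and abs(high - 0.3) < 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilson_interval(0, 0)


class TestBuildRanges:
    def test_pm20_arithmetic_for_costs(self, base):
        ranges = {r.path: r for r in build_ranges(base)}
        r = ranges["shared.medication_annual"]
        assert (r.low, r.high) == (pytest.approx(595.2), pytest.approx(892.8))
        assert r.source == "pm20"

    def test_utility_clipped_to_unit_interval(self, base):
        ranges = {r.path: r for r in build_ranges(base)}
        r = ranges["dbs.u_mt_y2plus"]  # base 0.91
        assert r.low == pytest.approx(0.728)
        assert r.high == 1.0

    def test_trial_proportion_uses_wilson(self, base):
        ranges = {r.path: r for r in build_ranges(base)}
        r = ranges["shared.p_marked"]
        assert (r.low, r.high) == pytest.approx(wilson_interval(8, 9))
        assert r.source == "ci95"

    def test_every_range_brackets_base(self, base):
        for r in build_ranges(base):
            assert r.low <= r.base <= r.high

    def test_override_takes_precedence(self, base):
        ranges = {r.path: r for r in build_ranges(
            base, overrides={"mrgfus.procedure_cost": (10_000.0, 30_000.0)})}
        r = ranges["mrgfus.procedure_cost"]
        assert (r.low, r.high) == (10_000.0, 30_000.0) and r.source == "ci95"


@pytest.fixture(scope="module")
def tornado(base):
    return run_dsa(base)


@pytest.fixture(scope="module")
def psa(base):
    return run_psa(base, PsaSpec(), n_iterations=200, seed=11)


class TestRunDsa:
    def test_zero_influence_parameter_filtered_out(self, base, tornado):
        # year-6+ monitoring never bills inside the 5-year horizon
        from tremor_cea.parameters import set_param
        from tremor_cea.sensitivity import _icer_value

        for df in tornado.values():
            assert "mrgfus.monitoring.6" not in set(df["path"])
        pair = (StrategyName.MRGFUS, StrategyName.NONE)
        lo = _icer_value(set_param(base, "mrgfus.monitoring.6", 0.0), pair)
        hi = _icer_value(set_param(base, "mrgfus.monitoring.6", 1000.0), pair)
        assert lo == hi == _icer_value(base, pair)

    def test_procedure_cost_moves_icer_monotonically(self, base, tornado):
        row = tornado["mrgfus_vs_none"].set_index("path").loc["mrgfus.procedure_cost"]
        base_icer = compare(
            evaluate_all(base)[StrategyName.MRGFUS],
            evaluate_all(base)[StrategyName.NONE],
        ).icer
        assert row["icer_low"] < base_icer < row["icer_high"]

    def test_rows_ordered_by_span(self, tornado):
        for df in tornado.values():
            spans = (df["icer_high"] - df["icer_low"]).abs()
            assert (spans.diff().dropna() <= 1e-9).all()

    def test_published_tornado_drivers_survive_filter(self, tornado):
        # the analysis singled out baseline utility, procedure cost and the
        # long-term marked-improvement utility as the top vs-no-procedure drivers
        paths = set(tornado["mrgfus_vs_none"]["path"])
        assert {"shared.u_bt", "mrgfus.procedure_cost", "mrgfus.u_mt_y2plus"} <= paths


class TestSampling:
    def test_degenerate_spec_returns_base_exactly(self, base, rng):
        sampled = sample_inputs(base, degenerate_psa_spec(), rng)
        for name in StrategyName:
            assert sampled.strategy(name) == base.strategy(name)

    def test_beta_moment_match(self, rng):
        from tremor_cea.sensitivity import _draw_beta

        draws = np.array([_draw_beta(rng, 0.69, 0.05) for _ in range(100_000)])
        se = 0.05 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.69) < 3 * se
        assert draws.std() == pytest.approx(0.05, rel=0.05)

    def test_gamma_moment_identities(self):
        mean, sd = 744.0, 148.8
        shape, scale = (mean / sd) ** 2, sd**2 / mean
        assert shape * scale == pytest.approx(mean)
        assert np.sqrt(shape) * scale == pytest.approx(sd)

    def test_infeasible_beta_moments_rejected(self, rng):
        from tremor_cea.sensitivity import _draw_beta

        with pytest.raises(ValidationError, match="infeasible"):
            _draw_beta(rng, 0.5, 0.6)

    def test_shared_parameters_identical_across_strategies(self, base, rng):
        sampled = sample_inputs(base, PsaSpec(), rng)
        assert sampled.mrgfus.p_marked == sampled.dbs.p_marked
        assert sampled.mrgfus.u_bt == sampled.dbs.u_bt == sampled.none.u_bt
        assert (sampled.mrgfus.medication_annual
                == sampled.dbs.medication_annual
                == sampled.none.medication_annual)
        # strategy-specific draws differ
        assert sampled.mrgfus.procedure_cost != sampled.dbs.procedure_cost

    def test_sampled_inputs_always_validate(self, base, rng):
        for _ in range(200):
            sampled = sample_inputs(base, PsaSpec(), rng)
            for s in sampled.strategies.values():
                s.validate()


class TestRunPsa:
    def test_single_degenerate_iteration_equals_base_case(self, base):
        psa = run_psa(base, degenerate_psa_spec(), n_iterations=1, seed=0)
        res = evaluate_all(base)
        for key, (a, b) in {
            "mrgfus_vs_none": (StrategyName.MRGFUS, StrategyName.NONE),
            "mrgfus_vs_dbs": (StrategyName.MRGFUS, StrategyName.DBS),
        }.items():
            dc, dq = psa.records(key)
            assert dc[0] == res[a].total_cost - res[b].total_cost
            assert dq[0] == res[a].total_qaly - res[b].total_qaly

    def test_seed_determinism_bitwise(self, base):
        a = run_psa(base, PsaSpec(), n_iterations=20, seed=7)
        b = run_psa(base, PsaSpec(), n_iterations=20, seed=7)
        assert a.frame.equals(b.frame)

    def test_counter_substreams_stable_under_iteration_count(self, base):
        short = run_psa(base, PsaSpec(), n_iterations=5, seed=3)
        long = run_psa(base, PsaSpec(), n_iterations=10, seed=3)
        merged = long.frame[long.frame["iteration"] < 5].reset_index(drop=True)
        assert merged.equals(short.frame)

    def test_different_seeds_differ(self, base):
        a = run_psa(base, PsaSpec(), n_iterations=5, seed=1)
        b = run_psa(base, PsaSpec(), n_iterations=5, seed=2)
        assert not a.frame.equals(b.frame)


class TestCeac:
    def test_curves_bounded(self, psa):
        for curve in ceac(psa, np.arange(0, 100_001, 5000)).values():
            p = curve.p_cost_effective
            assert np.all((0.0 <= p) & (p <= 1.0))

    def test_zero_wtp_counts_cost_savings(self, psa):
        curves = ceac(psa, [0.0])
        for key, curve in curves.items():
            dc, _ = psa.records(key)
            assert curve.at(0.0) == pytest.approx(np.mean(dc < 0))

    def test_monotone_when_qaly_gain_nearly_certain(self, psa):
        dc, dq = psa.records("mrgfus_vs_none")
        assert np.mean(dq > 0) >= 0.8
        curve = ceac(psa, np.arange(0, 200_001, 2000))["mrgfus_vs_none"]
        # recount NMB signs independently at two adjacent grid points
        for wtp in (20_000.0, 30_000.0):
            assert curve.at(wtp) == pytest.approx(np.mean(wtp * dq - dc > 0))

    def test_all_dominant_iterations_give_unit_curve(self, base):
        psa = run_psa(base, degenerate_psa_spec(), n_iterations=3, seed=0)
        curve = ceac(psa, [0, 30_000, 100_000])["mrgfus_vs_dbs"]
        assert np.all(curve.p_cost_effective == 1.0)

    def test_degenerate_curve_steps_at_the_icer(self, base):
        psa = run_psa(base, degenerate_psa_spec(), n_iterations=2, seed=0)
        res = evaluate_all(base)
        icer = compare(res[StrategyName.MRGFUS], res[StrategyName.NONE]).icer
        curve = ceac(psa, [icer - 1.0, icer + 1.0])["mrgfus_vs_none"]
        assert list(curve.p_cost_effective) == [0.0, 1.0]
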