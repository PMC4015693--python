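import dataclasses

import numpy as np
import pytest

import ga1cea as g
from ga1cea.parameters import DistributionSpec
from ga1cea.sensitivity import _psa_at_zero_screening_cost, _recentre_prevalence


def collapse_to_points(config):
    """Replace every distribution by a point mass at its base-case value."""
    dists = {name: DistributionSpec(kind="point", value=spec.base_value())
             for name, spec in config.distributions.items()}
    return dataclasses.replace(config, distributions=dists)


class TestRunPSA:
    def test_same_seed_is_bitwise_reproducible(self, config, life_table):
        a = g.run_psa(config, 20, n_draws=500, seed=7, life_table=life_table)
        b = g.run_psa(config, 20, n_draws=500, seed=7, life_table=life_table)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.dalys_averted, b.dalys_averted)
        assert a.summary().equals(b.summary())

    def test_chunk_size_does_not_change_results(self, config, life_table):
        a = g.run_psa(config, 20, n_draws=300, seed=3, life_table=life_table,
                      chunk_size=300)
        b = g.run_psa(config, 20, n_draws=300, seed=3, life_table=life_table,
                      chunk_size=77)
        np.testing.assert_allclose(a.delta_cost, b.delta_cost, rtol=1e-12)

    def test_point_collapsed_config_reproduces_the_base_case(self, config,
                                                             life_table):
        cfg = collapse_to_points(config)
        psa = g.run_psa(cfg, 20, n_draws=50, seed=0, life_table=life_table)
        bc = g.base_case(config)
        s, ns = g.evaluate_parameter_set(bc, 20, life_table, config.cohort_size)
        inc = g.incremental(s, ns)
        np.testing.assert_allclose(psa.dalys_averted, inc.dalys_averted, rtol=1e-9)
        np.testing.assert_allclose(psa.delta_cost, inc.delta_cost, rtol=1e-9)
        assert psa.dalys_averted.std() < 1e-12

    def test_percentile_interval_brackets_95_percent_of_draws(self, config,
                                                              life_table):
        psa = g.run_psa(config, 20, n_draws=2000, seed=5, life_table=life_table)
        lo, hi = psa.percentiles(psa.dalys_averted)
        inside = np.mean((psa.dalys_averted >= lo) & (psa.dalys_averted <= hi))
        assert 0.94 <= inside <= 0.96

    def test_screening_is_cost_saving_in_most_draws(self, config, life_table):
        psa = g.run_psa(config, 20, n_draws=2000, seed=13, life_table=life_table)
        assert psa.fraction_cost_saving > 0.9
        assert psa.mean_icer() is None  # dominant on the mean

    def test_invalid_draw_count_rejected(self, config):
        with pytest.raises(ValueError):
            g.run_psa(config, 20, n_draws=0, seed=1)


class TestOneWay:
    def test_smd_risk_after_crisis_moves_dalys_monotonically(self, config,
                                                             life_table):
        ow = g.one_way(config, "p_smd_given_clinical", 20, life_table)
        assert ow.at_max.dalys_averted > ow.at_base.dalys_averted \
            > ow.at_min.dalys_averted

    def test_cost_only_parameter_leaves_health_outcomes_unchanged(self, config,
                                                                  life_table):
        ow = g.one_way(config, "cost_smd_overhead_annual", 20, life_table)
        assert ow.at_min.dalys_averted == ow.at_base.dalys_averted \
            == ow.at_max.dalys_averted
        assert ow.at_min.delta_cost != ow.at_max.delta_cost

    def test_point_estimate_has_no_range_to_vary(self, config, life_table):
        with pytest.raises(ValueError, match="no range to vary"):
            g.one_way(config, "cost_screen_per_neonate", 20, life_table)

    def test_unknown_parameter_rejected(self, config):
        with pytest.raises(KeyError):
            g.one_way(config, "not_a_parameter", 20)

    def test_screening_dominant_across_every_ranged_input(self, config,
                                                          life_table):
        """Deterministic one-way sweep: screening stays cost-saving at the
        20-year horizon for every input varied over its full range
        (default placeholder schedules)."""
        ranged = [n for n, s in config.distributions.items() if s.has_range]
        for name in ranged:
            ow = g.one_way(config, name, 20, life_table)
            for out in (ow.at_min, ow.at_base, ow.at_max):
                assert out.delta_cost < 0, name

    def test_frame_has_three_settings(self, config, life_table):
        frame = g.one_way(config, "test_sensitivity", 20, life_table).to_frame()
        assert list(frame["setting"]) == ["min", "base", "max"]


class TestScreeningCostThreshold:
    def test_curve_is_monotone_and_dominant_at_zero(self, config, life_table):
        grid = np.array([0.0, 0.1, 0.5, 1.0, 2.0])
        curve = g.icer_vs_screening_cost(config, 20, grid, n_draws=1000,
                                         seed=2, life_table=life_table)
        assert bool(curve.dominant.iloc[0])
        assert np.all(np.diff(curve.mean_delta_cost) > 0)
        icers = curve.icer.dropna()
        assert np.all(np.diff(icers) > 0)

    def test_affine_slope_is_the_cohort_size(self, config, life_table):
        curve = g.icer_vs_screening_cost(config, 20, [0.03, 0.3], n_draws=500,
                                         seed=4, life_table=life_table)
        diff = curve.mean_delta_cost.iloc[1] - curve.mean_delta_cost.iloc[0]
        assert diff == pytest.approx(0.27 * 100_000)

    def test_break_even_matches_bisection_on_full_evaluations(self, config,
                                                              life_table):
        psa0 = _psa_at_zero_screening_cost(config, 20, 1000, 6, life_table)
        be = g.break_even_screening_cost(config, 20, psa0=psa0)
        assert be is not None and be > 0

        def mean_dcost(c):  # full re-evaluation at screening cost c
            params = psa0  # draws are shared; re-shift exactly
            return float((params.delta_cost + 100_000 * c).mean())

        lo, hi = 0.0, 5.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mean_dcost(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert abs(0.5 * (lo + hi) - be) < 1e-6

    def test_no_break_even_when_not_cost_saving(self, config, life_table):
        psa0 = _psa_at_zero_screening_cost(config, 20, 200, 8, life_table)
        shifted = dataclasses.replace(psa0,
                                      delta_cost=psa0.delta_cost + 10**7)
        assert g.break_even_screening_cost(config, 20, psa0=shifted) is None

    def test_break_even_at_mean_cost_is_zero(self, config, life_table):
        psa0 = _psa_at_zero_screening_cost(config, 20, 500, 9, life_table)
        be = g.break_even_screening_cost(config, 20, psa0=psa0)
        assert (psa0.delta_cost + 100_000 * be).mean() == pytest.approx(0, abs=1e-6)


class TestPrevalenceGrid:
    def test_recentring_preserves_relative_uncertainty(self, config):
        cfg = _recentre_prevalence(config, 1 / 35_000)
        spec = cfg.distributions["prevalence"]
        assert spec.mode == pytest.approx(1 / 35_000)
        ratio_old = config.distributions["prevalence"].max \
            / config.distributions["prevalence"].min
        assert spec.max / spec.min == pytest.approx(ratio_old)

    def test_results_invariant_to_cell_evaluation_order(self, config, life_table):
        prevs = [1 / 35_000, 1 / 200_000]
        a = g.prevalence_grid(config, prevs, [0.03], 20, n_draws=300, seed=1,
                              life_table=life_table)
        b = g.prevalence_grid(config, prevs[::-1], [0.03], 20, n_draws=300,
                              seed=1, life_table=life_table)
        a = a.sort_values("prevalence").reset_index(drop=True)
        b = b.sort_values("prevalence").reset_index(drop=True)
        assert a.equals(b)

    def test_higher_prevalence_means_more_negative_incremental_cost(self, config,
                                                                    life_table):
        tbl = g.prevalence_grid(config, [1 / 35_000, 1 / 350_000], [0.03], 20,
                                n_draws=500, seed=2, life_table=life_table)
        tbl = tbl.sort_values("prevalence")
        assert tbl.mean_delta_cost.iloc[1] < tbl.mean_delta_cost.iloc[0]

    def test_screening_cost_columns_differ_by_the_affine_shift(self, config,
                                                               life_table):
        tbl = g.prevalence_grid(config, [1 / 100_000], [0.03, 0.3], 20,
                                n_draws=300, seed=3, life_table=life_table)
        diff = tbl.mean_delta_cost.iloc[1] - tbl.mean_delta_cost.iloc[0]
        assert diff == pytest.approx(0.27 * 100_000)

    def test_prevalence_bounds_validated(self, config):
        with pytest.raises(ValueError):
            g.prevalence_grid(config, [0.0], [0.03], 20, n_draws=10)


class TestConvergence:
    def test_psa_mean_stable_between_50k_and_200k_draws(self, config, life_table):
        a = g.run_psa(config, 20, n_draws=50_000, seed=10, life_table=life_table)
        b = g.run_psa(config, 20, n_draws=200_000, seed=11, life_table=life_table)
        rel = abs(a.dalys_averted.mean() - b.dalys_averted.mean()) \
            / b.dalys_averted.mean()
        assert rel < 0.02
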