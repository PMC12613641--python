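"""Closed-form and integration-based group sequential design mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from vaptrials import (GSDesign, compute_boundaries, crossing_probabilities,
                       expected_events, hr_from_incidence, max_events,
                       optimal_ia_timing, schoenfeld_events, spending_value)
from vaptrials.design import (TrialAssumptions, _efficacy_bounds,
                              _stagewise_exit_probs)


class TestSchoenfeldEvents:
    @pytest.mark.parametrize("hr, expected", [(0.79, 566), (0.68, 212), (0.58, 106)])
    def test_fixed_design_counts(self, hr, expected):
        assert schoenfeld_events(hr, 0.025, 0.80, 0.5, 0.5) == expected

    def test_unbalanced_allocation_needs_more_events(self):
        assert schoenfeld_events(0.68, alloc_inv=0.25, alloc_soc=0.75) \
            > schoenfeld_events(0.68)

    def test_unit_hazard_ratio_rejected(self):
        with pytest.raises(ValueError):
            schoenfeld_events(1.0)

    def test_invalid_error_rates_rejected(self):
        with pytest.raises(ValueError):
            schoenfeld_events(0.7, alpha=0.0)


class TestHazardRatioFromIncidence:
    @pytest.mark.parametrize("reduction, hr2dp",
                             [(0.20, 0.79), (0.25, 0.73), (0.30, 0.68),
                              (0.35, 0.63), (0.40, 0.58)])
    def test_scenario_grid(self, reduction, hr2dp):
        assert round(hr_from_incidence(0.155, reduction), 2) == hr2dp

    def test_no_reduction_is_unit_hazard(self):
        assert hr_from_incidence(0.155, 0.0) == pytest.approx(1.0)

    def test_degenerate_control_incidence_rejected(self):
        with pytest.raises(ValueError):
            hr_from_incidence(0.0, 0.2)

    def test_assumptions_wrap_the_same_quantities(self):
        a = TrialAssumptions(p_soc=0.155, reduction=0.30)
        assert a.p_inv == pytest.approx(0.1085)
        assert round(a.hr, 2) == 0.68
        assert a.fixed_events() == schoenfeld_events(a.hr)


class TestSpendingFunctions:
    @given(kind=st.sampled_from(["obf", "pocock"]),
           err=st.floats(0.005, 0.2),
           t=st.floats(0.01, 0.99), dt=st.floats(0.001, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, kind, err, t, dt):
        lo = spending_value(kind, err, t)
        hi = spending_value(kind, err, min(t + dt, 1.0))
        assert 0.0 <= lo <= hi <= err + 1e-12

    @pytest.mark.parametrize("kind", ["obf", "pocock"])
    def test_exhausts_total_error_at_one(self, kind):
        assert spending_value(kind, 0.025, 1.0) == pytest.approx(0.025, abs=1e-12)

    def test_vanishes_at_zero(self):
        assert spending_value("obf", 0.025, 1e-8) < 1e-10

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            spending_value("haybittle", 0.025, 0.5)


class TestBoundaries:
    def test_single_analysis_reduces_to_fixed_test(self):
        b = compute_boundaries(GSDesign(info_fractions=(1.0,)))
        assert b.efficacy_z[0] == pytest.approx(norm.ppf(0.975), abs=1e-4)

    def test_obf_interim_stricter_than_final(self, scenario1_summary):
        u = scenario1_summary.boundaries.efficacy_z
        assert u[0] > u[-1]

    def test_futility_below_efficacy_at_interims(self, scenario1_summary):
        b = scenario1_summary.boundaries
        assert b.futility_z[0] < b.efficacy_z[0]
        assert b.futility_z[-1] == pytest.approx(b.efficacy_z[-1])

    def test_non_increasing_fractions_rejected(self):
        with pytest.raises(ValueError):
            GSDesign(info_fractions=(0.8, 0.5, 1.0))

    def test_boundary_spending_consistency(self):
        # cumulative null crossing probability of the solved efficacy
        # boundaries must match the spending function at every analysis
        design = GSDesign(info_fractions=(0.2, 0.4, 0.6, 0.8, 1.0))
        u, cum = _efficacy_bounds(design)
        p_up, _ = _stagewise_exit_probs(np.asarray(design.info_fractions),
                                        0.0, u, np.full(5, -8.0))
        assert np.allclose(np.cumsum(p_up), cum, atol=1e-6)

    def test_null_crossing_matches_monte_carlo_oracle(self, scenario1_summary,
                                                      rng):
        # brute-force 1e6 correlated-normal draws of the two sequential
        # z-statistics; null efficacy crossing must agree with alpha
        u = scenario1_summary.boundaries.efficacy_z
        n = 1_000_000
        z1 = rng.standard_normal(n)
        z2 = np.sqrt(0.64) * z1 + np.sqrt(0.36) * rng.standard_normal(n)
        reject = (z1 >= u[0]) | ((z1 < u[0]) & (z2 >= u[1]))
        p = reject.mean()
        se = np.sqrt(0.025 * 0.975 / n)
        assert abs(p - 0.025) < 3 * se


class TestSizingAndCrossing:
    def test_scenario1_operating_characteristics(self, scenario1_summary):
        s = scenario1_summary
        stops = s.stop_probabilities
        assert s.n_fixed_events == 566
        assert s.n_max_events == 617
        assert round(stops.p_eff[0], 2) == 0.41
        assert round(stops.p_fut[0], 2) == 0.11
        assert round(s.expected_events) == 502

    def test_degenerate_single_analysis_equals_fixed(self):
        s = max_events(GSDesign(info_fractions=(1.0,)), 0.68)
        assert s.n_max_events == s.n_fixed_events == 212

    def test_alternative_power_calibration(self, obf_one_ia_design,
                                           scenario1_summary):
        # rejection probability at the solved maximum must hit the target
        b = scenario1_summary.boundaries
        stops = crossing_probabilities(b, obf_one_ia_design, 0.79,
                                       scenario1_summary.n_max_events)
        assert stops.power == pytest.approx(0.80, abs=2e-3)

    def test_null_efficacy_exit_within_alpha(self, obf_one_ia_design,
                                             scenario1_summary):
        stops = crossing_probabilities(scenario1_summary.boundaries,
                                       obf_one_ia_design, 1.0,
                                       scenario1_summary.n_max_events)
        assert stops.power <= 0.025 + 1e-9

    def test_stop_probabilities_sum_to_one(self, scenario1_summary):
        stops = scenario1_summary.stop_probabilities
        total = sum(stops.p_eff) + sum(stops.p_fut) + stops.p_final_accept
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_scenario_invariance_of_stop_probabilities(self):
        # each design powered for its own hazard ratio has identical interim
        # stopping probabilities across the scenario grid
        design = GSDesign(info_fractions=(0.64, 1.0))
        probs = [max_events(design, hr).stop_probabilities
                 for hr in (0.79, 0.73, 0.68, 0.63, 0.58)]
        for p in probs[1:]:
            assert p.p_eff[0] == pytest.approx(probs[0].p_eff[0], abs=1e-4)
            assert p.p_fut[0] == pytest.approx(probs[0].p_fut[0], abs=1e-4)

    def test_unit_hazard_ratio_rejected(self, obf_one_ia_design):
        with pytest.raises(ValueError):
            max_events(obf_one_ia_design, 1.0)


class TestExpectedEvents:
    def test_one_interim_algebraic_identity(self, scenario1_summary):
        # E[n] = n_max * (1 - p_stop_IA * (1 - t_IA)) for a single interim
        s = scenario1_summary
        p_stop = s.stop_probabilities.p_eff[0] + s.stop_probabilities.p_fut[0]
        n1, n_max = s.n_events_per_stage
        identity = n_max - p_stop * (n_max - n1)
        assert s.expected_events == pytest.approx(identity, abs=1e-6)

    def test_length_mismatch_rejected(self, scenario1_summary):
        from vaptrials.design import expected_events_from
        with pytest.raises(ValueError):
            expected_events_from([100], scenario1_summary.stop_probabilities)

    def test_expected_below_maximum(self, scenario1_summary):
        assert scenario1_summary.expected_events < scenario1_summary.n_max_events


class TestOptimalTiming:
    def test_obf_optimum_recovered_on_local_grid(self):
        grid = np.round(np.arange(0.58, 0.71, 0.01), 2)
        assert optimal_ia_timing("obf", 0.79, grid=grid) == pytest.approx(0.64)

    def test_pocock_optimum_recovered_on_local_grid(self):
        grid = np.round(np.arange(0.42, 0.55, 0.01), 2)
        assert optimal_ia_timing("pocock", 0.79, grid=grid) == pytest.approx(0.48)

    def test_refined_grid_stays_within_one_coarse_step(self):
        # the expected-events curve is extremely flat near its minimum, so a
        # 0.5% grid must land within one 1% step of the coarse optimum and
        # gain a negligible number of expected events
        from vaptrials.design import max_events as _me
        fine = np.round(np.arange(0.625, 0.656, 0.005), 3)
        t = optimal_ia_timing("obf", 0.79, grid=fine)
        assert abs(t - 0.64) <= 0.01
        e_fine = _me(GSDesign(info_fractions=(t, 1.0)), 0.79,
                     _round=False).expected_events
        e_coarse = _me(GSDesign(info_fractions=(0.64, 1.0)), 0.79,
                       _round=False).expected_events
        assert e_coarse - e_fine < 0.05

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optimal_ia_timing("obf", 0.79, grid=[])
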