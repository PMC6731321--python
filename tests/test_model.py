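"""Unit and property tests for the core ODE right-hand sides and unit
conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pactmab.model import (
    ModelParams,
    ModelState,
    WellGeometry,
    antiproliferative_effect,
    capacity_reduction,
    cells_to_confluence,
    combined_rhs,
    confluence_to_cells,
    logistic_solution,
    paclitaxel_rhs,
    trastuzumab_rhs,
)


class TestDrugEffects:
    def test_no_bound_antibody_gives_zero_effect(self):
        assert antiproliferative_effect(0.0, 5.0, 2.51, 0.6) == 0.0

    def test_effect_zero_during_delay(self):
        assert antiproliferative_effect(0.5, 0.5, 2.51, 0.6) == 0.0
        # boundary: at exactly t_star the delay branch still applies
        assert antiproliferative_effect(0.5, 0.6, 2.51, 0.6) == 0.0

    def test_effect_is_direct_product_after_delay(self):
        assert antiproliferative_effect(0.1, 1.0, 2.51, 0.6) == pytest.approx(0.251)

    def test_negative_bound_antibody_rejected(self):
        with pytest.raises(ValueError):
            antiproliferative_effect(-0.1, 1.0, 2.51, 0.6)

    def test_capacity_reduction_zero_without_drug(self):
        assert capacity_reduction(0.0, 1.0, 0.8, 6.35, 0.3) == 0.0

    def test_capacity_reduction_at_tstar_is_twice_asymptote(self):
        # exponent vanishes at t = t_star, leaving delta * (1 + S) * P_i
        v = capacity_reduction(0.4, 0.3, 0.8, 6.35, 0.3, S=1.0)
        assert v == pytest.approx(2 * 0.8 * 0.4)

    def test_capacity_reduction_late_time_limit(self):
        v = capacity_reduction(0.4, 100.0, 0.8, 6.35, 0.3, S=1.0)
        assert v == pytest.approx(0.8 * 0.4, rel=1e-12)

    def test_negative_internalized_drug_rejected(self):
        with pytest.raises(ValueError):
            capacity_reduction(-0.1, 1.0, 0.8, 6.35, 0.3)

    @given(
        a1=st.floats(0, 2), a2=st.floats(0, 2),
        t=st.floats(0.7, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f_nondecreasing_in_bound_antibody(self, a1, a2, t):
        lo, hi = sorted((a1, a2))
        f_lo = antiproliferative_effect(lo, t, 2.51, 0.6)
        f_hi = antiproliferative_effect(hi, t, 2.51, 0.6)
        assert f_hi >= f_lo

    @given(
        p1=st.floats(0, 2), p2=st.floats(0, 2),
        t=st.floats(0, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_h_nondecreasing_in_internalized_drug(self, p1, p2, t):
        lo, hi = sorted((p1, p2))
        h_lo = capacity_reduction(lo, t, 0.8, 6.35, 0.3, 1.0)
        h_hi = capacity_reduction(hi, t, 0.8, 6.35, 0.3, 1.0)
        assert h_hi >= h_lo


class TestRightHandSides:
    def test_no_drug_reduces_to_logistic(self, default_params):
        p = default_params
        y = np.array([0.5, 0.0, 0.0, 0.0, 0.0])
        d = combined_rhs(y, 0.7, p)
        logistic = p.k * (1 - 0.5 / p.theta) * 0.5
        assert d[0] == logistic
        assert np.all(d[1:] == 0.0)

    def test_carrying_capacity_fixed_point(self, default_params):
        p = default_params
        y = np.array([p.theta, 0.0, 0.0, 0.0, 0.0])
        assert combined_rhs(y, 0.5, p)[0] == 0.0

    def test_binding_stops_without_free_antibody(self, default_params):
        y = np.array([0.5, 0.3, 0.0, 0.0, 0.0])
        d = trastuzumab_rhs(y, 1.5, default_params, tmab_apply_time=1.0)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_uptake_stops_without_free_drug(self, default_params):
        y = np.array([0.5, 0.0, 0.0, 0.4, 0.0])
        d = paclitaxel_rhs(y, 1.5, default_params, pac_apply_time=1.0)
        assert d[3] == 0.0 and d[4] == 0.0

    def test_drug_pools_are_conservative(self, default_params):
        y = np.array([0.5, 0.2, 0.6, 0.1, 0.7])
        d = combined_rhs(y, 1.5, default_params, tmab_apply_time=1.0, pac_apply_time=1.0)
        assert d[1] + d[2] == 0.0
        assert d[3] + d[4] == 0.0

    def test_combined_matches_single_drug_bitwise(self, default_params):
        p = default_params
        # paclitaxel present, antibody absent
        y = np.array([0.5, 0.0, 0.0, 0.3, 0.6])
        assert np.array_equal(
            combined_rhs(y, 1.5, p, tmab_apply_time=None, pac_apply_time=1.0),
            paclitaxel_rhs(y, 1.5, p, pac_apply_time=1.0),
        )
        # antibody present, paclitaxel absent
        y = np.array([0.5, 0.4, 0.5, 0.0, 0.0])
        assert np.array_equal(
            combined_rhs(y, 1.8, p, tmab_apply_time=1.0, pac_apply_time=None),
            trastuzumab_rhs(y, 1.8, p, tmab_apply_time=1.0),
        )

    def test_both_death_mechanisms_never_read_as_growth(self):
        # f > 1 and capacity below T together must yield net loss
        p = ModelParams(eta_A=5.0, delta_P=3.0, S=1.5)
        y = np.array([0.6, 1.0, 0.0, 0.9, 0.0])
        d = combined_rhs(y, 2.5, p, tmab_apply_time=1.0, pac_apply_time=2.0)
        assert d[0] < 0.0


class TestValidation:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(k=-0.1)

    def test_synergy_default_is_exactly_one(self):
        assert ModelParams().S == 1.0

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            ModelState(T=-0.1)


class TestUnitConversions:
    def test_zero_confluence_is_zero_cells(self):
        assert confluence_to_cells(0.0) == 0.0

    def test_full_well_cell_count(self):
        # well_area / (pi r^2) = 0.32 / (pi * (1.25e-3)^2)
        expected = 0.32 / (math.pi * 1.25e-3**2)
        assert confluence_to_cells(1.0) == pytest.approx(expected)
        assert expected == pytest.approx(6.52e4, rel=1e-3)

    def test_round_trip_identity(self):
        cells = np.array([0.0, 1e3, 3.5e4, 6.5e4])
        back = confluence_to_cells(cells_to_confluence(cells))
        assert np.allclose(back, cells, rtol=1e-14)

    def test_out_of_range_confluence_rejected(self):
        with pytest.raises(ValueError):
            confluence_to_cells(1.2)
        with pytest.raises(ValueError):
            confluence_to_cells(-0.1)

    def test_geometry_must_be_positive(self):
        with pytest.raises(ValueError):
            WellGeometry(cell_radius=0.0)


def test_logistic_solution_limits():
    t = np.linspace(0, 4, 9)
    # k = 0 keeps T constant
    assert np.allclose(logistic_solution(t, 0.3, 0.0, 0.67), 0.3)
    # starting at theta stays at theta
    assert np.allclose(logistic_solution(t, 0.67, 0.83, 0.67), 0.67)
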