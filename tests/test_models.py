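"""The three psychometric models and their interrelations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from tojrace import (
    IndecisionParams,
    InvalidParameterError,
    RaceParams,
    ResetParams,
    model_probability,
    percept_probabilities_indecision,
    prob_probe_first_indecision,
    prob_probe_first_reset,
    prob_probe_first_simple,
    probe_first_probability,
    reset_probability,
)

GRID = np.linspace(-200.0, 200.0, 401)

RATES = st.floats(min_value=1e-4, max_value=1.0)
indecision_params = st.builds(
    IndecisionParams,
    rates=st.builds(RaceParams, vp=RATES, vr=RATES),
    delta=st.floats(min_value=0.0, max_value=200.0),
    xi=st.floats(min_value=0.0, max_value=1.0),
    tau=st.floats(min_value=-200.0, max_value=200.0),
)
reset_params = st.builds(
    ResetParams,
    rates=st.builds(RaceParams, vp=RATES, vr=RATES),
    t0=st.floats(min_value=0.0, max_value=200.0),
    s0=st.floats(min_value=0.0, max_value=100.0),
    tau=st.floats(min_value=-200.0, max_value=200.0),
)


class TestIndecisionModel:
    def test_zero_width_range_has_no_simultaneity(self, sym_rates):
        p = percept_probabilities_indecision(
            IndecisionParams(sym_rates, delta=0.0, xi=0.5), 0.0
        )
        assert (p.p_probe_first, p.p_simultaneous, p.p_reference_first) == (0.5, 0.0, 0.5)

    def test_percept_probabilities_at_20ms_range(self, typical_indecision):
        p = percept_probabilities_indecision(typical_indecision, 0.0)
        edge = 0.5 * math.exp(-1.0)  # race evaluated at +/- delta
        assert p.p_probe_first == pytest.approx(edge, abs=1e-12)
        assert p.p_reference_first == pytest.approx(edge, abs=1e-12)
        assert p.p_simultaneous == pytest.approx(1 - 2 * edge, abs=1e-12)

    def test_infinite_range_is_all_simultaneous(self, sym_rates):
        p = percept_probabilities_indecision(
            IndecisionParams(sym_rates, delta=1e6, xi=0.5), 0.0
        )
        assert p.p_probe_first == pytest.approx(0.0, abs=1e-12)
        assert p.p_simultaneous == pytest.approx(1.0, abs=1e-12)

    def test_neutral_bias_plateau_sits_at_half(self, typical_indecision):
        """Equal rates, tau=0, xi=0.5: symmetry pins the plateau to 0.5."""
        assert prob_probe_first_indecision(typical_indecision, 0.0) == pytest.approx(
            0.5, abs=1e-15
        )

    def test_biased_response_example(self, sym_rates):
        params = IndecisionParams(sym_rates, delta=20.0, xi=0.3)
        expected = 0.5 * math.exp(-1) + 0.7 * (1 - math.exp(-1))
        assert prob_probe_first_indecision(params, 0.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.626424, abs=1e-6)

    def test_bias_is_inert_when_range_has_zero_width(self, asym_rates):
        params = IndecisionParams(asym_rates, delta=0.0, xi=0.9)
        assert np.allclose(
            prob_probe_first_indecision(params, GRID),
            probe_first_probability(asym_rates, GRID),
            atol=1e-15,
        )

    def test_plateau_height_formula_and_xi_linearity(self, sym_rates):
        """At soa = -tau the response probability equals
        p(delta) + (1 - xi) * (p(-delta) - p(delta)), linear in xi."""
        delta, tau = 25.0, 10.0
        hi = probe_first_probability(sym_rates, -delta)
        lo = probe_first_probability(sym_rates, delta)
        for xi in (0.0, 0.25, 0.5, 0.8, 1.0):
            params = IndecisionParams(sym_rates, delta=delta, xi=xi, tau=tau)
            expected = lo + (1 - xi) * (hi - lo)
            assert prob_probe_first_indecision(params, -tau) == pytest.approx(
                expected, abs=1e-12
            )

    @given(params=indecision_params)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_percepts_form_a_distribution_and_curve_is_monotone(self, params):
        p = percept_probabilities_indecision(params, 12.5)
        for v in (p.p_probe_first, p.p_simultaneous, p.p_reference_first):
            assert -1e-12 <= v <= 1 + 1e-12
        curve = prob_probe_first_indecision(params, GRID)
        assert np.all(curve >= 0) and np.all(curve <= 1)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_invalid_parameters_rejected(self, sym_rates):
        with pytest.raises(InvalidParameterError):
            IndecisionParams(sym_rates, delta=-1.0, xi=0.5)
        with pytest.raises(InvalidParameterError):
            IndecisionParams(sym_rates, delta=1.0, xi=1.5)


class TestResetModel:
    def test_reset_probability_branches_agree_at_zero(self, asym_rates):
        for t0, s0 in [(5.0, 3.0), (15.0, 18.0), (40.0, 1.0)]:
            params = ResetParams(asym_rates, t0=t0, s0=s0)
            assert reset_probability(params, 0.0) == pytest.approx(
                ndtr(t0 / s0), abs=1e-12
            )

    def test_reset_probability_example(self, typical_reset):
        assert reset_probability(typical_reset, -30.0) == pytest.approx(
            ndtr(-5.0 / 6.0), abs=1e-12
        )

    def test_no_reset_for_widely_separated_onsets(self, typical_reset):
        assert reset_probability(typical_reset, -2000.0) == pytest.approx(0.0, abs=1e-12)
        assert reset_probability(typical_reset, 2000.0) == pytest.approx(0.0, abs=1e-12)

    def test_plateau_value_is_luce_ratio_at_shifted_origin(self, asym_rates):
        """At soa + tau = 0 both mixture components equal vp/(vp+vr),
        whatever t0 and s0 are."""
        for t0, s0, tau in [(15.0, 18.0, 0.0), (50.0, 5.0, -20.0), (2.0, 60.0, 35.0)]:
            params = ResetParams(asym_rates, t0=t0, s0=s0, tau=tau)
            assert prob_probe_first_reset(params, -tau) == pytest.approx(
                0.6, abs=1e-12
            )

    def test_response_probability_example(self, typical_reset):
        w = ndtr(-5.0 / 6.0)
        base = probe_first_probability(typical_reset.rates, -30.0)
        expected = w * 0.6 + (1 - w) * base
        assert prob_probe_first_reset(typical_reset, -30.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.8663270, abs=1e-6)

    def test_unequal_rates_shift_plateau_away_from_half(self):
        """Vertical plateau displacement requires vp != vr."""
        up = ResetParams(RaceParams(0.06, 0.04), t0=15.0, s0=18.0)
        level = ResetParams(RaceParams(0.05, 0.05), t0=15.0, s0=18.0)
        assert prob_probe_first_reset(up, 0.0) > 0.5
        assert prob_probe_first_reset(level, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_spread_is_step_function(self, asym_rates):
        params = ResetParams(asym_rates, t0=15.0, s0=0.0)
        assert reset_probability(params, -10.0) == 1.0
        assert reset_probability(params, -15.0) == 1.0  # boundary resets
        assert reset_probability(params, -15.1) == 0.0

    @given(params=reset_params)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_curve_in_unit_interval_and_monotone(self, params):
        curve = prob_probe_first_reset(params, GRID)
        assert np.all(curve >= 0) and np.all(curve <= 1)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_invalid_parameters_rejected(self, asym_rates):
        with pytest.raises(InvalidParameterError):
            ResetParams(asym_rates, t0=15.0, s0=-1.0)
        with pytest.raises(InvalidParameterError):
            ResetParams(asym_rates, t0=math.inf, s0=1.0)


class TestReductionsToSimpleRace:
    def test_indecision_with_zero_width(self, asym_rates):
        params = IndecisionParams(asym_rates, delta=0.0, xi=0.37, tau=7.0)
        assert np.allclose(
            prob_probe_first_indecision(params, GRID),
            prob_probe_first_simple(asym_rates, GRID, tau=7.0),
            atol=1e-12,
        )

    @pytest.mark.parametrize("s0", [0.0, 1e-12])
    def test_reset_with_zero_threshold(self, asym_rates, s0):
        params = ResetParams(asym_rates, t0=0.0, s0=s0, tau=-3.0)
        assert np.allclose(
            prob_probe_first_reset(params, GRID),
            prob_probe_first_simple(asym_rates, GRID, tau=-3.0),
            atol=1e-9,
        )

    def test_simple_race_is_strictly_decreasing(self, asym_rates):
        curve = prob_probe_first_simple(asym_rates, GRID)
        assert np.all(np.diff(curve) < 0)


def test_model_registry_dispatch(asym_rates, typical_reset, typical_indecision):
    assert model_probability("simple", {"vp": 0.06, "vr": 0.04, "tau": 0.0}, 0.0) == 0.6
    assert model_probability("reset", typical_reset, -30.0) == pytest.approx(
        prob_probe_first_reset(typical_reset, -30.0)
    )
    assert model_probability("indecision", typical_indecision, 0.0) == 0.5
    with pytest.raises(InvalidParameterError):
        model_probability("nope", typical_reset, 0.0)
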