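"""Temperature scaling, Van't Hoff propagation and the regime profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycotherm import (ConfigurationError, DomainError, RatkowskyParams,
                        SensitivitySpec, TemperatureProfile, VantHoffParams,
                        apply_sensitivity, compute_b, keq_at_temperature,
                        keq_fold_change, profile_temperature, ratkowsky_scale,
                        vant_hoff_delta_h, vant_hoff_params_from_table)
from glycotherm.thermo import KEQ_TABLE, T12_K, T30_K, ctc_profile, lts_profile


class TestRatkowsky:
    def test_normalized_at_reference(self, params):
        assert ratkowsky_scale(params, params.t_ref) == 1.0

    def test_zero_at_t_min(self, params):
        assert ratkowsky_scale(params, params.t_min) == 0.0

    def test_six_fold_ratio_between_30_and_12(self, params):
        r12 = ratkowsky_scale(params, 12.0)
        assert r12 == pytest.approx((12.42 / 30.42) ** 2, rel=1e-6)
        assert 1.0 / r12 == pytest.approx(6.0, rel=2e-3)

    def test_below_t_min_is_domain_error(self, params):
        with pytest.raises(DomainError):
            ratkowsky_scale(params, -5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t=st.floats(min_value=0.0, max_value=30.0))
    def test_strictly_increasing(self, params, t):
        if t + 0.5 <= params.t_ref:
            assert ratkowsky_scale(params, t + 0.5) > ratkowsky_scale(params, t)


class TestComputeB:
    def test_uptake_reaction_keeps_b_glc(self):
        assert compute_b(0.02, 5.0, 5.0) == pytest.approx(0.02)

    def test_flux_share_proportionality(self):
        assert compute_b(0.02, 2.5, 5.0) == pytest.approx(0.01)

    def test_zero_reference_flux_gives_zero(self):
        assert compute_b(0.02, 0.0, 5.0) == 0.0

    def test_zero_uptake_is_error(self):
        with pytest.raises(DomainError):
            compute_b(0.02, 1.0, 0.0)


class TestVantHoff:
    def test_equal_keq_gives_zero_enthalpy(self):
        assert vant_hoff_delta_h(5.0, 285.15, 5.0, 303.15) == 0.0

    def test_pgk_enthalpy_from_printed_pair(self):
        dh = vant_hoff_delta_h(20.0, T12_K, 16.0, T30_K)
        expected = 8.314 * math.log(16.0 / 20.0) / (1 / T12_K - 1 / T30_K)
        assert dh == pytest.approx(expected)
        assert dh == pytest.approx(-8.91e3, rel=5e-3)

    def test_label_swap_is_symmetric(self):
        a = vant_hoff_delta_h(20.0, T12_K, 16.0, T30_K)
        b = vant_hoff_delta_h(16.0, T30_K, 20.0, T12_K)
        assert a == pytest.approx(b)

    def test_nonpositive_keq_is_domain_error(self):
        with pytest.raises(DomainError):
            vant_hoff_delta_h(-1.0, T12_K, 16.0, T30_K)

    def test_keq_at_reference_temperature(self):
        p = VantHoffParams(keq_ref=16.0, delta_h=-8910.0)
        assert keq_at_temperature(p, T30_K) == pytest.approx(16.0)

    def test_zero_enthalpy_keq_constant(self):
        p = VantHoffParams(keq_ref=3.0, delta_h=0.0)
        for t in (275.0, 290.0, 310.0):
            assert keq_at_temperature(p, t) == 3.0

    @pytest.mark.parametrize("enzyme", sorted(KEQ_TABLE))
    def test_round_trip_reproduces_both_anchors(self, enzyme):
        p = vant_hoff_params_from_table(enzyme)
        row = KEQ_TABLE[enzyme]
        assert keq_at_temperature(p, T30_K) == pytest.approx(row["keq_30"], rel=1e-10)
        assert keq_at_temperature(p, T12_K) == pytest.approx(row["keq_12"], rel=1e-10)

    @pytest.mark.parametrize("enzyme", sorted(KEQ_TABLE))
    def test_printed_fold_change_consistency(self, enzyme):
        """The table's own Keq pair reproduces the printed |fold| exactly at
        the two-decimal precision of the printed column."""
        assert round(keq_fold_change(enzyme), 2) == \
            pytest.approx(KEQ_TABLE[enzyme]["fold"])


class TestSensitivity:
    def test_factor_one_is_baseline(self, model, params):
        base = apply_sensitivity(params, None, model.reaction_ids)
        same = apply_sensitivity(params, SensitivitySpec("TDHL", 1.0),
                                 model.reaction_ids)
        for rid in model.reaction_ids:
            assert same[rid](17.3) == base[rid](17.3)

    def test_halved_exponent_at_12(self, model, params):
        funs = apply_sensitivity(params, SensitivitySpec("TDHL", 2.0),
                                 model.reaction_ids)
        assert funs["TDHL"](12.0) == pytest.approx(12.42 / 30.42, rel=1e-6)
        assert funs["PFK"](12.0) == pytest.approx((12.42 / 30.42) ** 2, rel=1e-6)

    def test_infinite_factor_limit_is_insensitive(self, model, params):
        funs = apply_sensitivity(params, SensitivitySpec("TDHL", 1e9),
                                 model.reaction_ids)
        for t in (12.0, 21.0, 30.0):
            assert funs["TDHL"](t) == pytest.approx(1.0, abs=1e-6)

    def test_all_scale_functions_normalized_at_reference(self, model, params):
        funs = apply_sensitivity(params, SensitivitySpec("PYK", 2.0),
                                 model.reaction_ids)
        for rid in model.reaction_ids:
            assert funs[rid](params.t_ref) == pytest.approx(1.0, abs=1e-15)

    def test_unknown_reaction_is_configuration_error(self, model, params):
        with pytest.raises(ConfigurationError):
            apply_sensitivity(params, SensitivitySpec("NOPE", 2.0),
                              model.reaction_ids)


class TestProfiles:
    def test_sinoid_starts_at_30(self):
        assert round(profile_temperature(ctc_profile(), 0.0), 2) == 30.00

    def test_sinoid_period_and_range(self):
        prof = ctc_profile()
        assert prof.period_h == pytest.approx(24.0)
        temps = [prof.temperature(t) for t in np.linspace(0, 48, 4801)]
        assert min(temps) == pytest.approx(12.0, abs=1e-4)
        assert max(temps) == pytest.approx(30.0, abs=1e-4)

    def test_phase_is_printed_literal_not_half_pi(self):
        assert ctc_profile().phase == 1.57

    def test_linear_shift_spans_three_hours(self):
        prof = lts_profile(30.0, 12.0)
        assert prof.leg_duration_h == pytest.approx(1.5)       # 18 °C / 0.2 °C·min⁻¹
        assert prof.shift_span_h == pytest.approx(3.0)
        assert prof.temperature(1.5) == pytest.approx(12.0)
        assert prof.temperature(3.0) == pytest.approx(30.0)
        assert prof.temperature(5.0) == pytest.approx(30.0)    # hold

    def test_linear_shift_up_and_back(self):
        prof = lts_profile(12.0, 30.0)
        assert prof.temperature(1.5) == pytest.approx(30.0)
        assert prof.temperature(0.5) == pytest.approx(18.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(t=st.floats(min_value=0.0, max_value=6.0),
           dt=st.floats(min_value=1e-4, max_value=0.05))
    def test_profile_continuity_bounded_by_ramp_rate(self, t, dt):
        prof = lts_profile(30.0, 12.0)
        jump = abs(prof.temperature(t + dt) - prof.temperature(t))
        assert jump <= 0.2 * 60.0 * dt + 1e-9

    def test_constant_profile(self):
        prof = TemperatureProfile("constant", constant_t=18.0)
        assert prof.temperature(0.0) == 18.0
        assert prof.temperature(99.0) == 18.0

    def test_negative_time_is_domain_error(self):
        with pytest.raises(DomainError):
            ctc_profile().temperature(-1.0)
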