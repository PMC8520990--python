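"""Unit and property tests for the cochlear-place computations."""

import pytest
from hypothesis import given, settings, strategies as st

from cochlear_gain import (
    GainReductionRule,
    IOFunction,
    ListenerProfile,
    StimulusSpec,
    apply_gain_reduction,
    elicited_gain_reduction,
    erb_bandwidth,
    io_output,
    level_per_erb,
    place_excitation,
    spectrum_level,
)
from cochlear_gain.cochlea import is_on_frequency


class TestERBConversions:
    @pytest.mark.parametrize("f_khz, expected", [
        (4.0, 456.46),       # the auditory-filter bandwidth at the signal frequency
        (1.0, 132.639),      # direct evaluation
    ])
    def test_erb_bandwidth_values(self, f_khz, expected):
        assert erb_bandwidth(f_khz) == pytest.approx(expected, abs=0.005)

    def test_erb_limit_at_low_frequency(self):
        assert erb_bandwidth(1e-9) == pytest.approx(24.7, abs=1e-6)

    def test_erb_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            erb_bandwidth(0.0)

    @given(st.floats(0.05, 20), st.floats(0.05, 20))
    def test_erb_strictly_increasing(self, f1, f2):
        if f1 == f2:
            return
        lo, hi = sorted([f1, f2])
        assert erb_bandwidth(lo) < erb_bandwidth(hi)

    @pytest.mark.parametrize("overall, lo, hi, expected", [
        (64.0, 80.0, 10_000.0, 24.03),
        (24.0, 80.0, 10_000.0, -15.97),
    ])
    def test_spectrum_level(self, overall, lo, hi, expected):
        assert spectrum_level(overall, lo, hi) == pytest.approx(expected, abs=0.005)

    def test_spectrum_level_unit_band_is_identity(self):
        assert spectrum_level(30.0, 100.0, 101.0) == pytest.approx(30.0)

    def test_spectrum_level_rejects_empty_band(self):
        with pytest.raises(ValueError):
            spectrum_level(60.0, 500.0, 500.0)

    @pytest.mark.parametrize("sl, erb, expected", [
        (0.0, 456.46, 26.59),
        (24.03, 456.46, 50.62),
    ])
    def test_level_per_erb(self, sl, erb, expected):
        assert level_per_erb(sl, erb) == pytest.approx(expected, abs=0.005)

    def test_level_per_erb_unit_bandwidth_identity(self):
        assert level_per_erb(17.5, 1.0) == 17.5

    def test_level_per_erb_rejects_nonpositive_bandwidth(self):
        with pytest.raises(ValueError):
            level_per_erb(10.0, 0.0)


class TestIOFunction:
    @pytest.mark.parametrize("input_dB, expected", [
        (40.0, 80.0),   # continuity at the breakpoint
        (30.0, 70.0),   # linear segment: input + G
        (60.0, 84.0),   # compressive segment: BP + G + c (input - BP)
    ])
    def test_output_values(self, io_fig, input_dB, expected):
        assert io_output(input_dB, io_fig) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            IOFunction(-1.0, 0.2, 40.0)
        with pytest.raises(ValueError):
            IOFunction(40.0, 0.0, 40.0)
        with pytest.raises(ValueError):
            IOFunction(40.0, 1.2, 40.0)

    @given(st.floats(-20, 120), st.floats(-20, 120))
    @settings(max_examples=50)
    def test_strictly_increasing(self, io_fig, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert io_output(lo, io_fig) < io_output(hi, io_fig)

    def test_segment_slopes_by_finite_difference(self, io_fig):
        h = 1e-4
        below = (io_output(30 + h, io_fig) - io_output(30, io_fig)) / h
        above = (io_output(60 + h, io_fig) - io_output(60, io_fig)) / h
        assert below == pytest.approx(1.0, abs=1e-6)
        assert above == pytest.approx(0.2, abs=1e-6)

    def test_inverse_round_trip(self, io_fig):
        for level in [-10.0, 25.0, 40.0, 55.0, 90.0]:
            assert io_fig.inverse(io_output(level, io_fig)) == pytest.approx(level)

    def test_json_round_trip(self, io_fig):
        assert IOFunction.from_json(io_fig.to_json()) == io_fig


class TestGainReduction:
    def test_zero_reduction_is_identity(self, io_fig):
        assert apply_gain_reduction(io_fig, 0.0) is io_fig

    def test_breakpoint_pivot(self, io_fig):
        # new breakpoint BP + dg/(1-c); low-level outputs drop by dg,
        # compressive segment unchanged
        r = apply_gain_reduction(io_fig, 10.0)
        assert r.breakpoint_dB == pytest.approx(52.5)
        assert io_output(30.0, r) == pytest.approx(60.0)
        assert io_output(60.0, r) == pytest.approx(84.0)

    def test_out_of_range_rejected(self, io_fig):
        with pytest.raises(ValueError):
            apply_gain_reduction(io_fig, -1.0)
        with pytest.raises(ValueError):
            apply_gain_reduction(io_fig, 41.0)

    @given(st.floats(0, 40), st.floats(-20, 120))
    @settings(max_examples=100)
    def test_output_nonincreasing_in_delta_g(self, io_fig, dg, level):
        reduced = apply_gain_reduction(io_fig, dg)
        assert io_output(level, reduced) <= io_output(level, io_fig) + 1e-9

    @given(st.floats(0.01, 39.9))
    @settings(max_examples=50)
    def test_exact_shift_identities(self, io_fig, dg):
        r = apply_gain_reduction(io_fig, dg)
        c = io_fig.compression_exponent
        # unchanged at/above the new breakpoint
        pivot = io_fig.breakpoint_dB + dg / (1 - c)
        for lv in [pivot, pivot + 5, pivot + 30]:
            assert io_output(lv, r) == pytest.approx(io_output(lv, io_fig))
        # exactly dg lower below the original breakpoint
        for lv in [-10.0, 0.0, io_fig.breakpoint_dB - 1]:
            assert io_output(lv, r) == pytest.approx(io_output(lv, io_fig) - dg)

    def test_unit_compression_shifts_below_breakpoint_only(self):
        io = IOFunction(30.0, 1.0, 50.0)
        r = apply_gain_reduction(io, 5.0)
        assert io_output(20.0, r) == pytest.approx(io_output(20.0, io) - 5.0)
        assert r.breakpoint_dB == io.breakpoint_dB


class TestPlaceExcitation:
    def test_off_frequency_is_linear_and_gain_invariant(self, listener):
        tone = StimulusSpec.tone("masker", 2.4, 65.0, duration_ms=20.0)
        full = place_excitation(tone, 4.0, listener)
        reduced = place_excitation(tone, 4.0, listener,
                                   gain_reduced_io=listener.io.reduced(10.0))
        assert full == pytest.approx(65.0 - 9.0)
        assert reduced == full

    def test_on_frequency_through_io(self, listener):
        tone = StimulusSpec.tone("masker", 4.0, 16.0, duration_ms=20.0)
        assert place_excitation(tone, 4.0, listener) == pytest.approx(56.0)

    def test_bbn_through_erb_conversion(self, listener):
        noise = StimulusSpec.noise("precursor", 64.0)
        # 64 dB over 80-10000 Hz -> 24.03 dB spectrum level -> 50.62 dB/ERB
        # -> compressive segment output 82.12 dB
        assert place_excitation(noise, 4.0, listener) == pytest.approx(82.12, abs=0.01)

    def test_noise_band_must_cover_signal(self, listener):
        noise = StimulusSpec.noise("precursor", 60.0, 80.0, 2_000.0)
        with pytest.raises(ValueError):
            place_excitation(noise, 4.0, listener)

    def test_silence_returns_internal_noise(self, listener):
        assert place_excitation(StimulusSpec.silence(), 4.0, listener) == \
            listener.internal_noise_dB

    def test_on_frequency_rule_uses_one_erb(self):
        assert is_on_frequency(4.0, 4.0)
        assert is_on_frequency(4.3, 4.0)       # within 456 Hz
        assert not is_on_frequency(2.4, 4.0)   # nearly an octave below

    @given(st.floats(0, 30))
    @settings(max_examples=25)
    def test_off_frequency_invariant_to_any_reduction(self, listener, dg):
        tone = StimulusSpec.tone("masker", 2.4, 70.0, duration_ms=20.0)
        out = place_excitation(tone, 4.0, listener,
                               gain_reduced_io=listener.io.reduced(dg))
        assert out == pytest.approx(61.0)


class TestElicitedGainReduction:
    def test_silence_elicits_nothing(self, listener):
        assert elicited_gain_reduction(StimulusSpec.silence(), listener) == 0.0

    def test_mechanistic_level_slope_ratio_equals_compression(self):
        # above the breakpoint the on-frequency elicitation slope is s*c,
        # the off-frequency slope is s (numeric differentiation)
        io = IOFunction(45.0, 0.41, 35.0)
        rule = GainReductionRule(mode="mechanistic", elicitation_slope_s=0.80,
                                 elicitation_floor_E0=40.0, cap_dB=45.0)
        lst = ListenerProfile.calibrated("m", 10.0, io, gain_rule=rule)
        h = 0.5

        def slope(freq, level):
            lo = elicited_gain_reduction(
                StimulusSpec.tone("precursor", freq, level), lst)
            hi = elicited_gain_reduction(
                StimulusSpec.tone("precursor", freq, level + h), lst)
            return (hi - lo) / h

        on = slope(4.0, 70.0)    # above breakpoint, compressive path
        off = slope(2.4, 80.0)   # linear path
        assert off == pytest.approx(0.80, abs=1e-6)
        assert on == pytest.approx(0.80 * 0.41, abs=1e-6)
        assert on / off == pytest.approx(0.41, abs=1e-6)

    def test_cap_clamps(self):
        io = IOFunction(40.0, 0.3, 40.0)
        rule = GainReductionRule(mode="mechanistic", elicitation_slope_s=1.0,
                                 elicitation_floor_E0=0.0, cap_dB=20.0)
        lst = ListenerProfile.calibrated("c", 10.0, io, gain_rule=rule)
        dg = elicited_gain_reduction(StimulusSpec.tone("precursor", 4.0, 90.0), lst)
        assert dg == 20.0

    def test_empirical_mode_and_unknown_class(self):
        io = IOFunction(40.0, 0.3, 40.0)
        rule = GainReductionRule(
            mode="empirical",
            empirical_intercepts={"on_tone": -4.32},
            empirical_slopes={"on_tone": 0.33})
        lst = ListenerProfile.calibrated("e", 10.0, io, gain_rule=rule)
        dg = elicited_gain_reduction(StimulusSpec.tone("precursor", 4.0, 60.0), lst)
        assert dg == pytest.approx(-4.32 + 0.33 * 60.0)
        with pytest.raises(ValueError):
            elicited_gain_reduction(StimulusSpec.tone("precursor", 2.4, 80.0), lst)


class TestListenerProfile:
    def test_calibration_sets_noise_floor(self, listener, io_fig):
        assert listener.internal_noise_dB == pytest.approx(
            io_output(12.0, io_fig) - listener.criterion_smr_dB)

    def test_json_round_trip(self, listener):
        clone = ListenerProfile.from_json(listener.to_json())
        assert clone == listener

    def test_invalid_spread_rejected(self, io_fig):
        with pytest.raises(ValueError):
            ListenerProfile.calibrated("x", 10.0, io_fig,
                                       psychometric_spread_dB=0.0)
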