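"""Control-differenced mass-specific rates, gating and summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventflux.flux import (
    AquariumConfig,
    FluxRate,
    GatingPolicy,
    gate_sets,
    net_rate,
    pair_intervals,
    summarize_rates,
    sustained_excretion,
)
from ventflux.voltammetry import IntervalConcentration


def ic(mean, channel="experimental-1", analyte="sulfide", set_index=0,
       is_bdl=False, start_s=0.0):
    return IntervalConcentration(
        channel=channel, analyte=analyte, start_s=start_s, mean_uM=mean,
        n_used=32, n_discarded=10, frac_censored=0.0, is_bdl=is_bdl,
        set_index=set_index,
    )


def aquarium(flow=1.0, volume=2.0, gill=22.56, genus="Alviniconcha"):
    return AquariumConfig(
        id="experimental-1", role="experimental", flow_L_per_h=flow,
        volume_L=volume, total_gill_wet_g=gill, genus=genus,
    )


class TestNetRate:
    def test_sulfide_uptake_hand_arithmetic(self):
        # (5.7 − 66) µM · 1 L/h / 22.56 g
        r = net_rate(ic(5.7), ic(66.0, channel="control"), aquarium())
        assert r.rate_umol_g_h == pytest.approx((5.7 - 66.0) / 22.56)
        assert r.rate_umol_g_h == pytest.approx(-2.673, abs=5e-4)
        assert r.rate_umol_g_h < 0  # net uptake

    def test_equal_concentrations_give_zero(self):
        r = net_rate(ic(50.0), ic(50.0, channel="control"), aquarium())
        assert r.rate_umol_g_h == 0.0

    def test_excretion_against_bdl_reference_is_positive(self):
        exp = ic(73.0, analyte="thiosulfate")
        ref = ic(10.0, channel="input", analyte="thiosulfate", is_bdl=True)
        r = net_rate(exp, ref, aquarium(flow=0.5, gill=36.85))
        assert r.rate_umol_g_h == pytest.approx(73.0 * 0.5 / 36.85)
        assert r.rate_umol_g_h == pytest.approx(0.990, abs=1e-3)
        assert r.flag == "bdl"

    def test_both_sides_bdl_flagged_pair(self):
        r = net_rate(
            ic(0.1, is_bdl=True), ic(0.1, channel="control", is_bdl=True), aquarium()
        )
        assert r.flag == "bdl_pair"
        assert r.rate_umol_g_h == 0.0

    def test_mismatches_and_zero_gill_error(self):
        with pytest.raises(ValueError, match="analyte"):
            net_rate(ic(5.0), ic(5.0, analyte="thiosulfate"), aquarium())
        with pytest.raises(ValueError, match="set"):
            net_rate(ic(5.0), ic(5.0, set_index=1), aquarium())
        with pytest.raises(ValueError, match="gill"):
            net_rate(ic(5.0), ic(6.0), aquarium(gill=0.0))

    @given(
        c_exp=st.floats(0, 500),
        c_ref=st.floats(0, 500),
        flow=st.floats(0.1, 10),
        gill=st.floats(1, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_flow_linearity(self, c_exp, c_ref, flow, gill):
        aq = aquarium(flow=flow, gill=gill)
        fwd = net_rate(ic(c_exp), ic(c_ref, channel="control"), aq).rate_umol_g_h
        rev = net_rate(ic(c_ref), ic(c_exp, channel="control"), aq).rate_umol_g_h
        assert fwd == pytest.approx(-rev, abs=1e-12)
        double = net_rate(
            ic(c_exp), ic(c_ref, channel="control"), aquarium(flow=2 * flow, gill=gill)
        ).rate_umol_g_h
        assert double == pytest.approx(2 * fwd, rel=1e-12, abs=1e-12)


class TestGating:
    def test_elapsed_time_bound_dominates(self):
        aq = aquarium(flow=1.0, volume=2.0)
        _, cutoff = gate_sets([], aq, GatingPolicy(10.0, 3.0))
        assert cutoff == 10.0

    def test_turnover_bound_dominates(self):
        aq = aquarium(flow=1.0, volume=8.0)
        with pytest.warns(UserWarning):
            _, cutoff = gate_sets([], aq, GatingPolicy(10.0, 3.0))
        assert cutoff == 24.0

    def test_filter_keeps_only_post_cutoff_intervals(self):
        early = ic(5.0, start_s=2 * 3600.0)
        late = ic(5.0, start_s=12 * 3600.0)
        kept, cutoff = gate_sets([early, late], aquarium(), GatingPolicy(10.0, 3.0))
        assert cutoff == 10.0
        assert kept == [late]


class TestSummaries:
    def test_two_point_mean_and_sd(self):
        rates = [
            FluxRate("A", "sulfide", i, v, "control")
            for i, v in enumerate([-7.0, -6.6])
        ]
        s = summarize_rates(rates)
        assert s.mean_rate_umol_g_h.iloc[0] == pytest.approx(-6.8)
        assert s.sd_rate_umol_g_h.iloc[0] == pytest.approx(math.sqrt(0.08), rel=1e-9)
        assert s.direction.iloc[0] == "uptake"

    def test_single_rate_reports_sd_zero(self):
        s = summarize_rates([FluxRate("A", "sulfide", 0, -3.0, "control")])
        assert s.sd_rate_umol_g_h.iloc[0] == 0.0
        assert s.n_sets.iloc[0] == 1

    def test_constant_rates_have_zero_sd(self):
        rates = [FluxRate("A", "sulfide", i, 2.5, "input") for i in range(5)]
        s = summarize_rates(rates)
        assert s.sd_rate_umol_g_h.iloc[0] == 0.0
        assert s.direction.iloc[0] == "excretion"

    def test_bdl_pairs_excluded_and_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_rates([])
        with pytest.raises(ValueError):
            summarize_rates([FluxRate("A", "sulfide", 0, 0.0, "c", flag="bdl_pair")])


class TestPairing:
    def test_per_set_pairing_uses_same_set_reference(self):
        ics = [
            ic(10.0, set_index=0), ic(20.0, set_index=1),
            ic(1.0, channel="control", set_index=0),
            ic(2.0, channel="control", set_index=1),
        ]
        pairs = pair_intervals(ics, "experimental-1", "control", "sulfide")
        assert [(e.mean_uM, r.mean_uM) for e, r in pairs] == [(10.0, 1.0), (20.0, 2.0)]

    def test_interpolated_reference_between_neighbours(self):
        ics = [
            ic(10.0, set_index=0, start_s=0.0),
            ic(1.0, channel="control", set_index=0, start_s=5400.0),
            ic(3.0, channel="control", set_index=1, start_s=12600.0),
        ]
        pairs = pair_intervals(
            ics, "experimental-1", "control", "sulfide", mode="interpolate"
        )
        # exp starts at 0 s, before the first reference: clamps to 1.0
        assert pairs[0][1].mean_uM == pytest.approx(1.0)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            pair_intervals([ic(10.0)], "experimental-1", "control", "sulfide")

    def test_rate_and_variation_modes_agree_when_control_equals_input(self):
        # same reference concentrations on both channels -> identical rates
        aq = aquarium()
        exp = ic(30.0)
        as_control = net_rate(exp, ic(60.0, channel="control"), aq)
        as_input = net_rate(exp, ic(60.0, channel="input"), aq)
        assert as_control.rate_umol_g_h == as_input.rate_umol_g_h


class TestSustainedExcretion:
    def test_two_consecutive_detections_qualify(self):
        pairs = [
            (ic(50.0, analyte="thiosulfate", set_index=i),
             ic(0.0, channel="input", analyte="thiosulfate", set_index=i, is_bdl=True))
            for i in range(3)
        ]
        assert sustained_excretion(pairs)

    def test_isolated_detection_does_not_qualify(self):
        def pair(i, exp_bdl):
            return (
                ic(0.0 if exp_bdl else 50.0, analyte="thiosulfate",
                   set_index=i, is_bdl=exp_bdl),
                ic(0.0, channel="input", analyte="thiosulfate",
                   set_index=i, is_bdl=True),
            )
        pairs = [pair(0, False), pair(1, True), pair(2, False), pair(3, True)]
        assert not sustained_excretion(pairs)

    def test_compound_present_in_reference_does_not_qualify(self):
        pairs = [
            (ic(50.0, analyte="thiosulfate", set_index=i),
             ic(45.0, channel="input", analyte="thiosulfate", set_index=i))
            for i in range(4)
        ]
        assert not sustained_excretion(pairs)
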