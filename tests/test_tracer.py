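"""Tracer mass-balance inversion: hand oracles, simulator oracles, properties."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from omzox.simulate import SimulationConfig, simulate_bottle
from omzox.tracer import (
    TracerIncubation,
    ammonia_oxidation_rate,
    atom_percent_to_delta,
    carrier_correction,
    correct_tracer_contamination,
    delta_to_atom_percent,
    exponential_average_atom_percent,
    nitrite_oxidation_rate,
    spike_atom_percent,
)


class TestSpikeAtomPercent:
    def test_no_spike_returns_pool_unchanged(self):
        assert spike_atom_percent(100.0, 0.3663, 0.0) == pytest.approx(0.3663)

    def test_hand_mass_balance(self):
        # (0.3663*100 + 98*10) / 110
        expected = (0.3663 * 100 + 98 * 10) / 110
        assert spike_atom_percent(100.0, 0.3663, 10.0, 98.0) == pytest.approx(expected)
        assert expected == pytest.approx(9.242, abs=2e-3)

    def test_equal_concentrations_give_arithmetic_mean(self):
        assert spike_atom_percent(50.0, 2.0, 50.0, 10.0) == pytest.approx(6.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            spike_atom_percent(0.0, 1.0, 0.0, 98.0)


class TestExponentialAverage:
    def test_no_dilution_is_identity(self):
        assert exponential_average_atom_percent(9.0, 0.0, 100.0, 1.0) == pytest.approx(9.0)

    def test_strong_dilution_limit_is_zero(self):
        assert exponential_average_atom_percent(9.0, 1e9, 100.0, 1.0) < 1e-6

    def test_against_numeric_integral(self):
        # independent oracle: time average of n0 exp(-k tau) by quadrature
        n0, R_AO, NO2, t = 10.0, math.log(2.0) * 100.0, 100.0, 1.0
        k = R_AO / NO2
        oracle = quad(lambda tau: n0 * math.exp(-k * tau), 0.0, t)[0] / t
        got = exponential_average_atom_percent(n0, R_AO, NO2, t)
        assert got == pytest.approx(oracle, rel=1e-10)
        assert got == pytest.approx(7.213, abs=1e-3)

    def test_series_branch_continuous_with_exact_branch(self):
        lo = exponential_average_atom_percent(10.0, 9.9e-7, 1.0, 1.0)
        hi = exponential_average_atom_percent(10.0, 1.1e-6, 1.0, 1.0)
        assert lo == pytest.approx(hi, rel=1e-6)


class TestContaminationCorrection:
    def test_zero_contamination_is_identity(self):
        assert correct_tracer_contamination(1.5, 0.4, 20_000.0, 10.0) == pytest.approx(1.5)

    def test_full_attribution_returns_background(self):
        n_o = 0.3663
        contam = 0.01
        excess = 98.0 * contam * 10.0 / (20_000.0 + contam * 10.0)
        out = correct_tracer_contamination(
            n_o + excess, n_o, 20_000.0, 10.0, contam_fraction=contam
        )
        assert out == pytest.approx(n_o, abs=1e-9)

    def test_hand_mass_balance(self):
        # 1% of a 10 nM spike at 98 at% entering a 20,000 nM pool
        raw = 1.0
        out = correct_tracer_contamination(
            raw, 0.3663, 20_000.0, 10.0, contam_fraction=0.01
        )
        assert raw - out == pytest.approx(98.0 * 0.01 * 10.0 / 20_000.0, rel=1e-2)

    def test_never_below_background_minus_precision(self):
        out = correct_tracer_contamination(
            0.3663, 0.3663, 100.0, 10.0, contam_fraction=0.05, atpct_sd=1e-4
        )
        assert out >= 0.3663 - 1e-4


class TestNitriteOxidationRate:
    def _inc(self, **kw):
        base = dict(
            n_t_raw=0.4663,
            n_oNO3=0.3663,
            NO3_conc=20_000.0,
            NO2_conc_initial=90.0,
            spike_conc=10.0,
            t_days=1.0,
            atpct_sd=1e-4,
        )
        base.update(kw)
        return TracerIncubation(**base)

    def test_no_label_transfer_gives_zero_rate(self):
        est = nitrite_oxidation_rate(self._inc(n_t_raw=0.3663))
        assert est.value == 0.0
        assert not est.detectable

    def test_hand_evaluation(self):
        # 0.1 at% excess, 20 uM nitrate, nbar 10 at%, 1 day -> 200 nmol/L/day;
        # pool at% chosen so the spiked mixture lands at exactly 10 at%
        pool_atpct = (10.0 * 100.0 - 98.0 * 10.0) / 90.0
        inc = self._inc(NO2_atpct_initial=pool_atpct)
        est = nitrite_oxidation_rate(inc)
        assert est.value == pytest.approx(0.1 * 20_000.0 / (10.0 * 1.0), rel=1e-9)

    def test_negative_excess_reported_as_zero_not_negative(self):
        est = nitrite_oxidation_rate(self._inc(n_t_raw=0.30))
        assert est.value == 0.0
        assert not est.detectable

    def test_detectability_threshold_is_three_propagated_sds(self):
        sd = 1e-4
        noise = math.sqrt(2.0) * sd
        just_below = self._inc(n_t_raw=0.3663 + 2.9 * noise, atpct_sd=sd)
        just_above = self._inc(n_t_raw=0.3663 + 3.1 * noise, atpct_sd=sd)
        assert not nitrite_oxidation_rate(just_below).detectable
        assert nitrite_oxidation_rate(just_above).detectable

    def test_recovers_simulated_rate_within_5pct(self):
        # simulator oracle: constant true rate 100, stable nitrite, no
        # ammonia oxidation, noise off
        cfg = SimulationConfig(
            initial_O2=100_000.0, initial_NO2=4625.0, initial_NO3=20_000.0,
            f15_NO2=0.09, vmax_NO=100.0, Km_NO=1e-6, duration=24.0, dt=0.01,
        )
        s = simulate_bottle(cfg)
        inc = TracerIncubation(
            n_t_raw=100.0 * s.f15_NO3[-1],
            n_oNO3=100.0 * s.f15_NO3[0],
            NO3_conc=cfg.initial_NO3,
            NO2_conc_initial=4625.0,
            spike_conc=0.0,
            t_days=1.0,
            NO2_atpct_initial=9.0,
            atpct_sd=1e-6,
        )
        est = nitrite_oxidation_rate(inc)
        assert est.value == pytest.approx(100.0, rel=0.05)

    def test_ignoring_dilution_biases_rate_low(self):
        # ammonia oxidation dilutes the labeled pool; using the initial
        # at% instead of the exponential average must underestimate
        # a strong label (30 at%) keeps the natural-abundance share of the
        # denominator negligible, isolating the dilution effect under test
        NO2 = 1000.0
        R_AO = 400.0
        cfg = SimulationConfig(
            initial_O2=100_000.0, initial_NH4=100_000.0, initial_NO2=NO2,
            initial_NO3=200_000.0, f15_NH4=0.0, f15_NO2=0.30,
            R_AO=R_AO, vmax_NO=R_AO, Km_NO=1e-6, duration=24.0, dt=0.005,
        )
        s = simulate_bottle(cfg)
        common = dict(
            n_t_raw=100.0 * s.f15_NO3[-1],
            n_oNO3=100.0 * s.f15_NO3[0],
            NO3_conc=cfg.initial_NO3,
            NO2_conc_initial=NO2,
            spike_conc=0.0,
            t_days=1.0,
            atpct_sd=1e-6,
        )
        with_dilution = nitrite_oxidation_rate(
            TracerIncubation(**common, R_AO=R_AO, NO2_atpct_initial=30.0)
        )
        without = nitrite_oxidation_rate(
            TracerIncubation(**common, R_AO=0.0, NO2_atpct_initial=30.0)
        )
        assert with_dilution.value == pytest.approx(R_AO, rel=0.05)
        assert without.value < with_dilution.value

    @given(
        excess=st.floats(0.01, 1.0),
        no3=st.floats(1000.0, 50_000.0),
        scale=st.floats(1.1, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_in_inputs(self, excess, no3, scale):
        def rate(excess, no3, nbar_boost=1.0, t=1.0):
            inc = TracerIncubation(
                n_t_raw=0.3663 + excess, n_oNO3=0.3663, NO3_conc=no3,
                NO2_conc_initial=100.0, spike_conc=10.0, t_days=t,
                NO2_atpct_initial=0.3663 * nbar_boost, atpct_sd=1e-9,
            )
            return nitrite_oxidation_rate(inc).value

        base = rate(excess, no3)
        assert rate(excess * scale, no3) > base
        assert rate(excess, no3 * scale) > base
        assert rate(excess, no3, nbar_boost=scale) < base
        assert rate(excess, no3, t=scale) < base

    def test_spike_band_warning(self):
        with pytest.warns(UserWarning, match="5-10%"):
            TracerIncubation(
                n_t_raw=0.5, n_oNO3=0.37, NO3_conc=1000.0, NO2_conc_initial=100.0,
                spike_conc=50.0, t_days=1.0, validate_spike_band=True,
            )


class TestAmmoniaOxidationRate:
    def test_no_change_gives_zero(self):
        est = ammonia_oxidation_rate(0.4, 0.4, 10_000.0, 20.0, 1.0)
        assert est.value == 0.0

    def test_hand_evaluation(self):
        est = ammonia_oxidation_rate(0.45, 0.40, 10_000.0, 20.0, 1.0)
        assert est.value == pytest.approx(25.0, rel=1e-9)

    def test_recovers_simulated_rate_within_5pct(self):
        cfg = SimulationConfig(
            initial_O2=100_000.0, initial_NH4=1950.0, initial_NO2=5000.0,
            initial_NO3=20_000.0, f15_NH4=0.20, R_AO=50.0, duration=24.0, dt=0.01,
        )
        s = simulate_bottle(cfg)
        prod0 = (s.NO2[0] * s.f15_NO2[0] + s.NO3[0] * s.f15_NO3[0]) / (
            s.NO2[0] + s.NO3[0]
        )
        prodt = (s.NO2[-1] * s.f15_NO2[-1] + s.NO3[-1] * s.f15_NO3[-1]) / (
            s.NO2[-1] + s.NO3[-1]
        )
        est = ammonia_oxidation_rate(
            100.0 * prodt, 100.0 * prod0, s.NO2[0] + s.NO3[0], 20.0, 1.0,
            atpct_sd=1e-9,
        )
        assert est.value == pytest.approx(50.0, rel=0.05)


class TestCarrierCorrection:
    def test_no_carrier_is_identity(self):
        assert carrier_correction(5.0, 100.0, 0.0, 4.0) == pytest.approx(5.0)

    def test_equal_concentration_mixing_solved_by_hand(self):
        assert carrier_correction(5.0, 50.0, 50.0, 4.0) == pytest.approx(6.0)

    def test_degenerate_mixing_identity(self):
        assert carrier_correction(5.0, 30.0, 70.0, 5.0) == pytest.approx(5.0)

    @given(
        d_sample=st.floats(-10.0, 30.0),
        d_carrier=st.floats(-10.0, 30.0),
        sample=st.floats(5.0, 500.0),
        carrier=st.floats(0.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_of_forward_mixing(self, d_sample, d_carrier, sample, carrier):
        mixed = (d_sample * sample + d_carrier * carrier) / (sample + carrier)
        back = carrier_correction(mixed, sample, carrier, d_carrier)
        assert back == pytest.approx(d_sample, abs=1e-9)


class TestDeltaConversions:
    def test_delta_zero_is_natural_abundance(self):
        assert delta_to_atom_percent(0.0) == pytest.approx(0.36630, abs=5e-6)

    def test_half_labeled_closed_form(self):
        expected = (1.0 / 0.0036765 - 1.0) * 1000.0
        assert atom_percent_to_delta(50.0) == pytest.approx(expected, rel=1e-12)

    @given(delta=st.floats(-900.0, 10_000.0))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_identity(self, delta):
        assert atom_percent_to_delta(delta_to_atom_percent(delta)) == pytest.approx(
            delta, abs=1e-10
        )
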