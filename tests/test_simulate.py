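"""Forward-simulator behavior: limits, conservation, convergence, design."""

import math
from dataclasses import replace

import numpy as np
import pytest

from omzox.simulate import (
    SimulationConfig,
    StationTemplate,
    amz_template,
    child_seed,
    default_scenarios,
    observe_bottle,
    simulate_bottle,
    simulate_dual_isotopes,
    simulate_experiment,
    simulate_profile,
    simulate_profile_isotopes,
)


class TestBottleDynamics:
    def test_null_dynamics_leaves_state_constant(self):
        cfg = SimulationConfig(duration=24.0, dt=0.1)
        s = simulate_bottle(cfg)
        for arr, init in [
            (s.O2, cfg.initial_O2),
            (s.NH4, cfg.initial_NH4),
            (s.NO2, cfg.initial_NO2),
            (s.NO3, cfg.initial_NO3),
        ]:
            assert np.all(arr == init)

    def test_zero_order_limit_half_mole_stoichiometry(self):
        # saturating O2 and nitrite: 100 nmol/L/day oxidized for 24 h
        # consumes exactly half as much O2
        cfg = SimulationConfig(
            initial_O2=500.0, initial_NO2=5000.0, vmax_NO=100.0, Km_NO=1e-6,
            duration=24.0, dt=0.01,
        )
        s = simulate_bottle(cfg)
        assert s.NO3[-1] - s.NO3[0] == pytest.approx(100.0, rel=1e-5)
        assert s.O2[-1] - s.O2[0] == pytest.approx(-50.0, rel=1e-5)

    def test_label_dilution_matches_exponential_closed_form(self):
        # nitrite production balanced by consumption, unlabeled ammonium
        # source: the nitrite pool's label halves in one day when
        # R_AO/[NO2-] = ln 2 per day
        NO2 = 1000.0
        k = math.log(2.0)
        cfg = SimulationConfig(
            initial_O2=1e6, initial_NH4=1e6, initial_NO2=NO2, initial_NO3=20_000.0,
            f15_NH4=0.0, f15_NO2=0.5, R_AO=NO2 * k, vmax_NO=NO2 * k, Km_NO=1e-6,
            duration=24.0, dt=0.005,
        )
        s = simulate_bottle(cfg)
        assert s.NO2[-1] == pytest.approx(NO2, rel=1e-6)
        assert s.f15_NO2[-1] == pytest.approx(0.25, rel=1e-4)

    def test_first_order_limit_exponential_o2_drawdown(self):
        # Km >> O2: drawdown is exponential with k = 0.5 * vmax/Km (the
        # half-mole O2 stoichiometry scales the N-rate constant)
        cfg = SimulationConfig(
            initial_O2=100.0, initial_NO2=1e6, vmax_NO=1000.0, Km_NO=1e6,
            duration=24.0, dt=0.005,
        )
        s = simulate_bottle(cfg)
        k = 0.5 * cfg.vmax_NO / cfg.Km_NO  # per day
        expected = cfg.initial_O2 * math.exp(-k * 1.0)
        assert s.O2[-1] == pytest.approx(expected, rel=5e-3)

    def test_nonfinite_state_aborts_with_step_diagnostic(self):
        cfg = SimulationConfig(duration=1.0, dt=0.1, vmax_NO=1e308, Km_NO=1e-6)
        with pytest.raises(RuntimeError, match=r"step \d+"):
            simulate_bottle(cfg)

    def test_o2_clipped_at_zero_and_consumption_halts(self):
        cfg = SimulationConfig(
            initial_O2=50.0, initial_NO2=5000.0, vmax_NO=2000.0, Km_NO=10.0,
            duration=24.0, dt=0.01,
        )
        s = simulate_bottle(cfg)
        assert np.all(s.O2 >= 0.0)
        # once O2 is gone, nitrite oxidation stops: NO3 gain bounded by 2x O2
        assert s.NO3[-1] - s.NO3[0] <= 2.0 * cfg.initial_O2 + 1.0


class TestConservation:
    @pytest.mark.parametrize("name", ["omz_edge", "scm", "snm"])
    def test_budgets_close_on_shipped_scenarios(self, name):
        cfg = replace(default_scenarios()[name], f15_NO2=0.09)
        s = simulate_bottle(cfg)
        assert s.n_budget_max_rel_err() < 1e-6
        assert s.n15_budget_max_rel_err() < 1e-6
        assert s.o2_budget_rel_err() < 1e-6

    def test_halving_dt_changes_endpoints_under_point1_percent(self, scm_like_config):
        coarse = simulate_bottle(replace(scm_like_config, dt=0.02))
        fine = simulate_bottle(replace(scm_like_config, dt=0.01))
        for a, b in [
            (coarse.O2[-1], fine.O2[-1]),
            (coarse.NO2[-1], fine.NO2[-1]),
            (coarse.NO3[-1], fine.NO3[-1]),
        ]:
            assert abs(a - b) / max(abs(b), 1.0) < 1e-3


class TestObservation:
    def test_zero_noise_zero_limit_is_identity(self, scm_like_series):
        cfg = replace(
            scm_like_series.config, sensor_sd=0.0, sensor_detection_limit=0.0
        )
        obs = observe_bottle(scm_like_series, cfg, n_obs=5)
        idx = np.searchsorted(scm_like_series.times, obs.times)
        assert np.allclose(obs.DO, scm_like_series.O2[idx])
        assert not obs.censored.any()

    def test_below_detection_reported_at_limit_and_censored(self):
        cfg = SimulationConfig(initial_O2=4.0, sensor_detection_limit=10.0, duration=1.0, dt=0.1)
        s = simulate_bottle(cfg)
        obs = observe_bottle(s, n_obs=3)
        assert np.all(obs.DO == 10.0)
        assert obs.censored.all()

    def test_fixed_seed_reproduces_observation(self, scm_like_series):
        cfg = replace(scm_like_series.config, sensor_sd=3.0, atpct_sd=1e-4, seed=42)
        a = observe_bottle(scm_like_series, cfg)
        b = observe_bottle(scm_like_series, cfg)
        assert np.array_equal(a.DO, b.DO)
        assert a.record == b.record


class TestExperiment:
    DO_LEVELS = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10_000.0, 15_000.0, 20_000.0)

    def test_eight_levels_three_treatments_give_24_bottles(self):
        base = SimulationConfig(duration=2.0, dt=0.05)
        obs = simulate_experiment(base, self.DO_LEVELS, seed=1)
        assert len(obs) == 24
        assert len({o.bottle_id for o in obs}) == 24

    def test_single_cell_matches_observe_bottle(self):
        base = SimulationConfig(duration=2.0, dt=0.05, sensor_sd=1.0)
        (obs,) = simulate_experiment(base, [500.0], treatments=("unlabeled",), seed=3)
        cfg = replace(base, initial_O2=500.0, seed=child_seed(3, 0, 0))
        direct = observe_bottle(simulate_bottle(cfg), n_obs=13)
        assert np.array_equal(obs.DO, direct.DO)

    def test_same_seed_reproduces_collection(self):
        base = SimulationConfig(duration=2.0, dt=0.05, sensor_sd=2.0)
        a = simulate_experiment(base, self.DO_LEVELS[:3], seed=9)
        b = simulate_experiment(base, self.DO_LEVELS[:3], seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.DO, y.DO)
            assert x.record == y.record

    def test_adding_levels_does_not_shift_earlier_noise(self):
        base = SimulationConfig(duration=2.0, dt=0.05, sensor_sd=2.0)
        short = simulate_experiment(base, self.DO_LEVELS[:2], seed=9)
        full = simulate_experiment(base, self.DO_LEVELS[:4], seed=9)
        assert np.array_equal(short[0].DO, full[0].DO)

    def test_empty_do_levels_rejected(self):
        with pytest.raises(ValueError):
            simulate_experiment(SimulationConfig(), [], seed=0)


class TestProfile:
    def test_no_snm_term_means_no_nitrite(self):
        rows, _ = simulate_profile(StationTemplate(snm_amplitude=0.0))
        assert all(r["NO2_nM"] == 0.0 for r in rows)

    def test_amz_template_accumulates_over_1uM_nitrite_below_oxycline(self):
        t = amz_template()
        rows, _ = simulate_profile(t)
        deep = [r for r in rows if r["depth_m"] > t.oxycline_depth]
        assert max(r["NO2_nM"] for r in deep) > 1000.0

    def test_single_depth_gives_single_row(self):
        t = StationTemplate(depths=np.array([100.0]))
        rows, configs = simulate_profile(t)
        assert len(rows) == 1 and len(configs) == 1

    def test_non_monotone_depth_grid_rejected(self):
        with pytest.raises(ValueError):
            StationTemplate(depths=np.array([10.0, 30.0, 20.0]))


class TestDualIsotopes:
    def test_equal_epsilon_no_reox_stays_on_one_to_one_line(self):
        f = np.linspace(1.0, 0.2, 30)
        d15, d18 = simulate_dual_isotopes(f, 25.0, 25.0, 0.0, 6.0, 2.0)
        assert np.allclose((d15 - 6.0) - (d18 - 2.0), 0.0, atol=1e-9)

    def test_reoxidation_drives_deviation_negative(self):
        f = np.linspace(0.95, 0.3, 20)
        d15, d18 = simulate_dual_isotopes(f, 25.0, 25.0, 0.3, 6.0, 2.0, delta18_water=0.0)
        dev = (d15 - 6.0) - (d18 - 2.0)
        assert np.all(dev < 0.0)

    def test_f_of_one_returns_initial_deltas(self):
        d15, d18 = simulate_dual_isotopes([1.0], 25.0, 25.0, 0.3, 6.0, 2.0)
        assert d15[0] == pytest.approx(6.0)
        assert d18[0] == pytest.approx(2.0)

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            simulate_dual_isotopes([0.0], 25.0, 25.0)

    def test_profile_overprinting_peaks_in_scm_band(self):
        t = amz_template()
        d15, d18 = simulate_profile_isotopes(t)
        dev = (d15 - d15[0]) - (d18 - d18[0])
        center, width, _ = t.chl_peaks[1]
        peak_depth = t.depths[np.argmin(dev)]
        assert abs(peak_depth - center) <= 2 * width
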