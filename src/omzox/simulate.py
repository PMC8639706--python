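"""Forward simulator of bottle incubations and depth profiles.

The process model is a four-pool box model of a sealed incubation bottle:
dissolved O2 and the three inorganic N pools (NH4+, NO2-, NO3-), with the
15N content of each N pool tracked explicitly so tracer experiments can be
emulated. Processes:

* ammonia oxidation (NH4+ -> NO2-) at a fixed rate ``R_AO``, consuming
  1.5 mol O2 per mol N;
* nitrite oxidation (NO2- -> NO3-) following Michaelis-Menten kinetics in
  dissolved O2 (``vmax_NO``, ``Km_NO``), consuming 0.5 mol O2 per mol N;
* heterotrophic respiration, Michaelis-Menten in O2 (``vmax_het``,
  ``Km_het``), consuming O2 only;
* nitrate reduction (NO3- -> NO2-) at a fixed rate ``R_NAR`` (anaerobic,
  no O2 term), resupplying the nitrite pool;
* an optional photosynthetic O2 source ``O2_production`` (the secondary
  chlorophyll maximum supports production of order 100 nM-O2 per day).

Label (15N) is advected with the fluxes: ammonia oxidation delivers
nitrite at the ammonium pool's atom fraction, nitrate reduction delivers
nitrite at the nitrate pool's atom fraction, and nitrite oxidation
delivers nitrate at the nitrite pool's atom fraction. No process
fractionates isotopes here; natural-abundance fractionation is handled
separately by the Rayleigh dual-isotope generator.

Integration is fixed-step explicit midpoint (RK2). Every substrate-limited
rate is multiplied by a ramp that falls linearly to zero over the last
1 nM of its substrate, which keeps pools non-negative without event
detection. Flux integrals are accumulated with the same midpoint
quadrature as the state update so mass and O2 budgets close to float
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import (
    HOURS_PER_DAY,
    NAT_ABUNDANCE_AT_PCT,
    O2_PER_NH4_OXIDIZED,
    O2_PER_NO2_OXIDIZED,
)

__all__ = [
    "SimulationConfig",
    "BottleTimeSeries",
    "BottleObservation",
    "StationTemplate",
    "simulate_bottle",
    "observe_bottle",
    "simulate_experiment",
    "simulate_profile",
    "simulate_profile_isotopes",
    "amz_template",
    "simulate_dual_isotopes",
    "simulate_rate_vs_do",
    "child_seed",
    "default_scenarios",
]

#: Natural-abundance 15N atom fraction (dimensionless).
NAT_FRAC = NAT_ABUNDANCE_AT_PCT / 100.0

#: Substrate ramp width (nM): rates fall linearly to 0 over the last 1 nM.
RAMP_NM = 1.0


@dataclass
class SimulationConfig:
    """Initial state, process rates, and observation noise for one bottle.

    Concentrations in nM, rates in nmol L^-1 day^-1, times in hours,
    isotope labels as atom fractions (0-1).
    """

    initial_O2: float = 400.0
    initial_NH4: float = 100.0
    initial_NO2: float = 2000.0
    initial_NO3: float = 20000.0
    f15_NH4: float = NAT_FRAC
    f15_NO2: float = NAT_FRAC
    f15_NO3: float = NAT_FRAC
    R_AO: float = 0.0
    vmax_NO: float = 0.0
    Km_NO: float = 100.0
    vmax_het: float = 0.0
    Km_het: float = 1000.0
    R_NAR: float = 0.0
    O2_production: float = 0.0
    duration: float = 24.0  # hours
    dt: float = 0.01  # hours
    seed: int = 0
    sensor_sd: float = 0.0  # nM
    sensor_detection_limit: float = 10.0  # nM (trace-level spots; 100 for wide-range)
    atpct_sd: float = 0.0  # at%
    o2_per_nh4: float = O2_PER_NH4_OXIDIZED
    o2_per_no2: float = O2_PER_NO2_OXIDIZED

    def __post_init__(self) -> None:
        for name in ("initial_O2", "initial_NH4", "initial_NO2", "initial_NO3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f15_NH4", "f15_NO2", "f15_NO3"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.Km_NO <= 0 or self.Km_het <= 0:
            raise ValueError("Km values must be positive")
        for name in ("R_AO", "vmax_NO", "vmax_het", "R_NAR", "sensor_sd", "atpct_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BottleTimeSeries:
    """Latent (noise-free) state trajectory of one simulated bottle."""

    times: np.ndarray  # hours
    O2: np.ndarray
    NH4: np.ndarray
    NO2: np.ndarray
    NO3: np.ndarray
    f15_NH4: np.ndarray
    f15_NO2: np.ndarray
    f15_NO3: np.ndarray
    config: SimulationConfig
    label_treatment: str = "unlabeled"
    #: cumulative nmol L^-1 processed by each pathway (midpoint quadrature)
    flux_integrals: dict = field(default_factory=dict)
    #: total clipped amounts per pool (non-negativity guard bookkeeping)
    clip_ledger: dict = field(default_factory=dict)

    def total_n(self) -> np.ndarray:
        return self.NH4 + self.NO2 + self.NO3

    def total_15n(self) -> np.ndarray:
        return (
            self.NH4 * self.f15_NH4 + self.NO2 * self.f15_NO2 + self.NO3 * self.f15_NO3
        )

    def n_budget_max_rel_err(self) -> float:
        """Largest relative drift of total N over the trajectory."""
        tot = self.total_n()
        return float(np.max(np.abs(tot - tot[0])) / max(tot[0], 1e-30))

    def n15_budget_max_rel_err(self) -> float:
        """Largest relative drift of total 15N atoms over the trajectory."""
        tot = self.total_15n()
        return float(np.max(np.abs(tot - tot[0])) / max(tot[0], 1e-30))

    def o2_budget_rel_err(self) -> float:
        """Relative closure error of the O2 budget at the endpoint.

        Cumulative drawdown must equal 0.5*int(R_NO) + 1.5*int(R_AO)
        + int(R_het) - int(O2_production), up to the clip ledger.
        """
        cfg = self.config
        fi = self.flux_integrals
        expected_drop = (
            cfg.o2_per_no2 * fi["R_NO"][-1]
            + cfg.o2_per_nh4 * fi["R_AO"][-1]
            + fi["R_het"][-1]
            - fi["O2_production"][-1]
        )
        actual_drop = self.O2[0] - self.O2[-1] + self.clip_ledger.get("O2", 0.0)
        scale = max(abs(expected_drop), abs(self.O2[0]), 1.0)
        return float(abs(actual_drop - expected_drop) / scale)


def _smooth_indicator(s: float, ramp: float = RAMP_NM) -> float:
    """Ramp from 0 at s<=0 to 1 at s>=ramp; substrate-exhaustion guard."""
    if s <= 0.0:
        return 0.0
    if s >= ramp:
        return 1.0
    return s / ramp


def _fluxes(state: np.ndarray, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous fluxes (nmol L^-1 day^-1) and state derivative.

    ``state`` is [O2, NH4, NO2, NO3, A_NH4, A_NO2, A_NO3] with A the 15N
    atom content (nM) of each pool.
    """
    O2, NH4, NO2, NO3, A_NH4, A_NO2, A_NO3 = state
    ind_O2 = _smooth_indicator(O2)
    R_AO = cfg.R_AO * _smooth_indicator(NH4) * ind_O2
    R_NO = (
        cfg.vmax_NO * max(O2, 0.0) / (cfg.Km_NO + max(O2, 0.0))
        * _smooth_indicator(NO2) * ind_O2
    )
    R_het = cfg.vmax_het * max(O2, 0.0) / (cfg.Km_het + max(O2, 0.0)) * ind_O2
    R_NAR = cfg.R_NAR * _smooth_indicator(NO3)

    f_NH4 = A_NH4 / NH4 if NH4 > 1e-12 else 0.0
    f_NO2 = A_NO2 / NO2 if NO2 > 1e-12 else 0.0
    f_NO3 = A_NO3 / NO3 if NO3 > 1e-12 else 0.0

    deriv = np.array(
        [
            cfg.O2_production
            - cfg.o2_per_no2 * R_NO
            - cfg.o2_per_nh4 * R_AO
            - R_het,
            -R_AO,
            R_AO + R_NAR - R_NO,
            R_NO - R_NAR,
            -f_NH4 * R_AO,
            f_NH4 * R_AO + f_NO3 * R_NAR - f_NO2 * R_NO,
            f_NO2 * R_NO - f_NO3 * R_NAR,
        ]
    )
    fluxes = np.array([R_NO, R_AO, R_het, cfg.O2_production])
    return fluxes, deriv


def simulate_bottle(
    config: SimulationConfig, label_treatment: str = "unlabeled"
) -> BottleTimeSeries:
    """Integrate one bottle's state with fixed-step explicit midpoint (RK2)."""
    n_steps = int(round(config.duration / config.dt))
    dt_days = config.dt / HOURS_PER_DAY
    state = np.array(
        [
            config.initial_O2,
            config.initial_NH4,
            config.initial_NO2,
            config.initial_NO3,
            config.initial_NH4 * config.f15_NH4,
            config.initial_NO2 * config.f15_NO2,
            config.initial_NO3 * config.f15_NO3,
        ]
    )
    traj = np.empty((n_steps + 1, 7))
    traj[0] = state
    flux_cum = np.zeros((n_steps + 1, 4))
    clip = {"O2": 0.0, "NH4": 0.0, "NO2": 0.0, "NO3": 0.0}
    pool_names = ("O2", "NH4", "NO2", "NO3")

    for i in range(n_steps):
        _, d1 = _fluxes(state, config)
        mid = state + 0.5 * dt_days * d1
        fx_mid, d2 = _fluxes(mid, config)
        new = state + dt_days * d2
        if not np.all(np.isfinite(new)):
            bad = int(np.argmax(~np.isfinite(new)))
            names = ("O2", "NH4", "NO2", "NO3", "A_NH4", "A_NO2", "A_NO3")
            raise RuntimeError(
                f"nonfinite state at step {i + 1} (t = {(i + 1) * config.dt:.4f} h): "
                f"first offending variable {names[bad]!r}"
            )
        # non-negativity guard; deficits recorded so budgets remain auditable
        for j, name in enumerate(pool_names):
            if new[j] < 0.0:
                clip[name] += -new[j]
                new[j] = 0.0
        np.clip(new[4:], 0.0, None, out=new[4:])
        flux_cum[i + 1] = flux_cum[i] + dt_days * fx_mid
        state = new
        traj[i + 1] = state

    times = np.arange(n_steps + 1) * config.dt
    pools = traj[:, 1:4]
    atoms = traj[:, 4:7]
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(pools > 1e-12, atoms / np.maximum(pools, 1e-300), 0.0)
    return BottleTimeSeries(
        times=times,
        O2=traj[:, 0],
        NH4=traj[:, 1],
        NO2=traj[:, 2],
        NO3=traj[:, 3],
        f15_NH4=fracs[:, 0],
        f15_NO2=fracs[:, 1],
        f15_NO3=fracs[:, 2],
        config=config,
        label_treatment=label_treatment,
        flux_integrals={
            "R_NO": flux_cum[:, 0],
            "R_AO": flux_cum[:, 1],
            "R_het": flux_cum[:, 2],
            "O2_production": flux_cum[:, 3],
        },
        clip_ledger=clip,
    )


@dataclass
class BottleObservation:
    """Noisy observations of one bottle: DO readings plus endpoint chemistry.

    ``record`` is a flat mapping suitable for the tracer and oxygen
    modules and for tidy CSV output.
    """

    bottle_id: str
    times: np.ndarray  # hours, observation times
    DO: np.ndarray  # nM, noisy, censored values reported at the limit
    censored: np.ndarray  # bool
    detection_limit: float
    record: dict


def observe_bottle(
    series: BottleTimeSeries,
    config: SimulationConfig | None = None,
    n_obs: int = 13,
    bottle_id: str = "bottle",
) -> BottleObservation:
    """Sample a latent trajectory into what the instruments would report.

    Gaussian sensor noise (sd ``config.sensor_sd``) is added to DO
    readings at ``n_obs`` evenly spaced times; readings below the
    detection limit are reported at the limit with a censored flag.
    Endpoint pool concentrations and atom percents get Gaussian noise of
    sd ``config.atpct_sd`` on the at% values. Deterministic for a fixed
    ``config.seed``.
    """
    cfg = config if config is not None else series.config
    rng = np.random.default_rng(cfg.seed)
    idx = np.unique(
        np.round(np.linspace(0, len(series.times) - 1, n_obs)).astype(int)
    )
    t_obs = series.times[idx]
    do_latent = series.O2[idx]
    do_obs = do_latent + rng.normal(0.0, cfg.sensor_sd, size=len(idx))
    censored = do_obs < cfg.sensor_detection_limit
    do_obs = np.where(censored, cfg.sensor_detection_limit, do_obs)

    def noisy_atpct(frac: float) -> float:
        return float(
            np.clip(100.0 * frac + rng.normal(0.0, cfg.atpct_sd), 0.0, 100.0)
        )

    t_h = float(series.times[-1])
    record = {
        "bottle_id": bottle_id,
        "treatment": series.label_treatment,
        "t_hours": t_h,
        "DO_start_nM": float(do_obs[0]),
        "DO_end_nM": float(do_obs[-1]),
        "DO_mean_nM": float(np.mean(do_obs)),
        "NH4_nM": float(series.NH4[0]),
        "NO2_nM": float(series.NO2[0]),
        "NO3_nM": float(series.NO3[0]),
        "NO3_end_nM": float(series.NO3[-1]),
        "atpct_NO3_0": noisy_atpct(series.f15_NO3[0]),
        "atpct_NO3_t": noisy_atpct(series.f15_NO3[-1]),
        "atpct_NO2_0": noisy_atpct(series.f15_NO2[0]),
        "atpct_NH4_0": noisy_atpct(series.f15_NH4[0]),
        "atpct_product_0": noisy_atpct(
            (
                series.NO2[0] * series.f15_NO2[0]
                + series.NO3[0] * series.f15_NO3[0]
            )
            / max(series.NO2[0] + series.NO3[0], 1e-300)
        ),
        "atpct_product_t": noisy_atpct(
            (
                series.NO2[-1] * series.f15_NO2[-1]
                + series.NO3[-1] * series.f15_NO3[-1]
            )
            / max(series.NO2[-1] + series.NO3[-1], 1e-300)
        ),
    }
    return BottleObservation(
        bottle_id=bottle_id,
        times=t_obs,
        DO=do_obs,
        censored=censored,
        detection_limit=cfg.sensor_detection_limit,
        record=record,
    )


def child_seed(master_seed: int, *indices: int) -> int:
    """Stable per-bottle seed: mixing is positional, so adding bottles or
    DO levels later never shifts the noise of earlier bottles."""
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


TREATMENTS = ("15NO2", "15NH4", "unlabeled")


def _apply_treatment(
    cfg: SimulationConfig, treatment: str, spike_fraction: float, spike_floor: float
) -> tuple[SimulationConfig, float]:
    """Spike the relevant pool to 98 at% at tracer level (5-10% of ambient)."""
    if treatment == "unlabeled":
        return cfg, 0.0
    if treatment == "15NO2":
        pool, fpool = cfg.initial_NO2, cfg.f15_NO2
        spike = max(spike_fraction * pool, spike_floor)
        new_pool = pool + spike
        f_new = (pool * fpool + spike * 0.98) / new_pool
        return replace(cfg, initial_NO2=new_pool, f15_NO2=f_new), spike
    if treatment == "15NH4":
        pool, fpool = cfg.initial_NH4, cfg.f15_NH4
        spike = max(spike_fraction * pool, spike_floor)
        new_pool = pool + spike
        f_new = (pool * fpool + spike * 0.98) / new_pool
        return replace(cfg, initial_NH4=new_pool, f15_NH4=f_new), spike
    raise ValueError(f"unknown treatment {treatment!r}")


def simulate_experiment(
    base_config: SimulationConfig,
    DO_levels: Sequence[float],
    treatments: Sequence[str] = TREATMENTS,
    seed: int = 0,
    spike_fraction: float = 0.075,
    spike_floor: float = 12.0,
    n_obs: int = 13,
    keep_series: bool = False,
) -> list[BottleObservation]:
    """One oxygen-manipulation experiment: one bottle per (DO level, treatment).

    Mirrors the shipboard design of 24 bottles per experiment — eight DO
    levels spanning 10s of nM to 1000s of nM, each run with a 15NO2-
    tracer, a 15NH4+ tracer, and an unlabeled bottle. Each bottle gets an
    independent child seed derived from ``seed`` and its position.
    """
    if len(DO_levels) == 0:
        raise ValueError("DO_levels must be non-empty")
    observations: list[BottleObservation] = []
    for i, do in enumerate(DO_levels):
        for j, treatment in enumerate(treatments):
            cfg = replace(
                base_config, initial_O2=float(do), seed=child_seed(seed, i, j)
            )
            cfg, _ = _apply_treatment(cfg, treatment, spike_fraction, spike_floor)
            series = simulate_bottle(cfg, label_treatment=treatment)
            obs = observe_bottle(
                series, n_obs=n_obs, bottle_id=f"L{i}_{treatment}"
            )
            obs.record["DO_level_nM"] = float(do)
            if keep_series:
                obs.record["_series"] = series
            observations.append(obs)
    return observations


@dataclass
class StationTemplate:
    """Parametric shapes for a station's depth profile.

    DO declines as a sigmoid across the oxycline; chlorophyll is a sum of
    Gaussian peaks (surface maximum plus an optional secondary chlorophyll
    maximum); nitrite accumulates below the oxycline when an SNM amplitude
    is given. Rate parameters per depth scale with these shapes.
    """

    station: str = "synthetic-AMZ"
    depths: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 310.0, 10.0)
    )
    DO_surface: float = 200_000.0  # nM
    DO_deep: float = 5.0  # nM
    oxycline_depth: float = 80.0  # m
    oxycline_width: float = 12.0  # m
    chl_peaks: tuple = ((20.0, 10.0, 3.0), (140.0, 20.0, 0.8))  # (depth, width, amp)
    snm_amplitude: float = 0.0  # nM; >1000 marks an anoxic marine zone
    snm_onset: float = 120.0  # m
    snm_width: float = 15.0  # m
    #: per-depth process scalings for bottle configs
    vmax_het_surface: float = 2000.0
    vmax_het_efold: float = 80.0  # m
    Km_het: float = 1800.0
    vmax_NO_scm: float = 150.0  # peaks where the SCM sits
    Km_NO: float = 64.0
    R_AO_surface: float = 30.0
    R_AO_efold: float = 100.0
    R_NAR_snm: float = 60.0
    O2_production_scm: float = 100.0  # nM day^-1
    #: dual nitrate-isotope shape parameters
    iso_eps: float = 25.0  # per mil, nitrate-reduction isotope effect (N = O)
    iso_f_deficit_max: float = 0.35  # max fraction of nitrate consumed at depth
    iso_reox_max: float = 0.0  # peak reoxidized fraction (overprinting strength)
    iso_reox_center: float | None = None  # m; defaults to the SCM peak depth
    iso_reox_width: float | None = None  # m; defaults to the SCM peak width
    delta0_15N: float = 6.0
    delta0_18O: float = 2.0
    delta18_water: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if d.ndim != 1 or len(d) == 0:
            raise ValueError("depth grid must be a non-empty 1-D array")
        if len(d) > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        self.depths = d


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_profile(template: StationTemplate):
    """Evaluate a station template on its depth grid.

    Returns ``(table, configs)``: a per-depth table of DO, nitrite and
    chlorophyll (as a list of flat dicts) and one ``SimulationConfig`` per
    depth, parameterized so bottles incubated "at depth" inherit the
    station's rate structure.
    """
    t = template
    z = t.depths
    DO = t.DO_deep + (t.DO_surface - t.DO_deep) * _sigmoid(
        (t.oxycline_depth - z) / t.oxycline_width
    )
    chl = np.zeros_like(z)
    for depth, width, amp in t.chl_peaks:
        chl = chl + amp * np.exp(-0.5 * ((z - depth) / width) ** 2)
    NO2 = t.snm_amplitude * _sigmoid((z - t.snm_onset) / t.snm_width)
    scm_shape = np.zeros_like(z)
    if len(t.chl_peaks) > 1:
        depth, width, amp = t.chl_peaks[1]
        scm_shape = np.exp(-0.5 * ((z - depth) / width) ** 2)
    vmax_het = t.vmax_het_surface * np.exp(-z / t.vmax_het_efold)
    no2_sat = NO2 / (NO2 + 500.0)
    vmax_NO = t.vmax_NO_scm * np.maximum(scm_shape, no2_sat)
    R_AO = t.R_AO_surface * np.exp(-z / t.R_AO_efold)
    R_NAR = t.R_NAR_snm * _sigmoid((z - t.snm_onset) / t.snm_width)
    O2_prod = t.O2_production_scm * scm_shape

    rows = []
    configs = []
    for k in range(len(z)):
        rows.append(
            {
                "station": t.station,
                "depth_m": float(z[k]),
                "DO_nM": float(DO[k]),
                "NO2_nM": float(NO2[k]),
                "chl_mg_m3": float(chl[k]),
            }
        )
        configs.append(
            SimulationConfig(
                initial_O2=max(float(DO[k]), t.DO_deep),
                initial_NH4=100.0,
                initial_NO2=max(float(NO2[k]), 10.0),
                initial_NO3=20_000.0,
                R_AO=float(R_AO[k]),
                vmax_NO=float(vmax_NO[k]),
                Km_NO=t.Km_NO,
                vmax_het=float(vmax_het[k]),
                Km_het=t.Km_het,
                R_NAR=float(R_NAR[k]),
                O2_production=float(O2_prod[k]),
            )
        )
    return rows, configs


def simulate_profile_isotopes(template: StationTemplate) -> tuple[np.ndarray, np.ndarray]:
    """Per-depth nitrate (delta15N, delta18O) for a station template.

    Nitrate is progressively consumed below the oxycline (Rayleigh, equal
    N and O isotope effects) and a Gaussian band of reoxidation
    overprinting — centered on the secondary chlorophyll maximum by
    default — decouples the two systems where cryptic nitrite recycling
    is active.
    """
    t = template
    z = t.depths
    f = 1.0 - t.iso_f_deficit_max * _sigmoid((z - t.oxycline_depth) / 20.0)
    if t.iso_reox_center is not None:
        center, width = t.iso_reox_center, t.iso_reox_width or 20.0
    elif len(t.chl_peaks) > 1:
        center, width, _ = t.chl_peaks[1]
    else:
        center, width = t.oxycline_depth + 50.0, 20.0
    phi = t.iso_reox_max * np.exp(-0.5 * ((z - center) / width) ** 2)
    d15 = np.empty_like(z)
    d18 = np.empty_like(z)
    for k in range(len(z)):
        a, b = simulate_dual_isotopes(
            [f[k]], t.iso_eps, t.iso_eps, float(phi[k]),
            t.delta0_15N, t.delta0_18O, t.delta18_water,
        )
        d15[k], d18[k] = a[0], b[0]
    return d15, d18


def amz_template(station: str = "synthetic-AMZ") -> StationTemplate:
    """An anoxic-marine-zone station: secondary chlorophyll maximum inside
    the oxygen minimum, nitrite accumulated above 1 uM below the oxycline,
    and isotopic overprinting confined to the SCM band."""
    return StationTemplate(
        station=station,
        snm_amplitude=2000.0,
        iso_reox_max=0.4,
    )


def simulate_dual_isotopes(
    f_remaining: Sequence[float] | np.ndarray,
    eps15: float,
    eps18: float,
    reox_fraction: float = 0.0,
    delta0_15N: float = 6.0,
    delta0_18O: float = 2.0,
    delta18_water: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dual nitrate-isotope evolution under nitrate reduction + reoxidation.

    The residual nitrate pool follows Rayleigh enrichment,
    ``delta = delta0 - eps * ln(f)``, identically in N and O when
    ``eps15 == eps18`` (the 1:1 line of respiratory nitrate reduction).
    A fraction ``reox_fraction`` of the reduced N is returned to the pool
    by nitrite reoxidation: its N keeps the (light) integrated isotopic
    composition of the reduced flux, while its O is reset to a
    water-derived end-member ``delta18_water`` — the N/O decoupling that
    drives the dual-isotope anomaly negative.
    """
    f = np.asarray(f_remaining, dtype=float)
    if np.any(f <= 0.0) or np.any(f > 1.0):
        raise ValueError("f_remaining must lie in (0, 1]")
    if not 0.0 <= reox_fraction < 1.0:
        raise ValueError("reox_fraction must lie in [0, 1)")
    lnf = np.log(f)
    d15_res = delta0_15N - eps15 * lnf
    d18_res = delta0_18O - eps18 * lnf
    removed = 1.0 - f
    # integrated composition of the reduced (removed) N, by mass balance
    with np.errstate(invalid="ignore", divide="ignore"):
        d15_removed = np.where(
            removed > 0, (delta0_15N - f * d15_res) / np.where(removed > 0, removed, 1.0), d15_res
        )
    phi = reox_fraction * removed  # amount reoxidized, relative to initial pool
    pool = f + phi
    d15 = (f * d15_res + phi * d15_removed) / pool
    d18 = (f * d18_res + phi * delta18_water) / pool
    return d15, d18


def simulate_rate_vs_do(
    DO_levels: Sequence[float],
    vmax: float,
    Km: float,
    noise_frac: float = 0.10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rates on a Michaelis-Menten curve with multiplicative Gaussian noise.

    The generator behind across-bottle kinetics recovery: one rate
    observation per DO level, ``v = vmax * S / (Km + S) * (1 + eps)`` with
    ``eps ~ N(0, noise_frac)``, floored at 0.
    """
    rng = np.random.default_rng(seed)
    S = np.asarray(DO_levels, dtype=float)
    v = vmax * S / (Km + S)
    v_obs = v * (1.0 + rng.normal(0.0, noise_frac, size=len(S)))
    return S, np.maximum(v_obs, 0.0)


def default_scenarios() -> Mapping[str, SimulationConfig]:
    """Shipped bottle scenarios spanning the water-column regimes studied.

    ``omz_edge``: oxygenated (20 uM DO), heterotrophy-dominated;
    ``scm``: secondary chlorophyll maximum water, sub-uM DO with active
    nitrite oxidation; ``snm``: secondary nitrite maximum, near-anoxic
    with nitrate reduction feeding a >1 uM nitrite pool. Incubations are
    dark, so no bottle scenario carries photosynthetic O2 production —
    the in-situ SCM source lives in ``StationTemplate``.
    """
    return {
        "omz_edge": SimulationConfig(
            initial_O2=19_940.0,
            initial_NH4=150.0,
            initial_NO2=203.0,
            initial_NO3=25_000.0,
            R_AO=20.0,
            vmax_NO=44.0,
            Km_NO=185.0,
            vmax_het=2757.0,
            Km_het=1787.0,
            R_NAR=0.0,
        ),
        "scm": SimulationConfig(
            initial_O2=480.0,
            initial_NH4=100.0,
            initial_NO2=2052.0,
            initial_NO3=20_000.0,
            R_AO=10.0,
            vmax_NO=149.0,
            Km_NO=63.8,
            vmax_het=2690.0,
            Km_het=1804.0,
            R_NAR=60.0,
        ),
        "snm": SimulationConfig(
            initial_O2=274.0,
            initial_NH4=50.0,
            initial_NO2=3265.0,
            initial_NO3=18_000.0,
            R_AO=5.0,
            vmax_NO=122.0,
            Km_NO=34.1,
            vmax_het=300.0,
            Km_het=1621.0,
            R_NAR=80.0,
        ),
    }
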