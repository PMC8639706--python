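"""Inversion of endpoint isotope measurements into N-oxidation rates.

The core quantity is the nitrite-oxidation rate obtained by isotope mass
balance on the nitrate pool of a 15NO2- tracer incubation:

    R_ox = (n_t - n_oNO3) * [NO3-] / (nbar_NO2 * t)

where ``n_t`` is the atom percent 15N of nitrate at the end of the
incubation (corrected for 15NO3- contamination of the spike), ``n_oNO3``
the atom percent of unlabeled nitrate, ``[NO3-]`` the nitrate pool size,
and ``nbar_NO2`` the exponential average atom percent of the nitrite pool
over the incubation — the labeled pool is progressively diluted by
unlabeled nitrite produced from ammonia oxidation, so its time-mean label
content is below its initial value.

All atom percents are on the 0-100 scale; rates are nmol L^-1 day^-1 and
incubation time is in days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .constants import NAT_ABUNDANCE_AT_PCT, R15_AIR, PRECISION_D15N

__all__ = [
    "TracerIncubation",
    "RateEstimate",
    "spike_atom_percent",
    "exponential_average_atom_percent",
    "correct_tracer_contamination",
    "nitrite_oxidation_rate",
    "ammonia_oxidation_rate",
    "carrier_correction",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_sd_from_delta_precision",
    "DEFAULT_ATPCT_SD",
]


def delta_to_atom_percent(delta15N: float) -> float:
    """Convert a delta-15N value (per mil vs air N2) to atom percent 15N."""
    if delta15N <= -1000.0:
        raise ValueError("delta15N must exceed -1000 per mil")
    R = R15_AIR * (1.0 + delta15N / 1000.0)
    return 100.0 * R / (1.0 + R)


def atom_percent_to_delta(at_pct: float) -> float:
    """Convert atom percent 15N back to delta-15N (exact inverse)."""
    if not 0.0 <= at_pct < 100.0:
        raise ValueError("atom percent must lie in [0, 100)")
    R = at_pct / (100.0 - at_pct)
    return (R / R15_AIR - 1.0) * 1000.0


def atom_percent_sd_from_delta_precision(
    precision_permil: float = PRECISION_D15N, at_pct: float = NAT_ABUNDANCE_AT_PCT
) -> float:
    """Atom-percent standard deviation implied by a delta-scale precision.

    Linearizes the delta -> at% conversion at the given working point
    (natural abundance by default, where tracer measurements start).
    """
    R = at_pct / (100.0 - at_pct)
    # d(at%)/dR = 100/(1+R)^2 ; dR/d(delta) = R15_AIR/1000
    return 100.0 / (1.0 + R) ** 2 * R15_AIR / 1000.0 * precision_permil


#: Default at% measurement noise: ±0.3 per-mil delta precision at natural abundance.
DEFAULT_ATPCT_SD = atom_percent_sd_from_delta_precision()


@dataclass
class RateEstimate:
    """A rate with first-order propagated uncertainty and a detectability flag."""

    value: float  # nmol L^-1 day^-1
    se: float = 0.0
    detectable: bool = True
    method: str = ""

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass
class TracerIncubation:
    """Everything the nitrite-oxidation mass balance needs for one bottle.

    ``n_t_raw`` is the measured endpoint at% 15N of nitrate before the
    spike-contamination correction; ``n_oNO3`` the at% of unlabeled nitrate.
    ``NO2_conc_initial`` is the ambient nitrite pool before the spike was
    added. ``R_AO`` is the measured ammonia-oxidation rate used to model
    dilution of the labeled nitrite pool.
    """

    n_t_raw: float  # at%
    n_oNO3: float  # at%
    NO3_conc: float  # nM
    NO2_conc_initial: float  # nM
    spike_conc: float  # nM
    t_days: float
    spike_atpct: float = 98.0
    spike_NO3_contam_fraction: float = 0.0
    R_AO: float = 0.0  # nmol L^-1 day^-1
    NO2_atpct_initial: float = NAT_ABUNDANCE_AT_PCT
    atpct_sd: float = DEFAULT_ATPCT_SD
    validate_spike_band: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("n_t_raw", "n_oNO3", "spike_atpct", "NO2_atpct_initial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] at%")
        if self.t_days <= 0:
            raise ValueError("incubation time must be positive")
        if self.spike_conc < 0:
            raise ValueError("spike concentration must be >= 0")
        if self.R_AO < 0:
            raise ValueError("ammonia-oxidation rate must be >= 0")
        if self.validate_spike_band and self.NO2_conc_initial > 0:
            frac = self.spike_conc / self.NO2_conc_initial
            if not 0.05 <= frac <= 0.10:
                warnings.warn(
                    f"spike is {100 * frac:.1f}% of ambient NO2- "
                    "(tracer-level additions target 5-10%)",
                    stacklevel=2,
                )


def spike_atom_percent(
    pool_conc: float, pool_atpct: float, spike_conc: float, spike_atpct: float = 98.0
) -> float:
    """Concentration-weighted at% of an ambient pool after a tracer spike."""
    total = pool_conc + spike_conc
    if total <= 0:
        raise ValueError("pool and spike concentrations are both zero")
    return (pool_conc * pool_atpct + spike_conc * spike_atpct) / total


def exponential_average_atom_percent(
    n0: float, R_AO: float, NO2_conc: float, t_days: float
) -> float:
    """Time-mean at% of a labeled nitrite pool diluted by ammonia oxidation.

    Assumes the nitrite pool size stays constant (production balancing
    consumption) while ammonia oxidation supplies unlabeled nitrite at rate
    ``R_AO``, so the label decays as n(tau) = n0 * exp(-k tau) with
    k = R_AO / [NO2-]. The average over the incubation is

        nbar = n0 * (1 - exp(-k t)) / (k t)

    evaluated by series expansion for k t below 1e-6.
    """
    if NO2_conc <= 0:
        raise ValueError("nitrite concentration must be positive")
    if t_days <= 0:
        raise ValueError("incubation time must be positive")
    if R_AO < 0:
        raise ValueError("ammonia-oxidation rate must be >= 0")
    kt = R_AO / NO2_conc * t_days
    if kt < 1e-6:
        # (1 - e^-x)/x = 1 - x/2 + x^2/6 - ...
        return n0 * (1.0 - kt / 2.0 + kt * kt / 6.0)
    return n0 * (1.0 - math.exp(-kt)) / kt


def correct_tracer_contamination(
    n_t_raw: float,
    n_oNO3: float,
    NO3_conc: float,
    spike_conc: float,
    spike_atpct: float = 98.0,
    contam_fraction: float = 0.0,
    atpct_sd: float = DEFAULT_ATPCT_SD,
) -> float:
    """Remove the at% excess contributed by 15NO3- contamination of the spike.

    A fraction ``contam_fraction`` of the spike's N atoms are present as
    nitrate rather than nitrite; they enter the nitrate pool instantly and
    inflate the measured endpoint at% by

        excess = spike_atpct * contam_fraction * spike_conc
                 / (NO3_conc + contam_fraction * spike_conc)

    The corrected value never drops below ``n_oNO3`` minus the measurement
    precision: over-correction beyond noise is attributed to the correction
    itself, not to negative label transfer.
    """
    if not 0.0 <= contam_fraction <= 0.05:
        raise ValueError("contam_fraction must lie in [0, 0.05]")
    if NO3_conc <= 0:
        raise ValueError("nitrate concentration must be positive")
    contam_conc = contam_fraction * spike_conc
    excess = spike_atpct * contam_conc / (NO3_conc + contam_conc)
    corrected = n_t_raw - excess
    floor = n_oNO3 - atpct_sd
    return max(corrected, floor)


def nitrite_oxidation_rate(inc: TracerIncubation) -> RateEstimate:
    """Invert a 15NO2- incubation into a nitrite-oxidation rate.

    Computes the initial labeled-pool at% from the spike mass balance, its
    exponential average under ammonia-oxidation dilution, corrects the
    endpoint nitrate at% for spike contamination, and evaluates the isotope
    mass balance. Measurement noise on the two nitrate at% values is
    propagated to a first-order standard error; a transfer below three
    times that propagated noise is flagged undetectable, and a negative
    excess is reported as rate 0 (tracer accumulation cannot be negative).
    """
    if inc.NO3_conc <= 0:
        raise ValueError("nitrate concentration must be positive")
    n0 = spike_atom_percent(
        inc.NO2_conc_initial, inc.NO2_atpct_initial, inc.spike_conc, inc.spike_atpct
    )
    NO2_total = inc.NO2_conc_initial + inc.spike_conc
    nbar = exponential_average_atom_percent(n0, inc.R_AO, NO2_total, inc.t_days)
    n_t = correct_tracer_contamination(
        inc.n_t_raw,
        inc.n_oNO3,
        inc.NO3_conc,
        inc.spike_conc,
        inc.spike_atpct,
        inc.spike_NO3_contam_fraction,
        inc.atpct_sd,
    )
    excess = n_t - inc.n_oNO3
    scale = inc.NO3_conc / (nbar * inc.t_days)
    noise = math.sqrt(2.0) * inc.atpct_sd  # sd of the at% difference
    se = noise * scale
    detectable = excess >= 3.0 * noise
    value = max(excess, 0.0) * scale
    return RateEstimate(value=value, se=se, detectable=detectable, method="15NO2_eq1")


def ammonia_oxidation_rate(
    atpct_product_t: float,
    atpct_product_0: float,
    product_pool_conc: float,
    atpct_NH4: float,
    t_days: float,
    atpct_sd: float = DEFAULT_ATPCT_SD,
) -> RateEstimate:
    """Ammonia-oxidation rate from 15N accumulation in the NO2- + NO3- pool.

    ``atpct_NH4`` is the at% of the ammonium pool after the 15NH4+ spike;
    ``product_pool_conc`` the combined oxidized-N pool (nM).
    """
    if product_pool_conc <= 0:
        raise ValueError("product pool concentration must be positive")
    if t_days <= 0:
        raise ValueError("incubation time must be positive")
    if atpct_NH4 <= 0:
        raise ValueError("ammonium at% must be positive")
    excess = atpct_product_t - atpct_product_0
    scale = product_pool_conc / (atpct_NH4 * t_days)
    noise = math.sqrt(2.0) * atpct_sd
    se = noise * scale
    detectable = excess >= 3.0 * noise
    value = max(excess, 0.0) * scale
    return RateEstimate(value=value, se=se, detectable=detectable, method="15NH4")


def carrier_correction(
    delta_measured: float, sample_conc: float, carrier_conc: float, delta_carrier: float
) -> float:
    """Recover a sample's delta from a measurement on sample + carrier.

    Low-concentration nitrate samples are analyzed after adding carrier
    nitrate of known isotopic composition; the sample value follows by
    two-component mass balance.
    """
    if sample_conc <= 0:
        raise ValueError("sample concentration must be positive")
    total = sample_conc + carrier_conc
    return (delta_measured * total - delta_carrier * carrier_conc) / sample_conc
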