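"""Partitioning oxygen consumption among its sinks.

Converts N-oxidation rates into O2 demand via fixed stoichiometry
(0.5 mol O2 per mol nitrite oxidized, 1.5 per mol ammonia oxidized),
expresses nitrite oxidation's O2 demand as a percentage of the measured
OCR, fits the percentage-versus-DO power law in log-log space, and
inverts it for the DO below which nitrite oxidation can account for all
consumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import O2_PER_NH4_OXIDIZED, O2_PER_NO2_OXIDIZED

__all__ = [
    "PartitionRecord",
    "PowerLawFit",
    "o2_demand_nitrite",
    "o2_demand_ammonia",
    "percent_contribution",
    "fit_power_law",
    "threshold_do",
]

logger = logging.getLogger(__name__)


@dataclass
class PartitionRecord:
    """One bottle or depth: OCR alongside N-oxidation O2 demands."""

    mean_DO: float  # nM
    OCR: float  # nmol-O2 L^-1 day^-1
    R_NO2ox: float = 0.0  # nmol-N L^-1 day^-1
    R_NH3ox: float = 0.0
    label: str = ""

    @property
    def pct_NO2ox(self) -> float:
        return percent_contribution(self.R_NO2ox, self.OCR)

    @property
    def pct_NH3ox(self) -> float:
        if self.OCR <= 0:
            raise ValueError("OCR must be positive for a percentage")
        return 100.0 * o2_demand_ammonia(self.R_NH3ox) / self.OCR


@dataclass
class PowerLawFit:
    """pct = a * DO^b fitted as OLS of log10(pct) on log10(DO)."""

    a: float
    b: float
    r2: float
    p: float
    n: int
    b_se: float = 0.0


def o2_demand_nitrite(rate: float, factor: float = O2_PER_NO2_OXIDIZED) -> float:
    """O2 demand (nmol-O2 L^-1 day^-1) of a nitrite-oxidation rate."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return factor * rate


def o2_demand_ammonia(rate: float, factor: float = O2_PER_NH4_OXIDIZED) -> float:
    """O2 demand of an ammonia-oxidation rate (to nitrite)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return factor * rate


def percent_contribution(R_NO2ox: float, OCR: float) -> float:
    """Nitrite oxidation's percentage of the oxygen consumption rate.

    Values above 100% are possible when the rate methods disagree and are
    returned uncapped (logged); OCR must be positive.
    """
    if OCR <= 0:
        raise ValueError("OCR must be positive for a percentage")
    pct = 100.0 * o2_demand_nitrite(R_NO2ox) / OCR
    if pct > 100.0:
        logger.info(
            "nitrite-oxidation O2 demand exceeds OCR (%.0f%%): rate-method "
            "mismatch, value kept uncapped", pct,
        )
    return pct


def fit_power_law(
    records: Sequence[PartitionRecord],
    do_ceiling: float | None = None,
) -> PowerLawFit:
    """Fit pct_NO2ox = a * DO^b over partition records.

    Records with non-positive OCR, percentage, or DO are dropped (logged),
    as are records above ``do_ceiling`` when given (profile comparisons
    are conventionally restricted to DO < 18 uM).
    """
    do, pct = [], []
    dropped = 0
    for rec in records:
        if rec.OCR <= 0 or rec.mean_DO <= 0:
            dropped += 1
            continue
        p = rec.pct_NO2ox
        if p <= 0:
            dropped += 1
            continue
        if do_ceiling is not None and rec.mean_DO > do_ceiling:
            dropped += 1
            continue
        do.append(rec.mean_DO)
        pct.append(p)
    if dropped:
        logger.info("power-law fit: dropped %d unusable records", dropped)
    if len(do) < 5:
        raise ValueError(
            f"need at least 5 usable records for a power-law fit, have {len(do)}"
        )
    lx = np.log10(np.asarray(do))
    ly = np.log10(np.asarray(pct))
    res = stats.linregress(lx, ly)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    return PowerLawFit(
        a=float(10.0**res.intercept), b=float(res.slope), r2=r2, p=p,
        n=len(do), b_se=float(res.stderr) if not math.isnan(res.stderr) else 0.0,
    )


def threshold_do(fit: PowerLawFit, target_pct: float = 100.0) -> float:
    """DO at which the fitted power law reaches ``target_pct``.

    DO* = (target/a)^(1/b). Meaningful as an "all consumption below this
    DO" threshold only when b < 0, so that the percentage rises as DO
    falls; a warning is raised otherwise.
    """
    if fit.b == 0:
        raise ValueError("exponent b is zero; the power law never crosses the target")
    if fit.a <= 0:
        raise ValueError("prefactor a must be positive")
    if fit.b > 0:
        import warnings

        warnings.warn(
            "power-law exponent is positive: the percentage grows with DO, "
            "so the threshold is a floor, not a ceiling", stacklevel=2,
        )
    return float((target_pct / fit.a) ** (1.0 / fit.b))
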