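"""Michaelis-Menten oxygen-affinity fits.

Two fit kinds, mirroring how affinity is estimated from oxygen
manipulation experiments:

* **overall** — across bottles: each bottle contributes one
  (mean DO, rate) pair and ``v = vmax * S / (Km + S)`` is fit by
  multi-start nonlinear least squares. These Km values characterize the
  community response over the full manipulated DO range.
* **low-level** — within a single bottle whose OCR declined as DO was
  consumed: the integrated Michaelis-Menten depletion model is fit to
  the DO decline itself. The progress curve has the closed form

      t(S) = (S0 - S)/vmax + (Km/vmax) * ln(S0/S)

  which is inverted numerically to predict DO at each reading time; Km is
  the parameter of interest and vmax a nuisance.

A fit whose Km fails a Wald test at the 0.05 level is reported but
flagged not-significant (NS), matching how experiments with
poorly-constrained affinity are tabulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .oxygen import OxygenTimeSeries

__all__ = [
    "KineticsFit",
    "fit_michaelis_menten",
    "fit_low_level_km",
    "predict_rate",
    "depletion_time",
    "depletion_do",
]


@dataclass
class KineticsFit:
    Km: float  # nM
    Km_se: float
    vmax: float  # nmol L^-1 day^-1
    vmax_se: float
    r2: float
    p_Km: float
    significant: bool
    n: int
    fit_kind: str  # "overall" | "low_level"
    message: str = ""

    def __post_init__(self) -> None:
        if self.significant and (self.Km <= 0 or self.vmax <= 0):
            raise ValueError("significant fits require positive Km and vmax")
        if self.Km_se < 0 or self.vmax_se < 0:
            raise ValueError("standard errors must be >= 0")


def _mm(S: np.ndarray, vmax: float, Km: float) -> np.ndarray:
    return vmax * S / (Km + S)


def fit_michaelis_menten(S, v) -> KineticsFit:
    """Fit v = vmax*S/(Km+S) to across-bottle (mean DO, rate) pairs.

    Multi-start: vmax initialized at the largest observed rate, Km at the
    median DO and a decade either side; the start with the lowest SSE
    wins. Uncertainties come from the fit covariance; the Km significance
    flag is a two-sided Wald t test with n - 2 degrees of freedom.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(S) != len(v):
        raise ValueError("S and v must have equal length")
    n = len(S)
    if n < 4:
        raise ValueError("need at least 4 (DO, rate) pairs")
    if np.any(S <= 0):
        raise ValueError("DO values must be positive")
    span = S.max() / S.min()
    if span < 10:
        warnings.warn(
            f"DO values span only a factor of {span:.1f}; Km is poorly "
            "constrained below one order of magnitude of coverage",
            stacklevel=2,
        )
    vmax0 = float(v.max()) if v.max() > 0 else 1.0
    med = float(np.median(S))
    best = None
    for Km0 in (med, 0.1 * med, 10.0 * med):
        try:
            popt, pcov = optimize.curve_fit(
                _mm, S, v, p0=[vmax0, Km0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10_000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((v - _mm(S, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return KineticsFit(
            Km=float("nan"), Km_se=0.0, vmax=float("nan"), vmax_se=0.0,
            r2=0.0, p_Km=1.0, significant=False, n=n, fit_kind="overall",
            message="non-convergence after multi-start",
        )
    sse, popt, pcov = best
    vmax, Km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    vmax_se, Km_se = float(perr[0]), float(perr[1])
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    df = max(n - 2, 1)
    if Km_se > 0 and math.isfinite(Km_se):
        p_Km = float(2.0 * stats.t.sf(abs(Km / Km_se), df))
    else:
        p_Km = 1.0 if not math.isfinite(Km_se) else 0.0
    return KineticsFit(
        Km=Km, Km_se=Km_se, vmax=vmax, vmax_se=vmax_se,
        r2=max(min(r2, 1.0), 0.0), p_Km=p_Km, significant=p_Km < 0.05,
        n=n, fit_kind="overall",
    )


def depletion_time(S: np.ndarray, S0: float, vmax: float, Km: float) -> np.ndarray:
    """Closed-form time to draw DO down from S0 to S under MM kinetics."""
    S = np.asarray(S, dtype=float)
    return (S0 - S) / vmax + (Km / vmax) * np.log(S0 / S)


def depletion_do(t_days, S0: float, vmax: float, Km: float) -> np.ndarray:
    """DO remaining at each time, by numeric inversion of the progress curve."""
    t_days = np.atleast_1d(np.asarray(t_days, dtype=float))
    out = np.empty_like(t_days)
    lo = S0 * 1e-12
    t_lo = float(depletion_time(np.array([lo]), S0, vmax, Km)[0])
    for i, t in enumerate(t_days):
        if t <= 0:
            out[i] = S0
        elif t >= t_lo:
            # beyond the resolvable depletion horizon for these parameters
            out[i] = lo
        else:
            f = lambda S: float(depletion_time(S, S0, vmax, Km)) - t
            out[i] = optimize.brentq(f, lo, S0, xtol=1e-12, rtol=1e-12)
    return out


def fit_low_level_km(
    series: OxygenTimeSeries,
    S0: float | None = None,
    fit_S0: bool = False,
    do_cutoff: float = 235.0,
) -> KineticsFit:
    """Low-level oxygen affinity from a single bottle's DO decline.

    Intended for nonlinear-classified bottles with average DO below
    ``do_cutoff`` (nM) — the regime where OCR visibly declines as DO is
    consumed. ``S0`` defaults to the first uncensored reading; set
    ``fit_S0`` to estimate it instead. Parameters are optimized on a log
    scale (positivity) by least squares on the DO residuals, with Km
    multi-started a decade either side of half the initial DO.
    """
    t_h, do = series.uncensored()
    n = len(t_h)
    if n < 4:
        raise ValueError("need at least 4 uncensored readings")
    if float(np.mean(do)) > do_cutoff:
        warnings.warn(
            f"average DO {np.mean(do):.0f} nM exceeds the low-level cutoff "
            f"({do_cutoff:.0f} nM); the integrated-MM fit targets declining, "
            "sub-cutoff bottles",
            stacklevel=2,
        )
    t_days = (t_h - t_h[0]) / 24.0
    rises = np.diff(do)
    noise_scale = float(np.median(np.abs(rises))) + 1e-9
    if do[-1] >= do[0] or float(np.max(rises, initial=0.0)) > 10.0 * noise_scale:
        return KineticsFit(
            Km=float("nan"), Km_se=0.0, vmax=float("nan"), vmax_se=0.0,
            r2=0.0, p_Km=1.0, significant=False, n=n, fit_kind="low_level",
            message="DO series is not a monotone decline beyond noise",
        )
    S0_fixed = float(do[0]) if S0 is None else float(S0)
    # crude initial vmax from the first-interval slope
    v0 = max((do[0] - do[1]) / max(t_days[1] - t_days[0], 1e-9), 1.0)

    def residuals(params: np.ndarray) -> np.ndarray:
        p = np.clip(params, -40.0, 40.0)  # keep exp() finite while LM explores
        vmax = math.exp(p[0])
        Km = math.exp(p[1])
        s0 = math.exp(p[2]) if fit_S0 else S0_fixed
        pred = depletion_do(t_days, s0, vmax, Km)
        return pred - do

    best = None
    for Km0 in (S0_fixed / 2.0, S0_fixed / 20.0, 5.0 * S0_fixed):
        x0 = [math.log(v0), math.log(Km0)]
        if fit_S0:
            x0.append(math.log(S0_fixed))
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return KineticsFit(
            Km=float("nan"), Km_se=0.0, vmax=float("nan"), vmax_se=0.0,
            r2=0.0, p_Km=1.0, significant=False, n=n, fit_kind="low_level",
            message="non-convergence after multi-start",
        )
    x_hat = np.clip(best.x, -40.0, 40.0)  # match the clamp used in residuals
    vmax = math.exp(x_hat[0])
    Km = math.exp(x_hat[1])
    n_par = len(best.x)
    dof = max(n - n_par, 1)
    sse = float(2.0 * best.cost)
    J = best.jac
    try:
        cov_log = sse / dof * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        vmax_se = vmax * float(se_log[0])
        Km_se = Km * float(se_log[1])
    except np.linalg.LinAlgError:
        vmax_se = Km_se = float("inf")
    sst = float(np.sum((do - do.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    # Wald test on log-Km against a diffuse null is ill-posed; test Km/se
    # on the linear scale as for overall fits
    if Km_se > 0 and math.isfinite(Km_se):
        p_Km = float(2.0 * stats.t.sf(abs(Km / Km_se), dof))
    else:
        p_Km = 1.0 if not math.isfinite(Km_se) else 0.0
    return KineticsFit(
        Km=Km, Km_se=Km_se, vmax=vmax, vmax_se=vmax_se,
        r2=max(min(r2, 1.0), 0.0), p_Km=p_Km, significant=p_Km < 0.05,
        n=n, fit_kind="low_level",
    )


def predict_rate(fit: KineticsFit, S: float) -> float:
    """Rate predicted by a fit at DO concentration S (nM)."""
    if S < 0:
        raise ValueError("DO concentration must be >= 0")
    if not fit.significant:
        warnings.warn("predicting from a not-significant fit", stacklevel=2)
    return fit.vmax * S / (fit.Km + S)
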