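# Methods

## The bottle process model

`omzox.simulate` integrates a sealed, dark incubation bottle as a
four-pool box model — dissolved O2 plus the inorganic nitrogen pools
NH4+, NO2-, NO3- (all nM) — with the 15N atom content of each N pool
tracked as a separate state variable. Processes and their rate laws
(rates in nmol L⁻¹ day⁻¹):

| process | law | N flux | O2 flux |
|---|---|---|---|
| ammonia oxidation | constant `R_AO` | NH4+ → NO2- | −1.5 per N |
| nitrite oxidation | `vmax_NO·[O2]/(Km_NO+[O2])` | NO2- → NO3- | −0.5 per N |
| heterotrophic respiration | `vmax_het·[O2]/(Km_het+[O2])` | — | −1 |
| nitrate reduction | constant `R_NAR` | NO3- → NO2- | 0 |
| photosynthesis | constant `O2_production` | — | +1 |

The 0.5 (nitrite) stoichiometry is the electron balance of
NO2- + ½O2 → NO3-; the 1.5 (ammonia) factor is the canonical
nitrification stoichiometry for NH4+ → NO2- and is exposed as a config
constant since only its consequence (ammonia oxidation being a minor O2
sink) is observationally constrained. Label moves with the fluxes at
the *source* pool's atom fraction: ammonia oxidation delivers nitrite
at `f15_NH4`, nitrate reduction at `f15_NO3`, nitrite oxidation
delivers nitrate at `f15_NO2`. No process fractionates isotopes in the
box model; natural-abundance fractionation lives in the separate
Rayleigh generator (below). Incubations are dark, so shipped bottle
scenarios carry `O2_production = 0`; the photosynthetic source matters
only for in-situ profile configurations.

**Integrator.** Fixed-step explicit midpoint (RK2), default
`dt = 0.01 h`. The system is smooth and non-stiff at these scales;
halving `dt` moves endpoint states by far less than 0.1% (asserted in
tests). Every substrate-limited rate is multiplied by a ramp falling
linearly to zero over the last 1 nM of its substrate (including O2 for
O2-consuming processes), which prevents overshoot into negative pools
without event detection; any residual clipping is recorded in a ledger
so budgets stay auditable. Flux integrals are accumulated with the same
midpoint quadrature as the state update, which is why the N-mass, 15N,
and O2 budgets close to ~1e-14 relative rather than merely 1e-6.
Non-finite states abort immediately, naming the step and variable.

**Observation model.** Gaussian sensor noise (sd `sensor_sd`) on DO
readings; readings below the detection limit (10 nM trace-level spots,
100 nM wide-range) are reported *at the limit* with a censored flag.
Endpoint atom percents get Gaussian noise `atpct_sd`, whose default
derives from the ±0.3‰ δ15N measurement precision linearized at
natural abundance (≈1.1e-4 at%). One master seed; each bottle's seed is
derived positionally (`SeedSequence([master, level_index,
treatment_index])`), so adding DO levels or treatments never shifts the
noise of existing bottles.

**Experiment design.** `simulate_experiment` mirrors the shipboard
oxygen-manipulation layout: one bottle per (DO level, treatment) with
treatments 15NO2-, 15NH4+, unlabeled — eight levels × three treatments
= 24 bottles. Spikes are 98 at% at 7.5% of the ambient pool (midpoint
of the 5–10% tracer-level convention), floored at 12 nM for
nitrite-free waters.

**Depth profiles.** `StationTemplate` composes parametric shapes: a
sigmoid DO decline across the oxycline, Gaussian chlorophyll peaks
(surface plus optional secondary chlorophyll maximum, SCM), nitrite
accumulating below the oxycline when a secondary nitrite maximum (SNM)
amplitude is set, and per-depth rate scalings (heterotrophy decaying
with depth, nitrite oxidation tracking the SCM and nitrite supply, a
~100 nM day⁻¹ photosynthetic O2 source confined to the SCM). The AMZ
factory template accumulates >1 µM nitrite below the oxycline, the
defining SNM criterion.

**Dual isotopes.** Residual nitrate follows Rayleigh enrichment
`δ = δ0 − ε·ln f` identically in N and O for equal isotope effects
(default ε = 25‰, the canonical denitrification value; source pool
δ15N = 6‰, δ18O = 2‰). Reoxidation returns a fraction
`reox_fraction` of the *removed* N to the pool carrying the integrated
(light) isotopic composition of the reduced flux — mass balance:
`δ_removed = (δ0 − f·δ_residual)/(1−f)` — while its O is reset to a
water-derived end-member (default 0‰ vs VSMOW). This is the N/O
decoupling that makes Δ(15,18) strictly negative wherever overprinting
acts, provided the water end-member is heavier than the removed O flux
(always true for realistic values). A model that only reset O without
lightening the returned N would produce the wrong sign.

## Tracer inversion

`nitrite_oxidation_rate` evaluates
`R_ox = (n_t − n_oNO3)·[NO3-]/(n̄_NO2·t)` with:

* `n0` from the concentration-weighted spike mass balance;
* `n̄ = n0·(1−e^(−kt))/(kt)`, `k = R_AO/[NO2-]` (constant-pool dilution
  by unlabeled nitrite from ammonia oxidation; series expansion below
  `kt < 1e-6`);
* `n_t` corrected for 15NO3- contamination of the spike by mass balance
  on the nitrate pool, floored at `n_oNO3` minus the measurement
  precision;
* first-order error propagation of the at% noise
  (`se = √2·σ_at%·[NO3-]/(n̄·t)`), with transfers below 3× the
  propagated noise flagged undetectable and negative excesses reported
  as rate 0 (tracer accumulation cannot be negative).

Known limitation, inherent to the equation rather than this
implementation: the denominator uses the labeled pool's absolute at%,
not its excess above natural abundance, so recovery of a known rate
carries a low bias of roughly `n_nat/n̄` — about 4% for a 9 at% spiked
pool, shrinking as the label strengthens. A second, smaller bias
appears when the transferred N is a non-negligible fraction of the
nitrate pool (endpoint at% differences are not strictly additive).
Both are visible in the noise-free end-to-end tests, which recover
~95.5 of a true 100 nmol L⁻¹ day⁻¹.

## OCR and the linearity screen

OCR is `(DO_start − DO_end)/Δt` (endpoint) or the negated OLS slope of
DO on time (monitored bottles), converted to per-day. Censored readings
are excluded from the regression; a bottle with more than half its
readings censored is reported rate-indeterminate. Replicates aggregate
as arithmetic mean ± sample SD, flagged when fewer than the standard
five are available.

The MIC (maximal information coefficient) is computed by direct
search: over all grid shapes `a×b` with `a·b ≤ n^0.6`, maximize
`I(binned x; binned y)/log2(min(a,b))` over bin-boundary placements.
Boundaries live between consecutive distinct sorted values, which makes
the statistic exactly invariant under strictly monotone transforms of
either axis. Both axes are searched exhaustively whenever the
combination count permits (always true at the ≤25-reading series this
package works with); beyond a cap of 2e5 combinations the finer axis is
equal-frequency binned while the other is searched, in both
orientations. The screen classifies a series linear iff `r² > 0.6` and
`MIC − r² < 0.2` (both thresholds configurable). The screen deliberately
uses *all* reported readings, censored ones included at the limit
value: a plateau at the detection limit is precisely the
declining-OCR signature the rule exists to catch, while the rate
regression continues to exclude censored points.

## Kinetics fits

**Overall** (across bottles): `v = vmax·S/(Km+S)` by
`scipy.optimize.curve_fit`, multi-started at `vmax0 = max(v)` and
`Km0 ∈ {median S, 0.1·, 10·}`, best SSE kept; parameter uncertainties
from the fit covariance; Km significance by two-sided Wald t with
`n−2` df, fits with `p ≥ 0.05` reported but flagged NS; `r² = 1 −
SSres/SStot` about the mean (the conventional nonlinear-fit report).
Fewer than four pairs is an error; a DO span under one decade warns.

**Low-level** (within one declining bottle): the integrated
Michaelis–Menten progress curve `t(S) = (S0−S)/vmax + (Km/vmax)·ln(S0/S)`
is inverted numerically (Brent) to predict DO at each reading time, and
squared DO residuals are minimized over `(log vmax, log Km)` —
log-parameterization enforces positivity — with Km multi-started a
decade either side of `S0/2`. `S0` is fixed to the first uncensored
reading by default (estimable via `fit_S0`). Series that do not
decline beyond noise return a non-convergence diagnostic rather than a
fit. Identifiability caveat: progress curves constrain Km only if the
decline actually traverses it. The recovery studies therefore monitor a
12 h window at 30-min readings from `S0 = 235 nM` with
`vmax = 1000 nmol L⁻¹ day⁻¹`, which draws DO from ~2·Km down to ~20 nM
— below Km but above the censoring floor. Shorter windows leave Km
ill-constrained; much longer ones accumulate censored plateau readings
whose retained upward noise biases Km high.

## Partition and threshold

O2 demands are fixed linear scalings (0.5, 1.5 mol O2 per mol N);
`pct = 100·0.5·R_NO2ox/OCR` is left uncapped above 100% (flagged as a
rate-method mismatch) since near-total and above-total shares are the
scientifically interesting regime. The power law is OLS of
`log10(pct)` on `log10(DO)` — symmetric treatment of multiplicative
scatter — over records with positive OCR, percentage and DO, optionally
below a DO ceiling (default 18 µM for profile comparisons). The
threshold `DO* = (target/a)^(1/b)` is meaningful as an
"all-consumption-below" bound only for `b < 0`; a positive exponent
warns.

## Δ(15,18) profiles

`Δ = (δ15N − ref15) − slope·(δ18O − ref18)` with slope 1 by default
(configurable for ε-ratio sensitivity runs) and propagated uncertainty
`√(0.3² + slope²·0.4²)` ‰. One reference pair per profile; the default
policy anchors at the shallowest measurement as a stand-in for source
water, with an explicit-pair override. Deviation *magnitudes* depend on
this choice; signs and peak depths do not. The profile's "peak
deviation" is the most negative value.

## What the synthetic data do and do not establish

The generator reproduces the statistical structure the inference
assumes: MM-limited drawdown with sensor noise and censoring, label
transfer with dilution, nitrate reduction resupplying nitrite, and
dual-isotope decoupling. Passing tests therefore demonstrate that the
inversion chain is self-consistent — it recovers what the model
generated, at the stated noise levels. They do not establish that field
bottles satisfy the assumptions: real incubations add bottle effects,
non-constant rates, community shifts, nitrite pools that are not in
production/consumption balance, and tracer recycling through
nitrate reduction in 15NO2- bottles (the pathway is included in the
simulator precisely so its bias on the inversion can be quantified, but
no field value constrains its in-bottle magnitude). Percentages of OCR
inherit both rate methods' biases and can exceed 100%.

## Numerical conventions

* Units: concentrations nM, rates nmol L⁻¹ day⁻¹, time in hours
  internally with day conversion at module boundaries; at% on the
  0–100 scale, atom fractions 0–1.
* 15N reference ratio 0.0036765 (air N2), natural abundance
  0.3663 at%; δ↔at% conversions are exact inverses.
* Default problem sizes: 24-bottle experiments at `dt = 0.01 h`,
  13-reading monitored series (25 for low-level studies), 200-seed
  recovery medians, 50-seed classification runs — sized so the full
  suite and the acceptance script each run in well under a minute of
  simulation time per stage.
* Determinism: every stochastic path flows from one seed through
  positional `SeedSequence` mixing; identical configs produce
  byte-identical outputs, and the pipeline refuses to overwrite a
  results directory created under a different config hash unless
  forced.
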