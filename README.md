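# omzox

Nitrite oxidation, oxygen consumption, and dual nitrate isotopes in
oceanic oxygen minimum zones (OMZs): a forward simulator of bottle
incubations plus the full inference chain that turns incubation
observations into rates, oxygen affinities, and isotope anomalies.

## The scientific problem

In OMZs, microbes draw dissolved oxygen (DO) down to nanomolar levels.
Aerobic nitrite-oxidizing bacteria (chiefly *Nitrospina*) oxidize
NO2- to NO3- using half a mole of O2 per mole of N, and may consume a
large — at the lowest DO, dominant — share of the remaining oxygen.
Quantifying that share requires chaining several measurements:

1. **Nitrite oxidation rates** from 15N tracer incubations. A 98 at%
   15NO2- spike (5–10% of the ambient pool) is added and the label
   accumulating in nitrate is inverted by isotope mass balance:

       R_ox = (n_t − n_oNO3) · [NO3-] / (n̄_NO2 · t)

   where `n_t` is the at% 15N of nitrate at time `t` (corrected for
   15NO3- contamination of the spike), `n_oNO3` the at% of unlabeled
   nitrate, and `n̄_NO2` the *exponential average* at% of the nitrite
   pool — ammonia oxidation feeds unlabeled NO2- into the pool, so the
   label decays as `n(τ) = n0·exp(−kτ)` with `k = R_AO/[NO2-]`, and
   `n̄ = n0·(1 − e^(−kt))/(kt)`.

2. **Oxygen consumption rates (OCR)** from DO decline in sealed bottles
   with optical sensor spots (detection limits 10 or 100 nM), either
   endpoint differences or OLS slopes over monitored series. Monitored
   series are screened for linearity with the maximal information
   coefficient: a series is linear iff `r² > 0.6` and `MIC − r² < 0.2`;
   a high-MIC/low-r² series is one whose OCR declined as DO was
   consumed.

3. **Michaelis–Menten oxygen affinities**: across bottles,
   `v = vmax·S/(Km+S)` fit to (mean DO, rate) pairs; within a single
   declining bottle, the integrated depletion model
   `t(S) = (S0−S)/vmax + (Km/vmax)·ln(S0/S)` fit to the DO time course
   ("low-level" Km).

4. **Partitioning**: nitrite oxidation's O2 demand (0.5 mol O2 per mol
   N) as a percentage of OCR, its power-law dependence on DO
   (`pct = a·DO^b`, fit in log-log space), and the DO below which
   nitrite oxidation could account for *all* consumption,
   `DO* = (100/a)^(1/b)`.

5. **Dual nitrate isotopes**: nitrate reduction enriches δ15N and δ18O
   of residual nitrate 1:1; cryptic reoxidation of nitrite decouples
   them (light N returns, O is reset from ambient water). The anomaly
   `Δ(15,18) = (δ15N − ref15) − (δ18O − ref18)` goes negative where
   overprinting is active.

Every stage is testable without field data: the `simulate` module
generates bottles and depth profiles with the statistical structure the
inference assumes (a four-pool O2/NH4+/NO2-/NO3- box model with tracked
15N, Michaelis–Menten O2 kinetics, sensor noise, detection-limit
censoring, and Rayleigh dual-isotope evolution with reoxidation
overprinting).

## Worked example

The numbered scripts under `analysis/` run the chain on a synthetic
secondary-chlorophyll-maximum (SCM) experiment — 24 bottles: eight DO
levels from 30 nM to 16 µM, each with a 15NO2- tracer, a 15NH4+ tracer,
and an unlabeled bottle. `python analysis/05_partition.py` prints:

```
bottle_id  mean_DO_nM    OCR  R_NO2ox  pct_NO2ox
 L1_15NO2        30.8   86.7     29.7       17.1
 L2_15NO2        52.6  112.5     53.5       23.8
 L3_15NO2       117.1  215.7     82.7       19.2
 L4_15NO2       262.7  399.2    107.1       13.4
 L5_15NO2       589.9  725.3    123.7        8.5
 L6_15NO2      3084.7 1774.9    135.2        3.8
 L7_15NO2     14754.8 2485.7    138.3        2.8

power law: pct = 85.2 * DO^-0.361 (r2 = 0.93, p = 0.00042, n = 7)
```

Reading it: OCR (nmol-O2 L⁻¹ day⁻¹) collapses as DO falls because
heterotrophic respiration has a weak O2 affinity (Km ≈ 1.8 µM), while
nitrite oxidation (Km ≈ 64 nM) barely slows — so its share of total
consumption (`pct_NO2ox`) rises from ~3% at 15 µM DO to ~20% below
100 nM, following a significant power law with negative exponent. The
30 nM bottle (L0) is absent: most of its readings fell below the 10 nM
detection limit and it is reported rate-indeterminate rather than
given a fabricated rate.

`analysis/04_kinetics.py` additionally refits synthetic 8-bottle
experiments generated at known affinities (10% rate noise, medians over
200 seeds):

```
     quantity  Km_true  Km_median  vmax_true  vmax_median  n_seeds
          OCR   1804.0     1865.1     2765.0       2805.3      200
NO2_oxidation     63.8       63.6      149.0        149.7      200
```

The same pipeline is scriptable (`omzox all --config
examples/scm_experiment.yaml --out results/scm`) and every stage can be
run on external CSV tables (see `src/omzox/io.py` for the schemas).

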