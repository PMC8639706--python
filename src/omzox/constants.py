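"""Physical constants and stoichiometry shared across the package.

Units convention: concentrations in nM (nmol L^-1), rates in nmol L^-1 day^-1,
time series in hours internally with explicit day/hour conversion at module
boundaries, isotope deltas in per mil, atom percent on the 0-100 scale.
"""

#: 15N/14N isotope ratio of atmospheric N2 (the delta-15N reference).
R15_AIR = 0.0036765

#: Natural-abundance atom percent 15N, i.e. 100 * R / (1 + R) at delta = 0.
NAT_ABUNDANCE_AT_PCT = 100.0 * R15_AIR / (1.0 + R15_AIR)

#: Moles of O2 consumed per mole of nitrite oxidized to nitrate.
O2_PER_NO2_OXIDIZED = 0.5

#: Moles of O2 consumed per mole of ammonia oxidized to nitrite
#: (canonical nitrification stoichiometry for the first step).
O2_PER_NH4_OXIDIZED = 1.5

HOURS_PER_DAY = 24.0

#: Measurement precision of natural-abundance nitrate isotope ratios (per mil).
PRECISION_D15N = 0.3
PRECISION_D18O = 0.4
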