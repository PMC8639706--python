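#!/usr/bin/env python
"""Partition oxygen consumption: what share does nitrite oxidation take?

Each 15NO2- bottle's rate is converted to O2 demand at 0.5 mol O2 per
mol N and divided by the same bottle's OCR; the percentage is regressed
on mean DO as a power law and inverted for the DO at which nitrite
oxidation would account for all consumption. Writes partition.csv and
prints the power-law fit and threshold.
"""

import logging
from pathlib import Path

from omzox.pipeline import PipelineConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"
CONFIG = PipelineConfig(seed=1)

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    tables = run_pipeline(CONFIG, outdir=OUTDIR, force=True, last_stage="partition")
    part = tables["partition"]
    pl = tables["power_law"]
    print(f"\nwrote {len(part)} partition records -> {OUTDIR}/partition.csv")
    print(
        part.sort_values("mean_DO_nM").to_string(
            index=False, float_format=lambda x: f"{x:.1f}"
        )
    )
    print(
        f"\npower law: pct = {pl['a']:.1f} * DO^{pl['b']:.3f} "
        f"(r2 = {pl['r2']:.2f}, p = {pl['p']:.2g}, n = {pl['n']})"
    )
    print(
        "nitrite oxidation accounts for all consumption below "
        f"{pl['threshold_DO_nM']:.0f} nM DO (extrapolated)"
    )
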