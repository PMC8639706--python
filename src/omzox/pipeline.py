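"""End-to-end pipeline: simulate (or load) -> rates -> OCR -> kinetics ->
partition -> isotopes.

Each stage consumes the tables the previous stage produced and writes its
own table under the output directory; a run manifest records the seed,
package version, and a hash of the configuration, and a run refuses to
write into a directory holding a different configuration hash unless
forced. One structured log line per stage reports records in/out/dropped
so every filtering step is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from . import __version__
from .kinetics import fit_low_level_km, fit_michaelis_menten
from .oxygen import linearity_classification, ocr_endpoint, ocr_regression, replicate_ocr
from .partition import PartitionRecord, fit_power_law, threshold_do
from .isotopes import NitrateIsotopeMeasurement, deviation_profile
from .simulate import (
    SimulationConfig,
    amz_template,
    observe_bottle,
    simulate_bottle,
    simulate_experiment,
    simulate_profile,
    simulate_profile_isotopes,
    default_scenarios,
)
from .tracer import (
    DEFAULT_ATPCT_SD,
    TracerIncubation,
    ammonia_oxidation_rate,
    nitrite_oxidation_rate,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rates", "ocr", "kinetics", "partition", "isotopes")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, schema-validated up front."""

    seed: int = 0
    scenario: str = "scm"  # base bottle scenario for the simulate stage
    DO_levels: tuple = (30.0, 60.0, 120.0, 250.0, 500.0, 1000.0, 4000.0, 16000.0)
    duration_hours: float = 24.0
    sensor_sd: float = 2.0  # nM
    sensor_detection_limit: float = 10.0  # nM
    atpct_sd: float = DEFAULT_ATPCT_SD
    spike_fraction: float = 0.075
    # thresholds
    r2_threshold: float = 0.6
    mic_gap_threshold: float = 0.2
    detect_multiplier: float = 3.0
    low_level_do_cutoff: float = 235.0  # nM
    partition_do_ceiling: float = 18_000.0  # nM, profile records only
    # stoichiometry (mol O2 per mol N)
    o2_per_no2: float = 0.5
    o2_per_nh4: float = 1.5
    # optional external inputs replacing the simulate stage
    input_endpoints: str | None = None
    input_timeseries: str | None = None
    input_profiles: str | None = None
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        if len(self.DO_levels) == 0:
            raise ValueError("DO_levels must be non-empty")
        if any(d <= 0 for d in self.DO_levels):
            raise ValueError("DO levels must be positive")
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must lie in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if "DO_levels" in data:
            data["DO_levels"] = tuple(data["DO_levels"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["DO_levels"] = list(self.DO_levels)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _stage_log(stage: str, n_in: int, n_out: int, dropped: int = 0) -> None:
    logger.info(
        "stage=%s records_in=%d records_out=%d dropped=%d", stage, n_in, n_out, dropped
    )


def _simulate_stage(cfg: PipelineConfig) -> dict:
    scenarios = default_scenarios()
    if cfg.scenario not in scenarios:
        raise PipelineError(
            f"simulate stage: unknown scenario {cfg.scenario!r} "
            f"(available: {sorted(scenarios)})"
        )
    base = dataclasses.replace(
        scenarios[cfg.scenario],
        duration=cfg.duration_hours,
        sensor_sd=cfg.sensor_sd,
        sensor_detection_limit=cfg.sensor_detection_limit,
        atpct_sd=cfg.atpct_sd,
        o2_per_no2=cfg.o2_per_no2,
        o2_per_nh4=cfg.o2_per_nh4,
    )
    observations = simulate_experiment(
        base,
        cfg.DO_levels,
        seed=cfg.seed,
        spike_fraction=cfg.spike_fraction,
    )
    ts_rows, ep_rows = [], []
    for obs in observations:
        for t, do, cen in zip(obs.times, obs.DO, obs.censored):
            ts_rows.append(
                {
                    "bottle_id": obs.bottle_id,
                    "time_h": float(t),
                    "DO_nM": float(do),
                    "censored": bool(cen),
                }
            )
        ep_rows.append(obs.record)
    timeseries = pd.DataFrame(ts_rows)
    endpoints = pd.DataFrame(ep_rows)

    template = amz_template()
    rows, _configs = simulate_profile(template)
    d15, d18 = simulate_profile_isotopes(template)
    profiles = pd.DataFrame(rows)
    profiles["delta15N"] = d15
    profiles["delta18O"] = d18
    _stage_log("simulate", len(cfg.DO_levels) * 3, len(endpoints))
    return {"endpoints": endpoints, "timeseries": timeseries, "profiles": profiles}


def _rates_stage(cfg: PipelineConfig, tables: dict) -> dict:
    endpoints = oio.apply_substitutions(tables["endpoints"])
    # ammonia-oxidation rates first: they feed the dilution term
    ao_by_level: dict = {}
    rows = []
    dropped = 0
    for _, rec in endpoints[endpoints["treatment"] == "15NH4"].iterrows():
        try:
            est = ammonia_oxidation_rate(
                atpct_product_t=rec["atpct_product_t"],
                atpct_product_0=rec["atpct_product_0"],
                product_pool_conc=rec["NO2_nM"] + rec["NO3_nM"],
                atpct_NH4=rec["atpct_NH4_0"],
                t_days=rec["t_hours"] / 24.0,
                atpct_sd=cfg.atpct_sd,
            )
        except ValueError as exc:
            raise PipelineError(
                f"rates stage: bottle {rec['bottle_id']}: {exc}"
            ) from exc
        ao_by_level[rec.get("DO_level_nM", rec["bottle_id"])] = est.value
        rows.append(
            {
                "bottle_id": rec["bottle_id"],
                "treatment": "15NH4",
                "rate": est.value,
                "se": est.se,
                "detectable": est.detectable,
                "method": est.method,
                "DO_level_nM": rec.get("DO_level_nM", np.nan),
                "DO_mean_nM": rec.get("DO_mean_nM", np.nan),
            }
        )
    for _, rec in endpoints[endpoints["treatment"] == "15NO2"].iterrows():
        level = rec.get("DO_level_nM", rec["bottle_id"])
        ambient_no2 = rec["NO2_nM"] / (1.0 + cfg.spike_fraction)
        spike = rec["NO2_nM"] - ambient_no2
        try:
            inc = TracerIncubation(
                n_t_raw=rec["atpct_NO3_t"],
                n_oNO3=rec["atpct_NO3_0"],
                NO3_conc=rec["NO3_nM"],
                NO2_conc_initial=ambient_no2,
                spike_conc=spike,
                t_days=rec["t_hours"] / 24.0,
                R_AO=ao_by_level.get(level, 0.0),
                atpct_sd=max(cfg.atpct_sd, 1e-12),
            )
            est = nitrite_oxidation_rate(inc)
        except ValueError as exc:
            raise PipelineError(
                f"rates stage: bottle {rec['bottle_id']}: {exc}"
            ) from exc
        rows.append(
            {
                "bottle_id": rec["bottle_id"],
                "treatment": "15NO2",
                "rate": est.value,
                "se": est.se,
                "detectable": est.detectable,
                "method": est.method,
                "DO_level_nM": rec.get("DO_level_nM", np.nan),
                "DO_mean_nM": rec.get("DO_mean_nM", np.nan),
            }
        )
    rates = pd.DataFrame(rows)
    _stage_log("rates", len(endpoints), len(rates), dropped)
    return {**tables, "rates": rates}


def _ocr_stage(cfg: PipelineConfig, tables: dict) -> dict:
    series_map = oio.timeseries_to_oxygen(
        tables["timeseries"], detection_limit=cfg.sensor_detection_limit
    )
    endpoints = tables["endpoints"].set_index("bottle_id")
    rows = []
    dropped = 0
    for bid, series in series_map.items():
        if series.censored_fraction > 0.5:
            dropped += 1
            rows.append(
                {
                    "bottle_id": bid,
                    "rate": np.nan,
                    "se": np.nan,
                    "r2": np.nan,
                    "mic": np.nan,
                    "classification": "rate-indeterminate",
                    "n_points": int((~series.censored).sum()),
                }
            )
            continue
        est = ocr_regression(series)
        cls = linearity_classification(
            series, cfg.r2_threshold, cfg.mic_gap_threshold
        )
        t_unc, do_unc = series.uncensored()
        rows.append(
            {
                "bottle_id": bid,
                "rate": est.rate,
                "se": est.se,
                "r2": cls.r2,
                "mic": cls.mic,
                "classification": cls.classification,
                "n_points": est.n_points,
                "DO_mean_nM": float(np.mean(do_unc)),
                "DO_level_nM": float(endpoints["DO_level_nM"].get(bid, np.nan))
                if "DO_level_nM" in endpoints.columns
                else np.nan,
            }
        )
    ocr = pd.DataFrame(rows)
    # replicate aggregation per DO level (the bottles at one level are
    # incubation replicates of the same water)
    agg_rows = []
    if "DO_level_nM" in ocr.columns:
        for level, grp in ocr.dropna(subset=["rate"]).groupby("DO_level_nM"):
            if len(grp) >= 2:
                mean, sd, full = replicate_ocr(list(grp["rate"]))
                agg_rows.append(
                    {
                        "DO_level_nM": level,
                        "OCR_mean": mean,
                        "OCR_sd": sd,
                        "n": len(grp),
                        "full_replication": full,
                    }
                )
    ocr_agg = pd.DataFrame(agg_rows)
    _stage_log("ocr", len(series_map), len(ocr), dropped)
    return {**tables, "ocr": ocr, "ocr_replicates": ocr_agg}


def _kinetics_stage(cfg: PipelineConfig, tables: dict) -> dict:
    if "ocr" not in tables or "rates" not in tables:
        raise PipelineError("kinetics stage: needs the ocr and rates tables")
    ocr = tables["ocr"].dropna(subset=["rate"])
    if "DO_mean_nM" not in ocr.columns:
        raise PipelineError(
            "kinetics stage: ocr table lacks a DO_mean_nM column"
        )
    rows = []
    usable = ocr[(ocr["DO_mean_nM"] > 0) & (ocr["rate"] > 0)]
    if len(usable) >= 4:
        fit = fit_michaelis_menten(usable["DO_mean_nM"], usable["rate"])
        rows.append({"quantity": "OCR", "fit_kind": "overall", **dataclasses.asdict(fit)})
    no2 = tables["rates"]
    no2 = no2[(no2["treatment"] == "15NO2") & no2["detectable"]]
    no2 = no2[(no2["DO_mean_nM"] > 0) & (no2["rate"] > 0)]
    if len(no2) >= 4:
        fit = fit_michaelis_menten(no2["DO_mean_nM"], no2["rate"])
        rows.append(
            {"quantity": "NO2_oxidation", "fit_kind": "overall", **dataclasses.asdict(fit)}
        )
    # low-level fits on nonlinear, low-DO bottles
    series_map = oio.timeseries_to_oxygen(
        tables["timeseries"], detection_limit=cfg.sensor_detection_limit
    )
    nonlinear = tables["ocr"][
        (tables["ocr"]["classification"] == "nonlinear")
        & (tables["ocr"]["DO_mean_nM"] < cfg.low_level_do_cutoff)
    ]
    for bid in nonlinear["bottle_id"]:
        try:
            fit = fit_low_level_km(series_map[bid], do_cutoff=cfg.low_level_do_cutoff)
        except ValueError:
            continue
        rows.append(
            {
                "quantity": f"OCR[{bid}]",
                "fit_kind": "low_level",
                **dataclasses.asdict(fit),
            }
        )
    kin = pd.DataFrame(rows)
    _stage_log("kinetics", len(ocr) + len(no2), len(kin))
    return {**tables, "kinetics": kin}


def _partition_stage(cfg: PipelineConfig, tables: dict) -> dict:
    if "rates" not in tables or "ocr" not in tables:
        raise PipelineError("partition stage: needs the rates and ocr tables")
    rates = tables["rates"]
    ocr = tables["ocr"].set_index("bottle_id")
    records = []
    dropped = 0
    for _, row in rates[rates["treatment"] == "15NO2"].iterrows():
        bid = row["bottle_id"]
        # same-bottle pairing: the tracer bottle's own OCR where available
        if bid in ocr.index and np.isfinite(ocr.loc[bid, "rate"]):
            ocr_val = float(ocr.loc[bid, "rate"])
            do_val = float(ocr.loc[bid, "DO_mean_nM"])
        else:
            dropped += 1
            continue
        if ocr_val <= 0:
            dropped += 1
            logger.info(
                "partition stage: bottle %s has non-positive OCR, skipped", bid
            )
            continue
        records.append(
            PartitionRecord(
                mean_DO=do_val,
                OCR=ocr_val,
                R_NO2ox=float(row["rate"]),
                label=str(bid),
            )
        )
    part = pd.DataFrame(
        [
            {
                "bottle_id": r.label,
                "mean_DO_nM": r.mean_DO,
                "OCR": r.OCR,
                "R_NO2ox": r.R_NO2ox,
                "pct_NO2ox": r.pct_NO2ox,
            }
            for r in records
        ]
    )
    result: dict = {**tables, "partition": part}
    try:
        fit = fit_power_law(records)
        result["power_law"] = {
            "a": fit.a,
            "b": fit.b,
            "r2": fit.r2,
            "p": fit.p,
            "n": fit.n,
            "threshold_DO_nM": threshold_do(fit) if fit.b < 0 else float("nan"),
        }
    except ValueError as exc:
        logger.info("partition stage: power-law fit skipped (%s)", exc)
        result["power_law"] = None
    _stage_log("partition", len(rates), len(part), dropped)
    return result


def _isotopes_stage(cfg: PipelineConfig, tables: dict) -> dict:
    profiles = tables.get("profiles")
    if profiles is None or "delta15N" not in profiles.columns:
        raise PipelineError(
            "isotopes stage: profile table with delta15N/delta18O columns required"
        )
    rows = []
    for station, grp in profiles.groupby("station"):
        ms = [
            NitrateIsotopeMeasurement(
                depth=float(r["depth_m"]),
                delta15N=float(r["delta15N"]),
                delta18O=float(r["delta18O"]),
            )
            for _, r in grp.iterrows()
        ]
        prof = deviation_profile(ms)
        for depth, dev, sd in zip(prof.depths, prof.deviations, prof.sds):
            rows.append(
                {
                    "station": station,
                    "depth_m": depth,
                    "delta_15_18": dev,
                    "sd": sd,
                    "peak_depth_m": prof.peak_depth,
                }
            )
    dev = pd.DataFrame(rows)
    _stage_log("isotopes", len(profiles), len(dev))
    return {**tables, "deviations": dev}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    force: bool = False,
    last_stage: str = "isotopes",
) -> dict:
    """Run the pipeline through ``last_stage`` and return the table bundle.

    When ``outdir`` is given every table is written as CSV alongside a
    ``manifest.json``; a directory holding a manifest with a different
    config hash is refused unless ``force``.
    """
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    if outdir is not None:
        outdir = Path(outdir)
        manifest_path = outdir / "manifest.json"
        if manifest_path.exists() and not force:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") != config.config_hash():
                raise PipelineError(
                    f"output directory {outdir} holds results for config hash "
                    f"{old.get('config_hash')}; rerun with force=True to overwrite"
                )
        outdir.mkdir(parents=True, exist_ok=True)

    tables: dict = {}
    if config.input_endpoints:
        tables["endpoints"] = oio.read_endpoints(config.input_endpoints)
    if config.input_timeseries:
        tables["timeseries"] = oio.read_timeseries(config.input_timeseries)
    if config.input_profiles:
        tables["profiles"] = oio.read_profiles(config.input_profiles)

    n_last = STAGES.index(last_stage)
    active = [s for s in STAGES[: n_last + 1] if s in config.stages]
    for stage in active:
        try:
            if stage == "simulate":
                if "endpoints" not in tables:
                    tables.update(_simulate_stage(config))
            elif stage == "rates":
                tables = _rates_stage(config, tables)
            elif stage == "ocr":
                tables = _ocr_stage(config, tables)
            elif stage == "kinetics":
                tables = _kinetics_stage(config, tables)
            elif stage == "partition":
                tables = _partition_stage(config, tables)
            elif stage == "isotopes":
                tables = _isotopes_stage(config, tables)
        except PipelineError:
            raise
        except KeyError as exc:
            raise PipelineError(f"{stage} stage: missing input {exc}") from exc

    if outdir is not None:
        for name, table in tables.items():
            if isinstance(table, pd.DataFrame):
                header = f"# omzox config_hash={config.config_hash()}\n"
                path = outdir / f"{name}.csv"
                with open(path, "w") as fh:
                    fh.write(header)
                    table.to_csv(fh, index=False)
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "omzox_version": __version__,
            "config": config.to_dict(),
            "tables": sorted(
                k for k, v in tables.items() if isinstance(v, pd.DataFrame)
            ),
        }
        if tables.get("power_law"):
            manifest["power_law"] = tables["power_law"]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
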