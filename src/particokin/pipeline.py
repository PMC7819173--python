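"""Reproducible analysis pipeline: raw or simulated inputs -> aerosol summary,
burden/retention/ratio tables, and a clearance-kinetics table, with a
machine-readable provenance record.

The run is configured by a YAML file (see ``particokin/data/demo_study.yaml``)
holding either real input paths or a ``simulate`` block (exactly one of the
two), per-cell fit configurations, and a seed.  Outputs are plain CSV + JSON;
human tables round to reporting precision (retention to 0.1 %, ratios to
0.01, half-times to 0.1 d) while JSON keeps full precision.  Reruns of the
same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aerosol import SizeDistribution, summarize_one
from .burden import (co_to_single_ratio, fit_calibration, group_summary,
                     load_burden_table, retention_percent)
from .kinetics import (FitConfig, fit_one_phase, fit_two_phase,
                       retention_series_from_table)
from .simulate import ExposureSchedule, KineticTruth, NoiseModel, simulate_study

__all__ = ["RunConfig", "run_pipeline", "load_config", "PipelineError"]


class PipelineError(RuntimeError):
    """Structured pipeline failure carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths to aerosol/burden/calibration CSVs) or
    ``simulate`` (synthetic-study block) must be present.
    """

    outdir: str = "particokin-out"
    seed: int = 0
    inputs: dict | None = None
    simulate: dict | None = None
    fits: list = field(default_factory=list)
    ratio_mode: str = "ratio_of_means"
    n_per_timepoint: dict | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise PipelineError(
                "config", "exactly one of 'inputs' or 'simulate' must be set")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PipelineError("config", f"{path} is not a mapping")
    known = {"outdir", "seed", "inputs", "simulate", "fits", "ratio_mode",
             "n_per_timepoint"}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _simulate_records(config: RunConfig) -> pd.DataFrame:
    """Build a combined per-animal table from the simulate block.

    The block maps cells (analyte + group) to kinetic-truth parameters, e.g.::

        simulate:
          schedule: {hours_per_day: 6, days_per_week: 5, weeks: 4}
          noise: {burden_cv: 0.25, lung_weight_mean: 1.4, lung_weight_cv: 0.08}
          cells:
            - {analyte: Au, group: AuNP, daily_deposit: 466,
               fast_fraction: 0.0, half_time_fast: 81.5, half_time_slow: 81.5}
    """
    block = config.simulate
    schedule = ExposureSchedule(**block.get("schedule", {}))
    noise = NoiseModel(**block.get("noise", {}))
    n_map = config.n_per_timepoint or {"E-1": 4, "PEO-1": 5, "PEO-7": 5,
                                       "PEO-28": 5}
    frames = []
    for i, cell in enumerate(block.get("cells", [])):
        cell = dict(cell)
        analyte = cell.pop("analyte")
        group = cell.pop("group")
        for half_key, lam_key in (("half_time_fast", "lambda_fast"),
                                  ("half_time_slow", "lambda_slow")):
            if half_key in cell:
                cell[lam_key] = float(np.log(2) / cell.pop(half_key))
        truth = KineticTruth(**cell)
        study = simulate_study(truth, schedule=schedule, noise=noise,
                               n_per_timepoint=n_map, analyte=analyte,
                               group=group, seed=config.seed + i)
        frames.append(study.records)
    if not frames:
        raise PipelineError("simulate", "simulate block has no cells")
    return pd.concat(frames, ignore_index=True)


def _load_real_records(config: RunConfig) -> pd.DataFrame:
    paths = config.inputs
    if "burdens" not in paths:
        raise PipelineError("inputs", "missing 'burdens' CSV path")
    curves = None
    if paths.get("calibration"):
        cal = pd.read_csv(paths["calibration"])
        need = {"analyte", "spiked_ng_g", "measured_ng_g"}
        if not need.issubset(cal.columns):
            raise PipelineError("calibration",
                                f"calibration CSV needs columns {sorted(need)}")
        curves = {a: fit_calibration(sub[["spiked_ng_g", "measured_ng_g"]]
                                     .to_numpy(), analyte=a)
                  for a, sub in cal.groupby("analyte")}
    try:
        return load_burden_table(paths["burdens"], curves=curves)
    except (ValueError, OSError) as exc:
        raise PipelineError("burden", str(exc)) from exc


def _fit_cell(records_summary, retention_tables, fit_spec, seed: int) -> dict:
    analyte = fit_spec["analyte"]
    group = fit_spec["group"]
    model = fit_spec.get("model", "one-phase")
    key = (group, analyte)
    if key not in retention_tables:
        raise PipelineError("fit", f"no retention table for cell {key}")
    series = retention_series_from_table(
        retention_tables[key], analyte=analyte,
        exposure_mode=fit_spec.get("exposure_mode", "single"))
    cfg = FitConfig(fraction_constraint=fit_spec.get("fast_fraction"),
                    seed=seed)
    try:
        if model == "two-phase":
            fit = fit_two_phase(series, cfg)
        elif model == "one-phase":
            fit = fit_one_phase(series, cfg)
        else:
            raise PipelineError("fit", f"unknown model {model!r}")
    except Exception as exc:
        raise PipelineError("fit", f"cell {key} ({model}): {exc}") from exc
    row = {"analyte": analyte, "group": group, **fit.summary()}
    return row


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory tables: ``aerosol`` (or None),
    ``summary``, ``retention``, ``ratios``, ``kinetics``, ``provenance``.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    aerosol_rows = None
    if config.inputs and config.inputs.get("aerosol"):
        aerosol_rows = []
        for spec in config.inputs["aerosol"]:
            spec = dict(spec)
            path = spec.pop("path")
            density = spec.pop("density", None)
            label = spec.pop("label", Path(path).stem)
            try:
                dist = SizeDistribution.from_csv(path)
            except Exception as exc:
                raise PipelineError("aerosol", f"{path}: {exc}") from exc
            rec = summarize_one(dist, density=density)
            rec["label"] = label
            aerosol_rows.append(rec)
        aerosol = pd.DataFrame(aerosol_rows).set_index("label")
        _write_csv(aerosol.reset_index(), out / "aerosol_summary.csv")
    else:
        aerosol = None

    records = (_simulate_records(config) if config.simulate
               else _load_real_records(config))
    summary = group_summary(records)

    retention_tables = {}
    retention_frames = []
    kinetic_cells = config.fits or _default_fits(summary)
    for spec in kinetic_cells:
        key = (spec["group"], spec["analyte"])
        if key in retention_tables:
            continue
        try:
            tab = retention_percent(summary, group=spec["group"],
                                    analyte=spec["analyte"],
                                    records=records, mode=config.ratio_mode
                                    if config.ratio_mode in
                                    ("ratio_of_means", "mean_of_ratios")
                                    else "ratio_of_means")
        except ValueError as exc:
            raise PipelineError("retention", str(exc)) from exc
        retention_tables[key] = tab
        retention_frames.append(tab)
    retention = (pd.concat(retention_frames, ignore_index=True)
                 if retention_frames else pd.DataFrame())

    ratio_frames = []
    co_groups = sorted(set(summary["group"]) & {"AuNP+AgNP"})
    for co_group in co_groups:
        for analyte in sorted(set(summary.loc[summary["group"] == co_group,
                                              "analyte"])):
            single_group = f"{analyte}NP"
            if single_group not in set(summary["group"]):
                continue
            ratio_frames.append(co_to_single_ratio(
                summary, analyte, co_group=co_group,
                single_group=single_group, records=records,
                mode=config.ratio_mode))
    ratios = (pd.concat(ratio_frames, ignore_index=True)
              if ratio_frames else pd.DataFrame())

    kinetics_rows = [_fit_cell(summary, retention_tables, spec, config.seed)
                     for spec in kinetic_cells]
    kinetics = pd.DataFrame(kinetics_rows)

    _write_csv(summary, out / "burden_summary.csv")
    _write_csv(_round(retention, {"retention_pct": 1, "se_pct": 1}),
               out / "retention.csv")
    if not ratios.empty:
        _write_csv(_round(ratios, {"ratio": 2, "se_ratio": 2}),
                   out / "ratios.csv")
    _write_csv(_round(kinetics, {"half_time_d": 1, "half_time_fast_d": 1,
                                 "half_time_slow_d": 1}),
               out / "kinetics.csv")

    provenance = {
        "package": "particokin",
        "version": __version__,
        "seed": config.seed,
        "ratio_mode": config.ratio_mode,
        "mode": "simulate" if config.simulate else "real",
        "config": {k: v for k, v in vars(config).items() if v is not None},
        "n_records": int(len(records)),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    with open(out / "kinetics.json", "w") as fh:
        json.dump(kinetics_rows, fh, indent=2, sort_keys=True)

    return {"aerosol": aerosol, "records": records, "summary": summary,
            "retention": retention, "ratios": ratios, "kinetics": kinetics,
            "provenance": provenance, "outdir": out}


def _default_fits(summary: pd.DataFrame) -> list:
    """One-phase for Au cells, constrained two-phase for Ag cells — the
    a-priori model assignment for biopersistent vs biosoluble analytes."""
    fits = []
    for (group, analyte), _ in summary.groupby(["group", "analyte"]):
        if group == "control":
            continue
        mode = "co" if "+" in group else "single"
        if analyte == "Au":
            fits.append({"analyte": analyte, "group": group,
                         "model": "one-phase", "exposure_mode": mode})
        else:
            fits.append({"analyte": analyte, "group": group,
                         "model": "two-phase", "exposure_mode": mode,
                         "fast_fraction": 0.5 if mode == "co" else 1 / 3})
    return fits


def _round(df: pd.DataFrame, spec: dict) -> pd.DataFrame:
    df = df.copy()
    for col, nd in spec.items():
        if col in df.columns:
            df[col] = df[col].astype(float).round(nd)
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float formatting keeps reruns byte-identical
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
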