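"""Readers/writers for the project's delimited-text dialects and the
pipeline orchestrator.

All streams are CSV with a header row; no binary formats.  Gaze files carry
``time_s`` plus either ``az_deg``/``el_deg`` or a unit direction vector
``gx, gy, gz`` (converted on read), optional ``valid``, ``head_az_deg`` and
``aoi`` columns.  Driving files carry ``time_s, dist_m, lane_offset_cm,
brake, speed_kmh``.  Configuration is a YAML file with one section per
pipeline stage; a run is fully described by (config, seed, inputs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eab as eab_mod
from .config import ConfigError, ProjectConfig
from .masking import vector_to_azel
from .metrics import aggregate, compute_scenario_metrics, records_frame
from .preprocess import preprocess

__all__ = [
    "read_gaze", "write_gaze", "read_drive", "write_drive",
    "read_config", "write_config", "write_study", "read_study",
    "run_pipeline", "PipelineError",
]

_GAZE_MAP = {"time_s": "time", "az_deg": "az", "el_deg": "el",
             "head_az_deg": "head_az", "valid": "valid", "aoi": "aoi"}
_DRIVE_MAP = {"time_s": "time", "dist_m": "dist",
              "lane_offset_cm": "lane_offset", "brake": "brake",
              "speed_kmh": "speed_kmh"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and the input."""


def _numeric(frame: pd.DataFrame, column: str, path) -> pd.Series:
    raw = frame[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
            f"{column!r} at line {line}"
        )
    return values


def _parse_bool(series: pd.Series) -> np.ndarray:
    if series.dtype == bool:
        return series.to_numpy()
    mapped = series.astype(str).str.strip().str.lower().map(
        {"true": True, "false": False, "1": True, "0": False,
         "t": True, "f": False}
    )
    return mapped.fillna(False).to_numpy(dtype=bool)


def read_gaze(path) -> pd.DataFrame:
    """Read a gaze log; columns are matched by name, order-independent."""
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    out = pd.DataFrame({"time": _numeric(frame, "time_s", path)})
    if "az_deg" in frame.columns:
        out["az"] = _numeric(frame, "az_deg", path)
        out["el"] = (_numeric(frame, "el_deg", path)
                     if "el_deg" in frame.columns else 0.0)
    elif {"gx", "gy", "gz"} <= set(frame.columns):
        az, el, valid = vector_to_azel(
            _numeric(frame, "gx", path), _numeric(frame, "gy", path),
            _numeric(frame, "gz", path),
        )
        out["az"], out["el"] = az, el
        out["valid"] = valid
    else:
        raise ValueError(
            f"{path}: need either column 'az_deg' or columns 'gx, gy, gz'"
        )
    if "valid" in frame.columns:
        out["valid"] = _parse_bool(frame["valid"])
    elif "valid" not in out.columns:
        out["valid"] = np.isfinite(out["az"].to_numpy())
    if "head_az_deg" in frame.columns:
        out["head_az"] = _numeric(frame, "head_az_deg", path)
    if "aoi" in frame.columns:
        out["aoi"] = frame["aoi"].astype(object)
    for extra in ("source", "excluded", "az_filt"):
        if extra in frame.columns:
            out[extra] = (_parse_bool(frame[extra]) if extra == "excluded"
                          else frame[extra])
    return out


def write_gaze(stream: pd.DataFrame, path) -> None:
    inverse = {v: k for k, v in _GAZE_MAP.items()}
    out = stream.rename(columns=inverse)
    out.to_csv(path, index=False)


def read_drive(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("time_s", "dist_m", "lane_offset_cm")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column {missing[0]!r}")
    out = pd.DataFrame({
        "time": _numeric(frame, "time_s", path),
        "dist": _numeric(frame, "dist_m", path),
        "lane_offset": _numeric(frame, "lane_offset_cm", path),
    })
    out["brake"] = (_parse_bool(frame["brake"]) if "brake" in frame.columns
                    else False)
    if "speed_kmh" in frame.columns:
        out["speed_kmh"] = _numeric(frame, "speed_kmh", path)
    return out


def write_drive(drive: pd.DataFrame, path) -> None:
    inverse = {v: k for k, v in _DRIVE_MAP.items()}
    drive.rename(columns=inverse).to_csv(path, index=False)


_REQUIRED_SECTIONS = ("rig", "mask", "buffer", "filter", "events", "metrics")


def read_config(path, strict: bool = True) -> ProjectConfig:
    """Load and validate a project configuration before any compute."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if strict:
        for section in _REQUIRED_SECTIONS:
            if section not in data:
                raise ConfigError(f"{path}: missing config section {section!r}")
    return ProjectConfig.from_dict(data)


def write_config(cfg: ProjectConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# study directories


def write_study(study: dict, outdir) -> Path:
    """Write a generated study as per-scenario CSV pairs plus manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for sc in study["scenarios"]:
        stem = f"{sc['subject']}_{sc['condition']}_{sc['intersection']}"
        write_gaze(sc["gaze"], outdir / f"{stem}_gaze.csv")
        write_drive(sc["drive"], outdir / f"{stem}_drive.csv")
        index_rows.append({
            "subject": sc["subject"], "condition": sc["condition"],
            "intersection": sc["intersection"],
            "gaze_file": f"{stem}_gaze.csv",
            "drive_file": f"{stem}_drive.csv",
        })
    pd.DataFrame(index_rows).to_csv(outdir / "scenarios.csv", index=False)
    study["manifest"].to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"master_seed": study.get("master_seed"),
                   "n_scenarios": len(study["scenarios"])}, fh, indent=2)
    return outdir


def read_study(directory):
    """Yield scenario dicts from a study directory written by write_study."""
    directory = Path(directory)
    index = pd.read_csv(directory / "scenarios.csv")
    for _, row in index.iterrows():
        yield {
            "subject": row["subject"], "condition": row["condition"],
            "intersection": row["intersection"],
            "gaze": read_gaze(directory / row["gaze_file"]),
            "drive": read_drive(directory / row["drive_file"]),
        }


# ---------------------------------------------------------------------------
# orchestration


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


_EAB_METRICS = ("lane_mean", "lane_variance", "phase_duration", "gaze_var",
                "gaze_mean", "gaze_min", "gaze_max", "fix_n_left",
                "fix_n_right", "fix_dur_left", "fix_dur_right",
                "sacc_amp_left", "sacc_amp_right")


def run_pipeline(scenarios, config: ProjectConfig | None = None,
                 out_dir=None, seed: int | None = None) -> dict:
    """Run preprocess -> events -> metrics -> EAB over a whole study.

    ``scenarios`` is an iterable of scenario dicts (``subject``,
    ``condition``, ``intersection``, ``gaze``, ``drive``) — e.g. the output
    of :func:`hemisim.synth.generate_study` or :func:`read_study`.  Returns
    a dict with the scenario-metrics table, aggregate summaries and EAB
    classifications; optionally writes every artifact plus a run log to
    ``out_dir``.
    """
    config = config or ProjectConfig()
    config.validate()
    records = []
    for sc in scenarios:
        key = f"{sc['subject']}/{sc['condition']}/{sc['intersection']}"
        try:
            gaze = preprocess(sc["gaze"], config.filter)
        except Exception as exc:
            raise PipelineError(f"stage 'preprocess' failed for {key}: {exc}") from exc
        try:
            rec = compute_scenario_metrics(
                gaze, sc["drive"], config.metrics, config.events,
                subject=sc["subject"], condition=sc["condition"],
                intersection=sc["intersection"],
            )
        except Exception as exc:
            raise PipelineError(f"stage 'metrics' failed for {key}: {exc}") from exc
        records.append(rec)
    table = records_frame(records)
    try:
        summaries = aggregate(table)
    except Exception as exc:
        raise PipelineError(f"stage 'aggregate' failed: {exc}") from exc

    eab_results = {}
    try:
        for metric in _EAB_METRICS:
            if metric in table.columns and (table["condition"] == "NV").any():
                eab_results[metric] = eab_mod.eab_table(table, metric)
        lane_buffers = (
            eab_mod.lane_buffer_counts(eab_results["lane_mean"]["classifications"])
            if "lane_mean" in eab_results else None
        )
        blind_seeing = (
            eab_mod.blind_seeing_fixation_table(table)
            if {"LHH", "RHH"} <= set(table["condition"]) else None
        )
    except Exception as exc:
        raise PipelineError(f"stage 'eab' failed: {exc}") from exc

    result = {
        "metrics": table,
        "summaries": summaries,
        "eab": eab_results,
        "lane_buffers": lane_buffers,
        "blind_seeing_fixations": blind_seeing,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "scenario_metrics.csv", index=False)
        summaries["summary"].to_csv(out_dir / "summary.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(_jsonify({k: v for k, v in summaries.items()
                                if k != "summary"}), fh, indent=2)
        eab_rows = []
        for metric, res in eab_results.items():
            cls = res["classifications"].assign(metric=metric)
            eab_rows.append(cls)
        if eab_rows:
            pd.concat(eab_rows, ignore_index=True).to_csv(
                out_dir / "eab_classifications.csv", index=False)
        with open(out_dir / "eab_counts.json", "w") as fh:
            json.dump(_jsonify({m: r["counts"] for m, r in eab_results.items()}),
                      fh, indent=2)
        if lane_buffers is not None:
            lane_buffers.to_csv(out_dir / "lane_buffers.csv", index=False)
        if blind_seeing is not None:
            blind_seeing["counts"].to_csv(
                out_dir / "blind_seeing_counts.csv", index=False)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump({"config_hash": config.hash(), "seed": seed,
                       "n_scenarios": int(len(table)),
                       "config": _jsonify(config.to_dict())}, fh, indent=2)
    return result
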