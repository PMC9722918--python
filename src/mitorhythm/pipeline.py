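"""End-to-end time-course orchestration: images per timepoint →
segmentation → per-cell morphology → per-timepoint aggregation →
rhythm detection on the aggregate metrics.

Input layout: a directory containing one subdirectory per timepoint
named ``t<hours>`` (e.g. ``t12``), each holding single-channel TIFFs,
or a manifest CSV with columns ``path,time_h``; when both are given the
manifest wins.  The rhythm stage fits a cosinor (and optionally the
JTK-style test) to four metrics over time — fission fraction, fusion
fraction, median mitochondrial length and mitochondrial-mask MFI — with
per-cell values entering as pooled replicates.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as mio
from .morphology import classify_by_length, measure_objects, summarize_cells
from .rhythm import Cosinor, CosinorResults, JTKResult, jtk_test
from .segmentation import SegmentationParams, normalize_image, segment_cells, segment_mitochondria
from .types import CalibratedImage, ParameterError

logger = logging.getLogger("mitorhythm")

RHYTHM_METRICS = ("fission_score", "fusion_score", "median_length_um", "mfi")


class ConfigError(ParameterError):
    """The run configuration is missing, malformed or inconsistent."""


@dataclass(frozen=True)
class RhythmSettings:
    period_h: float = 24.0
    method: str = "cosinor"  # cosinor | jtk | both
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.method not in ("cosinor", "jtk", "both"):
            raise ConfigError(f"unknown rhythm method {self.method!r}")
        if self.period_h <= 0:
            raise ConfigError("period_h must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one time-course run."""

    pixel_size_um: float
    input_dir: str | None = None
    manifest: str | None = None
    output_dir: str = "mitorhythm_out"
    seed: int = 0
    log_level: str = "INFO"
    aggregate: str = "cell"  # cell | object
    save_labels: bool = True
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    rhythm: RhythmSettings = field(default_factory=RhythmSettings)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.aggregate not in ("cell", "object"):
            raise ConfigError(f"aggregate must be 'cell' or 'object', got {self.aggregate!r}")
        if self.input_dir is None and self.manifest is None:
            raise ConfigError("config needs input_dir or manifest")

    def canonical_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how verbosely we log do not change the result)."""
        d = asdict(self)
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(given: dict, allowed: set[str], context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, sorted(allowed), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown {context} key {key!r}{suffix}")


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a YAML run configuration.

    Unknown keys are rejected with a nearest-valid-key suggestion;
    ``pixel_size_um`` is mandatory and never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    top_allowed = {
        "pixel_size_um",
        "input_dir",
        "manifest",
        "output_dir",
        "seed",
        "log_level",
        "aggregate",
        "save_labels",
        "segmentation",
        "rhythm",
    }
    _check_keys(raw, top_allowed, "config")
    if "pixel_size_um" not in raw:
        raise ConfigError("config must state pixel_size_um explicitly")

    seg_raw = raw.get("segmentation", {}) or {}
    _check_keys(seg_raw, set(SegmentationParams.__dataclass_fields__), "segmentation")
    rhythm_raw = raw.get("rhythm", {}) or {}
    _check_keys(rhythm_raw, set(RhythmSettings.__dataclass_fields__), "rhythm")

    kwargs = {k: v for k, v in raw.items() if k not in ("segmentation", "rhythm")}
    # paths are resolved relative to the config file
    for key in ("input_dir", "manifest", "output_dir"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = str((path.parent / kwargs[key]).resolve())
    return RunConfig(
        segmentation=SegmentationParams(**seg_raw),
        rhythm=RhythmSettings(**rhythm_raw),
        **kwargs,
    )


def discover_inputs(config: RunConfig) -> pd.DataFrame:
    """Resolve the (path, time_h) image list from manifest or layout."""
    if config.manifest is not None:
        mf = pd.read_csv(config.manifest)
        if not {"path", "time_h"} <= set(mf.columns):
            raise ConfigError("manifest must have columns path,time_h")
        base = Path(config.manifest).parent
        mf = mf.copy()
        mf["path"] = [str((base / p).resolve()) for p in mf["path"]]
        return mf[["path", "time_h"]]
    root = Path(config.input_dir)  # type: ignore[arg-type]
    rows = []
    for sub in sorted(root.iterdir()):
        m = re.fullmatch(r"t(\d+(?:\.\d+)?)", sub.name)
        if not (sub.is_dir() and m):
            continue
        for tif in sorted(sub.glob("*.tif")) + sorted(sub.glob("*.tiff")):
            rows.append({"path": str(tif), "time_h": float(m.group(1))})
    if not rows:
        raise ConfigError(f"no timepoint images found under {root} (expected t<hours>/ dirs)")
    return pd.DataFrame(rows)


@dataclass
class TimecourseReport:
    """All outputs of one time-course run."""

    per_object: pd.DataFrame
    per_cell: pd.DataFrame
    per_timepoint: pd.DataFrame
    rhythm: dict[str, dict[str, object]]  # metric -> {"cosinor": CosinorResults|None, "jtk": ...}
    errors: list[dict]
    provenance: dict

    def rhythm_summary(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.rhythm.items():
            row: dict = {"metric": metric}
            cos = res.get("cosinor")
            if isinstance(cos, CosinorResults):
                row.update(
                    mesor=cos.mesor,
                    amplitude=cos.amplitude,
                    acrophase_h=cos.acrophase_h,
                    p_cosinor=cos.p_zero_amplitude,
                )
            jtk = res.get("jtk")
            if isinstance(jtk, JTKResult):
                row.update(p_jtk=jtk.p_adjusted, jtk_phase_h=jtk.best_phase_h)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return {
            "provenance": self.provenance,
            "per_timepoint": [
                {k: _clean(v) for k, v in row.items()}
                for row in self.per_timepoint.to_dict("records")
            ],
            "rhythm": [
                {k: _clean(v) for k, v in row.items()}
                for row in self.rhythm_summary().to_dict("records")
            ],
            "errors": self.errors,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_object.to_csv(out / "per_object.csv", index=False)
        self.per_cell.to_csv(out / "per_cell.csv", index=False)
        self.per_timepoint.to_csv(out / "per_timepoint.csv", index=False)
        self.rhythm_summary().to_csv(out / "rhythm_summary.csv", index=False)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2, default=str))


def _process_image(
    img: CalibratedImage, params: SegmentationParams
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Segment one image and return per-object records + per-cell summary."""
    norm = normalize_image(img)
    cells = segment_cells(norm, params)
    mito = segment_mitochondria(norm, params, cells)
    # MFI is measured on the raw intensities: per-image normalisation would
    # erase the across-timepoint intensity signal the MFI metric carries
    records = classify_by_length(measure_objects(mito, img, cells))
    cell_ids = [int(c) for c in np.unique(cells) if c > 0]
    summary = summarize_cells(records, cell_ids)
    # pixel-weighted mitochondrial MFI per cell
    px2 = img.pixel_area_um2
    mfi = []
    for cid in summary["cell_id"]:
        grp = records[records["cell_id"] == cid]
        if len(grp) == 0:
            mfi.append(np.nan)
        else:
            w = grp["area_um2"].to_numpy() / px2
            mfi.append(float(np.average(grp["mean_intensity"], weights=w)))
    summary = summary.assign(mfi=mfi)
    return records, summary, cells, mito


def run_morphology_timecourse(config: RunConfig) -> TimecourseReport:
    """Execute the full study-shaped analysis; deterministic given config.

    Unreadable images are recorded under ``errors`` and the run
    continues; the rhythm stage is skipped with a warning when fewer
    than 4 distinct timepoints are available.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    inputs = discover_inputs(config)
    out_dir = Path(config.output_dir)
    labels_dir = out_dir / "labels"
    if config.save_labels:
        labels_dir.mkdir(parents=True, exist_ok=True)

    objects, cells_rows, errors = [], [], []
    for _, item in inputs.iterrows():
        path, time_h = item["path"], float(item["time_h"])
        try:
            img = mio.read_image(path, config.pixel_size_um)
            records, summary, cells, mito = _process_image(img, config.segmentation)
        except Exception as exc:  # per-file fault isolation
            logger.error("failed on %s: %s", path, exc)
            errors.append({"path": str(path), "time_h": time_h, "error": str(exc)})
            continue
        stem = Path(path).stem
        logger.info("%s (t=%gh): %d cells, %d mitochondria", stem, time_h, summary.shape[0], len(records))
        records.insert(0, "image", stem)
        records.insert(0, "time_h", time_h)
        summary.insert(0, "image", stem)
        summary.insert(0, "time_h", time_h)
        objects.append(records)
        cells_rows.append(summary)
        if config.save_labels:
            mio.write_labels(labels_dir / f"{stem}_cells.tif", cells)
            mio.write_labels(labels_dir / f"{stem}_mito.tif", mito)

    per_object = pd.concat(objects, ignore_index=True) if objects else pd.DataFrame()
    per_cell = pd.concat(cells_rows, ignore_index=True) if cells_rows else pd.DataFrame()

    # --- per-timepoint aggregation (unit: cell, or object via config) ---
    tp_rows = []
    for time_h, grp in (per_cell.groupby("time_h") if len(per_cell) else ()):
        row = {"time_h": float(time_h), "n_cells": len(grp), "n_mito": int(grp["n_mito"].sum())}
        source = grp
        if config.aggregate == "object":
            source = _object_level_metrics(per_object[per_object["time_h"] == time_h])
        for metric in RHYTHM_METRICS:
            vals = source[metric].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            row[f"{metric}_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{metric}_sem"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            )
        tp_rows.append(row)
    per_timepoint = pd.DataFrame(tp_rows).sort_values("time_h", ignore_index=True) if tp_rows else pd.DataFrame()

    # --- rhythm stage ---
    rhythm: dict[str, dict[str, object]] = {}
    n_timepoints = per_cell["time_h"].nunique() if len(per_cell) else 0
    if n_timepoints < 4:
        logger.warning("only %d distinct timepoints: rhythm stage skipped", n_timepoints)
    else:
        unit = per_cell if config.aggregate == "cell" else _object_level_metrics(per_object)
        for metric in RHYTHM_METRICS:
            sub = unit[["time_h", metric]].dropna()
            entry: dict[str, object] = {"cosinor": None, "jtk": None}
            try:
                if config.rhythm.method in ("cosinor", "both"):
                    entry["cosinor"] = Cosinor(
                        sub["time_h"].to_numpy(), sub[metric].to_numpy(), config.rhythm.period_h
                    ).fit()
                if config.rhythm.method in ("jtk", "both"):
                    entry["jtk"] = jtk_test(
                        _as_timeseries(sub, metric), period_h=config.rhythm.period_h
                    )
            except ParameterError as exc:
                logger.warning("rhythm fit failed for %s: %s", metric, exc)
                errors.append({"path": None, "time_h": None, "error": f"rhythm[{metric}]: {exc}"})
            rhythm[metric] = entry

    provenance = {
        "config_hash": config.canonical_hash(),
        "version": __version__,
        "seed": config.seed,
        "n_images": int(len(inputs)),
        "n_timepoints": int(n_timepoints),
    }
    report = TimecourseReport(per_object, per_cell, per_timepoint, rhythm, errors, provenance)
    report.write(out_dir)
    return report


def _object_level_metrics(per_object: pd.DataFrame) -> pd.DataFrame:
    """Object-level pooling alternative: one row per object."""
    out = per_object[["time_h", "length_um", "mean_intensity", "length_class"]].copy()
    out["fission_score"] = (out["length_class"] == "short").astype(float)
    out["fusion_score"] = (out["length_class"] == "long").astype(float)
    out["median_length_um"] = out["length_um"]
    out["mfi"] = out["mean_intensity"]
    return out


def _as_timeseries(sub: pd.DataFrame, metric: str):
    from .rhythm import TimeSeries

    return TimeSeries(sub["time_h"].to_numpy(float), sub[metric].to_numpy(float), label=metric)
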