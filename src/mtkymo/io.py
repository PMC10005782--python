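"""Interchange formats: tidy CSV tables with unit-bearing headers, TIFF
rasters with sidecar calibration, spreadsheet workbook ingestion, YAML
configuration, and run manifests.

All CSV writers prepend a single comment line ``# mtkymo <kind> rows=<N>``;
readers verify the row count so silently truncated files are rejected.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .kymo import LifetimeRecord, PhaseSegment, SegConfig, Trace, TipDetectConfig
from .model import Calibration, DynamicsParameters, KymographImage, OpticsConfig, Trajectory
from .stats import Conventions, DynamicsSummary

TRACE_COLUMNS = ["mt_id", "frame_time_s", "tip_position_um", "condition"]
SEGMENT_COLUMNS = ["mt_id", "lifetime_index", "segment_index", "state",
                   "t_start_s", "t_end_s", "slope_um_per_min", "censored", "condition"]
SUMMARY_COLUMNS = ["mt_id", "growth_rate", "n_cat", "n_res", "n_pause",
                   "t_grow", "t_shrink", "t_pause", "t_excursion", "lifetime",
                   "f_cat", "f_res", "pause_pct", "censored", "condition"]

_FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """CSV/workbook does not match the expected schema."""


# ---------------------------------------------------------------------------
# CSV primitives

def _write_csv(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mtkymo {kind} rows={len(df)}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_csv(path, kind: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    declared = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "rows=" in first:
        declared = int(first.rsplit("rows=", 1)[1].split()[0])
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} file {path} is missing column(s): {', '.join(missing)}")
    if declared is not None and len(df) != declared:
        raise SchemaError(
            f"{kind} file {path} declares {declared} rows but contains {len(df)} "
            "(truncated or edited?)"
        )
    return df


# ---------------------------------------------------------------------------
# trace tables

def trace_table(items: list[Trajectory] | list[Trace], condition: str = "") -> pd.DataFrame:
    rows = []
    for k, item in enumerate(items):
        mt_id = getattr(item, "mt_id", None) or f"mt{k:04d}"
        times = item.frame_times
        pos = item.lengths if isinstance(item, Trajectory) else item.positions
        rows.append(pd.DataFrame({
            "mt_id": mt_id,
            "frame_time_s": times,
            "tip_position_um": pos,
            "condition": condition,
        }))
    return pd.concat(rows, ignore_index=True)


def write_trace_csv(table: pd.DataFrame, path) -> None:
    _write_csv(table[TRACE_COLUMNS], path, "trace-table")


def read_trace_csv(path) -> pd.DataFrame:
    df = _read_csv(path, "trace-table", TRACE_COLUMNS)
    if df.duplicated(["mt_id", "frame_time_s"]).any():
        raise SchemaError("duplicated (mt_id, frame_time_s) rows in trace table")
    for mt_id, grp in df.groupby("mt_id"):
        dt = np.diff(grp["frame_time_s"].to_numpy())
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            warnings.warn(f"non-uniform frame spacing for {mt_id}", stacklevel=2)
    return df


def traces_from_table(df: pd.DataFrame, calibration: Calibration | None = None) -> list[Trace]:
    out = []
    for mt_id, grp in df.groupby("mt_id", sort=True):
        grp = grp.sort_values("frame_time_s")
        out.append(Trace(
            frame_times=grp["frame_time_s"].to_numpy(dtype=float),
            positions=grp["tip_position_um"].to_numpy(dtype=float),
            calibration=calibration,
            mt_id=str(mt_id),
        ))
    return out


# ---------------------------------------------------------------------------
# segment tables

def segment_table(
    lifetimes_by_mt: dict[str, list[LifetimeRecord]], condition: str = ""
) -> pd.DataFrame:
    rows = []
    for mt_id, records in lifetimes_by_mt.items():
        for li, rec in enumerate(records):
            for si, seg in enumerate(rec.segments):
                rows.append({
                    "mt_id": mt_id, "lifetime_index": li, "segment_index": si,
                    "state": seg.state, "t_start_s": seg.t_start,
                    "t_end_s": seg.t_end, "slope_um_per_min": seg.slope,
                    "censored": rec.censored, "condition": condition,
                })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segment_csv(table: pd.DataFrame, path) -> None:
    _write_csv(table[SEGMENT_COLUMNS], path, "segment-table")


def read_segment_csv(path) -> pd.DataFrame:
    df = _read_csv(path, "segment-table",
                   [c for c in SEGMENT_COLUMNS if c != "censored"])
    if "censored" not in df.columns:
        df["censored"] = False
    for (mt_id, li), grp in df.groupby(["mt_id", "lifetime_index"]):
        grp = grp.sort_values("segment_index")
        if not np.allclose(grp["t_start_s"].to_numpy()[1:],
                           grp["t_end_s"].to_numpy()[:-1], atol=1e-6):
            raise SchemaError(f"segments of {mt_id} lifetime {li} are not contiguous")
    return df


def lifetimes_from_table(df: pd.DataFrame) -> dict[str, list[LifetimeRecord]]:
    out: dict[str, list[LifetimeRecord]] = {}
    for mt_id, mt_grp in df.groupby("mt_id", sort=True):
        records = []
        for li, grp in mt_grp.groupby("lifetime_index", sort=True):
            grp = grp.sort_values("segment_index")
            segs = [
                PhaseSegment(state=r.state, t_start=r.t_start_s, t_end=r.t_end_s,
                             slope=r.slope_um_per_min)
                for r in grp.itertuples()
            ]
            rec = LifetimeRecord(
                segments=segs, t_nucleation=segs[0].t_start,
                t_end=segs[-1].t_end, censored=bool(grp["censored"].iloc[0]),
            )
            rec.validate()
            records.append(rec)
        out[str(mt_id)] = records
    return out


# ---------------------------------------------------------------------------
# summary tables

def write_summary_csv(summaries: list[DynamicsSummary] | pd.DataFrame, path,
                      condition: str = "") -> None:
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([vars(s) for s in summaries])
        df["condition"] = condition
    _write_csv(df[SUMMARY_COLUMNS], path, "summary-table")


def read_summary_csv(path) -> pd.DataFrame:
    return _read_csv(path, "summary-table", SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# workbook ingestion

REQUIRED_WORKBOOK_KEYS = ["state", "t_start_s", "t_end_s"]
OPTIONAL_WORKBOOK_KEYS = ["slope_um_per_min", "mt_id", "lifetime_index"]


def read_condition_workbook(path, column_map: dict[str, str],
                            skip_sheets: tuple[str, ...] = ("read me", "readme")) -> pd.DataFrame:
    """Pool the per-experiment sheets of a measurements workbook.

    ``column_map`` names which workbook columns hold each logical field
    (required: state, t_start_s, t_end_s; optional: slope_um_per_min, mt_id,
    lifetime_index) — deposited layouts vary, so no guessing is attempted.
    Sheets named like a read-me are skipped by convention; unparseable
    sheets are skipped with a warning.  Returns a segment-table-like frame
    with an ``experiment`` provenance column.
    """
    missing = [k for k in REQUIRED_WORKBOOK_KEYS if k not in column_map]
    if missing:
        raise SchemaError(f"column_map is missing required key(s): {', '.join(missing)}")
    sheets = pd.read_excel(path, sheet_name=None)
    frames = []
    for name, sheet in sheets.items():
        if name.strip().lower() in skip_sheets:
            continue
        try:
            out = pd.DataFrame()
            for key, col in column_map.items():
                if col not in sheet.columns:
                    raise KeyError(col)
                out[key] = sheet[col]
            out = out.dropna(subset=REQUIRED_WORKBOOK_KEYS)
        except KeyError as exc:
            warnings.warn(f"skipping unparseable sheet {name!r}: missing column {exc}",
                          stacklevel=2)
            continue
        out["experiment"] = name
        frames.append(out)
    if not frames:
        raise SchemaError("no parseable sheets in workbook")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# TIFF rasters

def write_kymograph_tiff(kymo: KymographImage, path) -> None:
    """Write channels as a (channel, time, position) TIFF (lattice first)
    with a YAML sidecar recording calibration and channel order."""
    path = Path(path)
    names = sorted(kymo.channels, key=lambda n: (n != "lattice", n))
    data = np.stack([kymo.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "channels": names,
        "axes": "CTX",
        "calibration": {"frame_interval_s": kymo.calibration.frame_interval,
                        "pixel_size_um": kymo.calibration.pixel_size},
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_kymograph_tiff(path) -> KymographImage:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = Path(str(path) + ".yaml")
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text())
        names = meta["channels"]
        calib = Calibration(frame_interval=meta["calibration"]["frame_interval_s"],
                            pixel_size=meta["calibration"]["pixel_size_um"])
    else:
        names = ["lattice", "seed"][: data.shape[0]]
        calib = Calibration()
    if data.ndim == 2:
        data = data[None]
    return KymographImage(
        channels={n: data[i].astype(float) for i, n in enumerate(names)},
        calibration=calib,
    )


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


# ---------------------------------------------------------------------------
# configuration and manifests

def _build(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} field(s): {', '.join(sorted(unknown))}")
    return cls(**d)


def load_config(path) -> dict:
    """Load a structured YAML configuration into typed objects.

    Recognized top-level keys: ``parameters`` (DynamicsParameters),
    ``calibration``, ``optics``, ``segmentation`` (SegConfig), ``detection``
    (TipDetectConfig), ``conventions``; unknown keys are preserved as-is.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(raw)
    mapping = {
        "parameters": DynamicsParameters,
        "calibration": Calibration,
        "optics": OpticsConfig,
        "segmentation": SegConfig,
        "detection": TipDetectConfig,
        "conventions": Conventions,
    }
    for key, cls in mapping.items():
        if key in raw and isinstance(raw[key], dict):
            out[key] = _build(cls, raw[key])
    return out


def write_manifest(path, seed: int | None, configs: dict) -> None:
    """Record software version, seed, and every configuration in force."""
    def encode(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return dataclasses.asdict(v)
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    manifest = {"mtkymo_version": __version__, "seed": seed,
                "configs": {k: encode(v) for k, v in configs.items()}}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
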