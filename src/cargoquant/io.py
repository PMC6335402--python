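"""File I/O: CSV/TIFF/JSON schemas, run configuration and report bundles.

Schemas
-------
- trace CSV: ``time_s,position_nm`` plus a JSON metadata sidecar
  (``trap_stiffness_pN_per_nm``, ``sampling_rate_hz``, ``cargo_id``,
  ``experiment_id``, ``condition``);
- tracks CSV: ``track_id,frame,time_s,x_nm,y_nm``;
- image stacks: multi-page 16-bit TIFF;
- results: CSV tables plus a JSON manifest carrying the seed, parameters and
  package version so every report is reproducible from (config, seed).

All CSV output is comma-separated UTF-8 with a header row and ``.`` decimal
separator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import InputError
from .tracks import MotilitySegment, Track, segments_to_frame
from .trap import AdaptationProfile, AttemptRecord, ForceTrace, attempts_to_frame

__all__ = [
    "RunConfig",
    "load_config",
    "write_trace_csv",
    "read_trace_csv",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_stack",
    "read_stack",
    "write_attempts_csv",
    "read_attempts_csv",
    "write_profile_csv",
    "write_segments_csv",
    "write_json",
    "write_report",
]


@dataclass
class RunConfig:
    """One analysis or simulation run."""

    stage: str
    inputs: list[str] = field(default_factory=list)
    out_dir: str = "."
    seed: int = 0
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "stage" not in raw:
        raise InputError(f"config {path} must be a mapping with a 'stage' key")
    return RunConfig(**raw)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace_csv(trace: ForceTrace, path: str | Path) -> None:
    """Write a trace CSV plus its ``.json`` metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "position_nm": trace.position}).to_csv(
        path, index=False
    )
    meta = {
        "trap_stiffness_pN_per_nm": trace.trap_stiffness,
        "sampling_rate_hz": trace.sampling_rate,
        "cargo_id": trace.cargo_id,
        "experiment_id": trace.experiment_id,
        "condition": trace.condition,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trace_csv(path: str | Path, metadata: Mapping | None = None) -> ForceTrace:
    """Read a trace CSV; metadata from the sidecar unless supplied."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "position_nm"], path)
    if metadata is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise InputError(f"{path}: metadata sidecar {sidecar.name} not found")
        metadata = json.loads(sidecar.read_text())
    time = df["time_s"].to_numpy(dtype=float)
    trace = ForceTrace(
        time=time,
        position=df["position_nm"].to_numpy(dtype=float),
        trap_stiffness=float(metadata["trap_stiffness_pN_per_nm"]),
        sampling_rate=float(
            metadata.get("sampling_rate_hz") or 1.0 / float(np.median(np.diff(time)))
        ),
        cargo_id=str(metadata.get("cargo_id", "")),
        experiment_id=str(metadata.get("experiment_id", "")),
        condition=str(metadata.get("condition", "")),
    )
    trace.validate_uniform()
    return trace


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def write_tracks_csv(tracks: Sequence[Track], path: str | Path) -> None:
    frames = []
    for track in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": track.track_id,
                    "frame": np.arange(track.time.size),
                    "time_s": track.time,
                    "x_nm": track.xy[:, 0],
                    "y_nm": track.xy[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(
    path: str | Path,
    axis: Sequence[float] = (1.0, 0.0),
    condition: str = "",
) -> list[Track]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["track_id", "frame", "time_s", "x_nm", "y_nm"], path)
    tracks = []
    for track_id, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        time = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(time) <= 0):
            raise InputError(f"{path}: non-monotone time in track {track_id!r}")
        tracks.append(
            Track(
                track_id=str(track_id),
                time=time,
                xy=sub[["x_nm", "y_nm"]].to_numpy(dtype=float),
                axis=np.asarray(axis, dtype=float),
                condition=condition,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_stack(path: str | Path, n_frames: int | None = None) -> np.ndarray:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if n_frames is not None and stack.shape[0] < n_frames:
        raise InputError(
            f"{path}: stack has {stack.shape[0]} page(s), {n_frames} requested"
        )
    return stack


# ---------------------------------------------------------------------------
# tables and reports
# ---------------------------------------------------------------------------


def write_attempts_csv(attempts: Sequence[AttemptRecord], path: str | Path) -> None:
    attempts_to_frame(attempts).to_csv(path, index=False)


def read_attempts_csv(path: str | Path) -> list[AttemptRecord]:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(
        df,
        ["cargo_id", "attempt_index", "peak_force", "persistence_time", "outcome"],
        path,
    )
    return [
        AttemptRecord(
            cargo_id=str(row.cargo_id),
            attempt_index=int(row.attempt_index),
            peak_force=float(row.peak_force),
            persistence_time=float(row.persistence_time),
            outcome=str(row.outcome),
            start_time=float(getattr(row, "start_time", 0.0)),
            end_time=float(getattr(row, "end_time", 0.0)),
            experiment_id=str(getattr(row, "experiment_id", "")),
            condition=str(getattr(row, "condition", "")),
        )
        for row in df.itertuples(index=False)
    ]


def write_profile_csv(profile: AdaptationProfile, path: str | Path) -> None:
    table = profile.table.copy()
    table.insert(0, "condition", profile.condition)
    table.to_csv(path, index=False)


def write_segments_csv(segments: Sequence[MotilitySegment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def write_report(
    results: Mapping[str, object],
    out_dir: str | Path,
    seed: int | None = None,
    params: Mapping | None = None,
) -> list[Path]:
    """Write a report bundle: one CSV per DataFrame, one JSON for the rest,
    plus a run manifest (seed, parameters, version). File names are the
    result keys, so re-running the same config produces byte-identical
    tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scalars: dict[str, object] = {}
    for key in sorted(results):
        value = results[key]
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{key}.csv"
            value.to_csv(path, index=False)
            written.append(path)
        else:
            scalars[key] = value
    if scalars:
        path = out_dir / "summary.json"
        write_json(scalars, path)
        written.append(path)
    manifest = {
        "seed": seed,
        "params": _jsonable(dict(params or {})),
        "version": __version__,
    }
    manifest_path = out_dir / "manifest.json"
    write_json(manifest, manifest_path)
    written.append(manifest_path)
    return written
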