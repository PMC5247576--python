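"""Readers and writers for the plain-text and TIFF formats the pipeline uses.

Conventions: CSV is comma-separated, '.' decimal, UTF-8, mandatory header
row.  Time series are 2-column CSVs (``time_s`` plus a value column); videos
are multi-page TIFF stacks with an optional YAML sidecar carrying ``fps``
and ``pixel_size``.  Numeric round trips preserve at least 12 significant
digits (the shortest-repr float formatting used is exact).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .circuit import ExpressionTrace
from .electrochem import CurrentTrace, SignalSchedule
from .tracking import VideoStack


def _read_two_column(path: str | Path, value_column: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_s", value_column]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: malformed header {list(df.columns)!r}, expected {expected}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # offending data row bad[0]+1 (0-based); header is file row 1
        raise ValueError(
            f"{path}: time column not strictly increasing at data row {bad[0] + 3}")
    return t, df[value_column].to_numpy(dtype=float)


def write_series(path: str | Path, times: np.ndarray, values: np.ndarray,
                 value_column: str) -> None:
    # %.17g round-trips float64 exactly
    pd.DataFrame({"time_s": times, value_column: values}).to_csv(
        path, index=False, float_format="%.17g")


def read_current_trace(path: str | Path) -> CurrentTrace:
    t, v = _read_two_column(path, "current_A")
    return CurrentTrace(times=t, currents=v)


def write_current_trace(path: str | Path, trace: CurrentTrace) -> None:
    write_series(path, trace.times, trace.currents, "current_A")


def read_expression_trace(path: str | Path) -> ExpressionTrace:
    t, v = _read_two_column(path, "fluor_au")
    return ExpressionTrace(times=t, fluorescence=v)


def write_expression_trace(path: str | Path, trace: ExpressionTrace) -> None:
    write_series(path, trace.times, trace.fluorescence, "fluor_au")


def read_schedule(path: str | Path) -> SignalSchedule:
    """Potential program from CSV (potential_V, duration_s) or YAML.

    In either format an empty/null potential denotes open circuit.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(path.read_text())
        segs = [(None if s["potential_V"] is None else float(s["potential_V"]),
                 float(s["duration_s"])) for s in data["segments"]]
        return SignalSchedule(segs)
    df = pd.read_csv(path)
    if list(df.columns) != ["potential_V", "duration_s"]:
        raise ValueError(f"{path}: malformed header {list(df.columns)!r}")
    segs = [(None if pd.isna(E) else float(E), float(d))
            for E, d in zip(df["potential_V"], df["duration_s"])]
    return SignalSchedule(segs)


def write_schedule(path: str | Path, schedule: SignalSchedule) -> None:
    pd.DataFrame(schedule.segments, columns=["potential_V", "duration_s"]).to_csv(
        path, index=False)


def read_video(path: str | Path, fps: float | None = None,
               pixel_size: float | None = None) -> VideoStack:
    """Multi-page TIFF stack; metadata from a YAML sidecar (``<stem>.yaml``)
    unless given explicitly."""
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = path.with_suffix(".yaml")
    if (fps is None or pixel_size is None) and sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        fps = fps if fps is not None else meta.get("fps")
        pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    return VideoStack(frames=frames, fps=fps or 10.0, pixel_size=pixel_size or 0.32)


def write_video(path: str | Path, video: VideoStack,
                sidecar: bool = True) -> None:
    path = Path(path)
    tifffile.imwrite(path, video.frames)
    if sidecar:
        path.with_suffix(".yaml").write_text(yaml.safe_dump(
            {"fps": float(video.fps), "pixel_size": float(video.pixel_size)}))


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns)[:3] != ["fsc", "ssc", "green"]:
        raise ValueError(f"{path}: malformed header {list(df.columns)!r}, "
                         "expected fsc,ssc,green")
    return df


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def read_params(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_params(path: str | Path, params: dict) -> None:
    Path(path).write_text(yaml.safe_dump(params))
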