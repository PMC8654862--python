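"""Readers and writers for the package's artifact formats.

Movies are multi-page little-endian uncompressed TIFF with a JSON sidecar
(pixel size, frame interval, misc metadata) and an optional ground-truth
CSV; tracks, traces and cycle summaries are plain CSV (comma separated,
'.' decimal, header row, no index column).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .movie import MovieStack
from .tracking import SpotTrack
from .traces import AngleTrace

__all__ = [
    "save_movie", "load_movie",
    "save_track", "load_track",
    "save_trajectory", "load_trace",
    "save_json", "load_json",
]


def save_movie(stack: MovieStack, path) -> Path:
    """Write a movie as TIFF + sidecar JSON (+ ground-truth CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack",
                     byteorder="<", compression=None)
    meta = {"pixel_size_nm": stack.pixel_size,
            "frame_interval_s": stack.frame_interval}
    for key in ("seed", "drift_corrected"):
        if key in stack.meta:
            meta[key] = stack.meta[key]
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    if stack.ground_truth is not None:
        stack.ground_truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def load_movie(path) -> MovieStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    truth_path = path.with_suffix(".truth.csv")
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return MovieStack(frames, meta["pixel_size_nm"], meta["frame_interval_s"],
                      truth, meta)


def save_track(track: SpotTrack, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    track.to_dataframe().to_csv(path, index=False)
    return path


def load_track(path) -> SpotTrack:
    df = pd.read_csv(path)
    return SpotTrack(int(df.particle_id.iloc[0]) if len(df) else 0,
                     df.x_px.to_numpy(float), df.y_px.to_numpy(float),
                     df.intensity.to_numpy(float),
                     df.converged.to_numpy(bool), window_radius=np.nan)


def save_trajectory(traj, path) -> Path:
    """Mechanism trajectory as CSV (t, theta_deg, d1..d6) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_dataframe().to_csv(path, index=False)
    sidecar = {"seed": traj.seed, "dt": traj.dt,
               "record_every": traj.record_every, **traj.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def save_trace(trace: AngleTrace, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t": trace.times, "theta_deg": trace.theta}).to_csv(
        path, index=False)
    return path


def load_trace(path, dt=None) -> AngleTrace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(float)
    if dt is None:
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return AngleTrace(t, df["theta_deg"].to_numpy(float), dt)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())
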