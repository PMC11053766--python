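"""Synthetic gaze traces and the generic gaze file format.

Hardware eye-tracking is replaced by a fixation/saccade simulator: a
schedule of angular targets with dwell times produces fixation samples
(target plus isotropic Gaussian angular noise) joined by linearly
interpolated saccade samples of fixed duration.  Samples carry both pixel
and angular coordinates, pupil diameter, a validity flag and a
fixation/saccade label.

Traces round-trip through a generic CSV format with the fixed header

    timestamp_s, gaze_x_px, gaze_y_px, azimuth_deg, elevation_deg,
    pupil_mm, validity, label

written into system-timestamped files (``gaze_YYYYMMDDTHHMMSS.csv``).
A :class:`GazeRecorder` state machine mirrors a device-agnostic tracker
interface where the device and the sampling thread are started and
stopped separately.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import StateError
from .scene_synthesis import PinholeCamera

__all__ = [
    "GazeSample",
    "GazeRecorder",
    "simulate_gaze_trace",
    "write_gaze_file",
    "read_gaze_file",
    "recorder_control",
    "timestamped_path",
]

GAZE_CSV_COLUMNS = [
    "timestamp_s",
    "gaze_x_px",
    "gaze_y_px",
    "azimuth_deg",
    "elevation_deg",
    "pupil_mm",
    "validity",
    "label",
]


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze record in both pixel and angular coordinates."""

    timestamp_s: float
    gaze_x_px: float
    gaze_y_px: float
    azimuth_deg: float
    elevation_deg: float
    pupil_mm: float = 4.0
    valid: bool = True
    label: str = "fixation"


def timestamped_path(folder, stem: str, suffix: str, now: Optional[_dt.datetime] = None) -> Path:
    """``folder/stem_YYYYMMDDTHHMMSS(suffix)``, deduplicated with _1, _2, ... on collision."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    stamp = (now or _dt.datetime.now()).strftime("%Y%m%dT%H%M%S")
    path = folder / f"{stem}_{stamp}{suffix}"
    counter = 1
    while path.exists():
        path = folder / f"{stem}_{stamp}_{counter}{suffix}"
        counter += 1
    return path


def simulate_gaze_trace(
    schedule: Sequence[Tuple[Tuple[float, float], float]],
    camera: PinholeCamera,
    rate_hz: float = 120.0,
    noise_sd_deg: float = 0.0,
    saccade_duration_s: float = 0.03,
    pupil_mm: float = 4.0,
    seed: Optional[int] = None,
) -> List[GazeSample]:
    """Fixation/saccade trace over a schedule of ((azimuth, elevation), dwell) entries.

    Fixation samples are the target plus isotropic Gaussian angular noise;
    samples between consecutive targets are linearly interpolated over
    ``saccade_duration_s`` and labelled ``saccade``.  Deterministic given
    the seed; sample count equals total duration x rate (+/- 1).
    """
    if not schedule:
        raise ValueError("gaze schedule is empty")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    for (_, dwell) in schedule:
        if dwell <= 0:
            raise ValueError("dwell times must be positive")
    rng = np.random.default_rng(seed)

    # segment list: (t_start, t_end, kind, target or (from, to))
    segments = []
    t = 0.0
    for i, (target, dwell) in enumerate(schedule):
        segments.append((t, t + dwell, "fixation", target))
        t += dwell
        if i + 1 < len(schedule) and saccade_duration_s > 0:
            segments.append((t, t + saccade_duration_s, "saccade", (target, schedule[i + 1][0])))
            t += saccade_duration_s
    duration = t

    samples: List[GazeSample] = []
    for ts in np.arange(0.0, duration, 1.0 / rate_hz):
        seg = next(s for s in segments if s[0] <= ts < s[1] or s is segments[-1])
        if seg[2] == "fixation":
            az, el = seg[3]
            az += rng.normal(0.0, noise_sd_deg) if noise_sd_deg > 0 else 0.0
            el += rng.normal(0.0, noise_sd_deg) if noise_sd_deg > 0 else 0.0
            label = "fixation"
        else:
            (az0, el0), (az1, el1) = seg[3]
            frac = (ts - seg[0]) / (seg[1] - seg[0])
            az = az0 + frac * (az1 - az0)
            el = el0 + frac * (el1 - el0)
            label = "saccade"
        x, y = camera.pixel_from_angles(az, el)
        samples.append(
            GazeSample(
                timestamp_s=float(ts),
                gaze_x_px=float(x),
                gaze_y_px=float(y),
                azimuth_deg=float(az),
                elevation_deg=float(el),
                pupil_mm=pupil_mm,
                valid=True,
                label=label,
            )
        )
    return samples


def write_gaze_file(
    trace: Sequence[GazeSample],
    folder,
    session_id: Optional[str] = None,
    now: Optional[_dt.datetime] = None,
) -> Path:
    """Write a trace as generic gaze CSV into a system-timestamped file; returns the path."""
    stem = f"gaze_{session_id}" if session_id else "gaze"
    path = timestamped_path(folder, stem, ".csv", now=now)
    frame = pd.DataFrame(
        {
            "timestamp_s": [s.timestamp_s for s in trace],
            "gaze_x_px": [s.gaze_x_px for s in trace],
            "gaze_y_px": [s.gaze_y_px for s in trace],
            "azimuth_deg": [s.azimuth_deg for s in trace],
            "elevation_deg": [s.elevation_deg for s in trace],
            "pupil_mm": [s.pupil_mm for s in trace],
            "validity": [s.valid for s in trace],
            "label": [s.label for s in trace],
        }
    )
    # full-precision floats so a write -> read round trip is exact
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_gaze_file(path) -> List[GazeSample]:
    """Read a generic gaze CSV; validates the header and timestamp monotonicity."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != GAZE_CSV_COLUMNS:
        raise ValueError(f"malformed gaze file header: {list(frame.columns)}")
    times = frame["timestamp_s"].to_numpy()
    if np.any(np.diff(times) <= 0):
        raise ValueError("gaze timestamps must be strictly increasing")
    return [
        GazeSample(
            timestamp_s=float(r.timestamp_s),
            gaze_x_px=float(r.gaze_x_px),
            gaze_y_px=float(r.gaze_y_px),
            azimuth_deg=float(r.azimuth_deg),
            elevation_deg=float(r.elevation_deg),
            pupil_mm=float(r.pupil_mm),
            valid=bool(r.validity),
            label=str(r.label),
        )
        for r in frame.itertuples()
    ]


@dataclass(frozen=True)
class GazeRecorder:
    """Device/sampling state machine of a device-agnostic tracker interface."""

    device_started: bool = False
    sampling: bool = False
    rate_hz: float = 120.0
    output_folder: str = "."


def recorder_control(recorder: GazeRecorder, action: str) -> GazeRecorder:
    """Apply start/stop transitions; illegal transitions raise StateError.

    Stopping the device while sampling also stops sampling (cascade).
    """
    if action == "start_device":
        return replace(recorder, device_started=True)
    if action == "stop_device":
        return replace(recorder, device_started=False, sampling=False)
    if action == "start_sampling":
        if not recorder.device_started:
            raise StateError("cannot start sampling on a stopped device")
        return replace(recorder, sampling=True)
    if action == "stop_sampling":
        return replace(recorder, sampling=False)
    raise ValueError(f"unknown recorder action {action!r}")
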