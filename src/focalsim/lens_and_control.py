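"""Focus-tunable lens dynamics and focus-control policies.

The tunable lens is modelled with exactly the two temporal parameters real
focus-tunable eyewear is specified by: a pure transport ``delay_s`` before
a command takes effect and a slew-rate limit ``rate_limit_D_per_s`` on how
fast the optical power can change.  After the delay the power tracks the
(range-clamped) command without overshoot and settles exactly on it.

Three control policies translate gaze and scene depth into power commands:

* :class:`GazePointController` — focus at the depth under the gaze point
  (robustified by a 5x5 median window, optionally smoothed over time);
* :class:`DepthModeController` — focus at the most frequent dioptric depth
  within a foveal radius of the gaze point (0.25 D histogram bins, ties
  broken toward the nearer bin);
* :class:`ManualController` — piecewise-constant power from time-stamped
  user step inputs (events effective at t >= event time).

:func:`progressive_power` models a progressive-addition lens: distance
power above the corridor, distance + add below it, linear in between, as a
function of gaze elevation.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .eye_optics import EyeModel, dioptric_demand, total_focus
from .gaze_sim_io import GazeSample
from .scene_synthesis import RGBDScene

__all__ = [
    "TunableLens",
    "ideal_lens",
    "lens_step",
    "ProgressiveLensMap",
    "progressive_power",
    "GazePointController",
    "DepthModeController",
    "ManualController",
    "run_closed_loop",
]

#: Width of the dioptric histogram bins used by DepthModeController.
DEPTH_MODE_BIN_D = 0.25

#: Side of the square median window used to robustify gaze depth (pixels).
GAZE_MEDIAN_WINDOW = 5


@dataclass
class TunableLens:
    """Focus-tunable lens state: power range, slew-rate limit, command delay.

    ``time_s`` is the lens's internal clock, advanced by :func:`lens_step`.
    """

    power_min_D: float = 0.0
    power_max_D: float = 4.0
    rate_limit_D_per_s: float = math.inf
    delay_s: float = 0.0
    current_power_D: float = 0.0
    time_s: float = 0.0
    _pending: List[Tuple[float, int, float]] = field(default_factory=list, repr=False)
    _target: Optional[float] = field(default=None, repr=False)
    _seq: "itertools.count" = field(default_factory=itertools.count, repr=False)

    def __post_init__(self) -> None:
        if self.power_min_D > self.power_max_D:
            raise ValueError("power_min_D must not exceed power_max_D")
        if self.rate_limit_D_per_s <= 0:
            raise ValueError("rate_limit_D_per_s must be positive")
        if self.delay_s < 0:
            raise ValueError("delay_s must be nonnegative")
        self.current_power_D = float(np.clip(self.current_power_D, self.power_min_D, self.power_max_D))
        if self._target is None:
            self._target = self.current_power_D

    def copy(self) -> "TunableLens":
        return TunableLens(
            power_min_D=self.power_min_D,
            power_max_D=self.power_max_D,
            rate_limit_D_per_s=self.rate_limit_D_per_s,
            delay_s=self.delay_s,
            current_power_D=self.current_power_D,
        )


def ideal_lens(power_min_D: float = 0.0, power_max_D: float = 4.0) -> TunableLens:
    """Lens with no delay and unbounded slew rate (settles within one step)."""
    return TunableLens(power_min_D=power_min_D, power_max_D=power_max_D)


def _advance(lens: TunableLens, dt: float) -> None:
    """Move the power toward the active target for dt seconds, no overshoot."""
    if dt <= 0:
        return
    gap = lens._target - lens.current_power_D
    if math.isinf(lens.rate_limit_D_per_s):
        lens.current_power_D = lens._target
    else:
        step = lens.rate_limit_D_per_s * dt
        lens.current_power_D += max(-step, min(step, gap))
    lens.time_s += dt


def lens_step(lens: TunableLens, commanded_D: float, dt: float) -> TunableLens:
    """Advance the lens by ``dt`` seconds with ``commanded_D`` issued at step start.

    The command is clamped to the power range and becomes effective
    ``delay_s`` later; power then slews toward it at the rate limit.
    Integration is piecewise-exact across command-effective instants that
    fall inside the step, so trajectories shift by exactly the delay.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    clamped = float(np.clip(commanded_D, lens.power_min_D, lens.power_max_D))
    heapq.heappush(lens._pending, (lens.time_s + lens.delay_s, next(lens._seq), clamped))
    t_end = lens.time_s + dt
    while lens._pending and lens._pending[0][0] <= t_end:
        t_eff, _, target = heapq.heappop(lens._pending)
        _advance(lens, t_eff - lens.time_s)
        lens.time_s = max(lens.time_s, t_eff)
        lens._target = target
    _advance(lens, t_end - lens.time_s)
    lens.time_s = t_end
    return lens


@dataclass(frozen=True)
class ProgressiveLensMap:
    """Progressive-addition lens: distance zone up, near zone down, corridor between."""

    distance_power_D: float
    add_power_D: float
    corridor_elevation_far_deg: float = 5.0
    corridor_elevation_near_deg: float = -15.0

    def __post_init__(self) -> None:
        if self.corridor_elevation_far_deg <= self.corridor_elevation_near_deg:
            raise ValueError("the far corridor boundary must lie above the near boundary")


def progressive_power(lens_map: ProgressiveLensMap, gaze_elevation_deg: float) -> float:
    """Effective power at a gaze elevation: continuous, nonincreasing in elevation."""
    far = lens_map.corridor_elevation_far_deg
    near = lens_map.corridor_elevation_near_deg
    if gaze_elevation_deg >= far:
        return lens_map.distance_power_D
    if gaze_elevation_deg <= near:
        return lens_map.distance_power_D + lens_map.add_power_D
    frac = (far - gaze_elevation_deg) / (far - near)
    return lens_map.distance_power_D + lens_map.add_power_D * frac


def _gaze_pixel(gaze: GazeSample, scene: RGBDScene) -> Optional[Tuple[int, int]]:
    if not gaze.valid:
        return None
    x = int(round(gaze.gaze_x_px))
    y = int(round(gaze.gaze_y_px))
    height, width = scene.shape
    if not (0 <= x < width and 0 <= y < height):
        return None
    return x, y


class GazePointController:
    """Command the demand of the depth under the gaze point.

    Depth is robustified with a median over a 5x5 pixel window (clipped at
    image borders) and the raw command optionally smoothed with a moving
    average over ``smoothing_window`` samples.  Invalid or out-of-image
    gaze holds the previous command.
    """

    def __init__(self, smoothing_window: int = 1, initial_power_D: float = 0.0):
        if smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        self.smoothing_window = smoothing_window
        self.last_command_D = float(initial_power_D)
        self._history: List[float] = []

    def __call__(self, t: float, gaze: GazeSample, scene: RGBDScene) -> float:
        pixel = _gaze_pixel(gaze, scene)
        if pixel is None:
            return self.last_command_D
        x, y = pixel
        half = GAZE_MEDIAN_WINDOW // 2
        window = scene.depth[
            max(0, y - half) : y + half + 1, max(0, x - half) : x + half + 1
        ]
        raw = dioptric_demand(float(np.median(window)))
        self._history.append(raw)
        if len(self._history) > self.smoothing_window:
            self._history.pop(0)
        self.last_command_D = float(np.mean(self._history))
        return self.last_command_D


class DepthModeController:
    """Command the modal dioptric depth within a foveal radius of gaze.

    Pixel demands within ``foveal_radius_deg`` of the gaze direction are
    histogrammed in 0.25 D bins; the command is the median demand of the
    most populated bin, ties broken toward the nearer (higher-diopter) bin.
    """

    def __init__(self, foveal_radius_deg: float = 5.0, initial_power_D: float = 0.0):
        if foveal_radius_deg < 0:
            raise ValueError("foveal_radius_deg must be >= 0")
        self.foveal_radius_deg = foveal_radius_deg
        self.last_command_D = float(initial_power_D)
        self._grid_cache = None

    def _angles(self, scene: RGBDScene):
        key = (scene.camera.width, scene.camera.height, scene.camera.fov_deg)
        if self._grid_cache is None or self._grid_cache[0] != key:
            az, el = scene.camera.angle_grid()
            self._grid_cache = (key, az, el)
        return self._grid_cache[1], self._grid_cache[2]

    def __call__(self, t: float, gaze: GazeSample, scene: RGBDScene) -> float:
        pixel = _gaze_pixel(gaze, scene)
        if pixel is None:
            return self.last_command_D
        az_grid, el_grid = self._angles(scene)
        gaze_az, gaze_el = scene.camera.angles_from_pixel(gaze.gaze_x_px, gaze.gaze_y_px)
        dist = np.hypot(az_grid - gaze_az, el_grid - gaze_el)
        mask = dist <= self.foveal_radius_deg
        if not np.any(mask):
            return self.last_command_D
        demands = dioptric_demand(scene.depth[mask])
        bins = np.floor(demands / DEPTH_MODE_BIN_D).astype(int)
        values, counts = np.unique(bins, return_counts=True)
        best = counts.max()
        winner = values[counts == best].max()  # tie -> nearer (higher D) bin
        self.last_command_D = float(np.median(demands[bins == winner]))
        return self.last_command_D


class ManualController:
    """Piecewise-constant command from time-stamped user step inputs.

    ``events`` is a sequence of (time_s, power_D); events take effect at
    t >= event time (inclusive).  Unordered events raise ConfigurationError.
    """

    def __init__(self, events: Sequence[Tuple[float, float]], initial_power_D: float = 0.0):
        times = [t for t, _ in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigurationError("manual events must be time-ordered")
        self.events = list(events)
        self.initial_power_D = float(initial_power_D)
        self.last_command_D = self.initial_power_D

    def __call__(self, t: float, gaze: GazeSample = None, scene: RGBDScene = None) -> float:
        command = self.initial_power_D
        for event_time, power in self.events:
            if event_time <= t:
                command = power
            else:
                break
        self.last_command_D = float(command)
        return self.last_command_D


def run_closed_loop(
    scene: RGBDScene,
    trace: Sequence[GazeSample],
    controller,
    lens: TunableLens,
    eye: EyeModel,
    duration_s: float,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Simulate controller -> lens -> defocus-at-gaze over ``duration_s``.

    Per step the controller issues a power command from the current gaze
    sample, the lens integrates it, and the residual defocus at the gaze
    pixel is evaluated through the eye model.  Returns a DataFrame with
    columns (t, command_D, power_D, defocus_D) — the tuning-power log.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not trace:
        raise ValueError("gaze trace is empty")
    times = np.array([s.timestamp_s for s in trace])
    n_steps = int(round(duration_s / dt))
    rows = []
    last_pixel = None
    for k in range(1, n_steps + 1):
        t = k * dt
        idx = int(np.searchsorted(times, t, side="right")) - 1
        sample = trace[max(idx, 0)]
        command = controller(t, sample, scene) if controller is not None else lens._target
        lens_step(lens, command, dt)
        pixel = _gaze_pixel(sample, scene)
        if pixel is not None:
            last_pixel = pixel
        if last_pixel is None:
            defocus = math.nan
        else:
            x, y = last_pixel
            demand = dioptric_demand(float(scene.depth[y, x]))
            defocus = abs(demand - total_focus(demand, lens.current_power_D, eye))
        rows.append((t, command, lens.current_power_D, defocus))
    return pd.DataFrame(rows, columns=["t", "command_D", "power_D", "defocus_D"])
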