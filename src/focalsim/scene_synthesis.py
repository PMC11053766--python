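"""Synthetic RGB-D scenes and RGB-D file I/O.

The substrate of the whole simulator is an :class:`RGBDScene`: an RGB
raster in [0, 1], a co-registered depth map in meters along the viewing
axis, and a pinhole camera.  The office scene generator places flat,
fronto-parallel "screens" (smartphone / monitor / TV) at configurable
distances in an otherwise empty room; this emulates a typical office with
near, intermediate and far working distances without any photorealism.

Coordinate convention (used everywhere in the package): row 0 is the top
of the image, x grows rightward, y grows downward; azimuth is signed
rightward and elevation signed upward.  Pixels map to angles through the
pinhole model

    x_px = cx + f_px * tan(azimuth),   f_px = (W/2) / tan(FOV/2),

with the principal point at the raster center.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .errors import ConfigurationError

__all__ = [
    "PinholeCamera",
    "ScreenSpec",
    "RGBDScene",
    "DEFAULT_SCREENS",
    "DEFAULT_BACKGROUND_DEPTH_M",
    "make_office_scene",
    "make_plane_scene",
    "screen_rect_px",
    "write_rgbd",
    "read_rgbd",
]


@dataclass(frozen=True)
class PinholeCamera:
    """Pinhole camera with a horizontal field of view in degrees."""

    width: int
    height: int
    fov_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("camera resolution must be positive")
        if not 0 < self.fov_deg < 180:
            raise ValueError("fov_deg must lie in (0, 180)")

    @property
    def f_px(self) -> float:
        """Focal length in pixels: (W/2) / tan(FOV/2)."""
        return (self.width / 2.0) / math.tan(math.radians(self.fov_deg) / 2.0)

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def cy(self) -> float:
        return (self.height - 1) / 2.0

    def pixel_from_angles(self, azimuth_deg, elevation_deg):
        """(azimuth, elevation) in degrees -> (x, y) pixel coordinates."""
        az = np.radians(np.asarray(azimuth_deg, dtype=float))
        el = np.radians(np.asarray(elevation_deg, dtype=float))
        x = self.cx + self.f_px * np.tan(az)
        y = self.cy - self.f_px * np.tan(el)
        return x, y

    def angles_from_pixel(self, x_px, y_px):
        """(x, y) pixel coordinates -> (azimuth, elevation) in degrees."""
        x = np.asarray(x_px, dtype=float)
        y = np.asarray(y_px, dtype=float)
        az = np.degrees(np.arctan((x - self.cx) / self.f_px))
        el = np.degrees(np.arctan((self.cy - y) / self.f_px))
        return az, el

    def angle_grid(self):
        """Per-pixel (azimuth, elevation) grids in degrees, shape H x W."""
        xs = np.arange(self.width, dtype=float)
        ys = np.arange(self.height, dtype=float)
        az, _ = self.angles_from_pixel(xs, np.zeros_like(xs))
        _, el = self.angles_from_pixel(np.zeros_like(ys), ys)
        return np.broadcast_to(az, (self.height, self.width)).copy(), np.broadcast_to(
            el[:, None], (self.height, self.width)
        ).copy()


@dataclass(frozen=True)
class ScreenSpec:
    """A flat display at a fixed distance: position given in angles, size in meters."""

    distance_m: float
    azimuth_deg: float
    elevation_deg: float
    width_m: float
    height_m: float
    label: str

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValueError("screen distance must be positive")
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("screen size must be positive")

    @property
    def half_angle_h_deg(self) -> float:
        return math.degrees(math.atan(self.width_m / (2 * self.distance_m)))

    @property
    def half_angle_v_deg(self) -> float:
        return math.degrees(math.atan(self.height_m / (2 * self.distance_m)))


@dataclass
class RGBDScene:
    """RGB raster in [0,1] plus depth (m) and camera; optional screen layout."""

    rgb: np.ndarray
    depth: np.ndarray
    camera: PinholeCamera
    screens: Optional[Tuple[ScreenSpec, ...]] = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.depth.shape != self.rgb.shape[:2]:
            raise ValueError(
                f"rgb {self.rgb.shape[:2]} and depth {self.depth.shape} dimensions differ"
            )
        if (self.camera.height, self.camera.width) != self.depth.shape:
            raise ValueError("camera resolution does not match rasters")
        if not np.all(np.isfinite(self.depth)) or np.any(self.depth <= 0):
            raise ValueError("every depth value must be finite and > 0")
        if np.any(self.rgb < 0) or np.any(self.rgb > 1):
            raise ValueError("rgb values must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.depth.shape

    def copy(self) -> "RGBDScene":
        return RGBDScene(self.rgb.copy(), self.depth.copy(), self.camera, self.screens)


#: Three-screen office layout: smartphone at reading distance, computer
#: display at 1 m, TV at far distance.  Angular positions keep the three
#: projected rectangles disjoint inside a 90 deg field of view.
DEFAULT_SCREENS: Tuple[ScreenSpec, ...] = (
    ScreenSpec(0.30, -25.0, -10.0, 0.07, 0.12, "near"),
    ScreenSpec(1.00, 0.0, 0.0, 0.40, 0.25, "intermediate"),
    ScreenSpec(6.00, 25.0, 4.0, 1.40, 0.80, "far"),
)

DEFAULT_BACKGROUND_DEPTH_M = 6.5  # flat wall behind the far screen

_WALL_GRAY = 0.55
_SCREEN_FILL = 0.92
_BEZEL = 0.10


def screen_rect_px(camera: PinholeCamera, screen: ScreenSpec) -> Tuple[int, int, int, int]:
    """Projected screen rectangle as inclusive pixel bounds (x0, x1, y0, y1).

    The rectangle edges follow the pinhole model applied to the screen's
    angular extents: half-width angle atan(width / (2 * distance)).
    Raises ConfigurationError when the projection leaves the image.
    """
    x_lo, _ = camera.pixel_from_angles(screen.azimuth_deg - screen.half_angle_h_deg, 0.0)
    x_hi, _ = camera.pixel_from_angles(screen.azimuth_deg + screen.half_angle_h_deg, 0.0)
    _, y_lo = camera.pixel_from_angles(0.0, screen.elevation_deg + screen.half_angle_v_deg)
    _, y_hi = camera.pixel_from_angles(0.0, screen.elevation_deg - screen.half_angle_v_deg)
    x0, x1 = int(round(float(x_lo))), int(round(float(x_hi)))
    y0, y1 = int(round(float(y_lo))), int(round(float(y_hi)))
    if x0 < 0 or y0 < 0 or x1 >= camera.width or y1 >= camera.height:
        raise ConfigurationError(
            f"screen {screen.label!r} projects outside the {camera.width}x{camera.height} image"
        )
    return x0, x1, y0, y1


def make_office_scene(
    screens: Sequence[ScreenSpec] = DEFAULT_SCREENS,
    background_depth_m: float = DEFAULT_BACKGROUND_DEPTH_M,
    resolution: Tuple[int, int] = (320, 240),
    fov_deg: float = 90.0,
) -> RGBDScene:
    """Office scene: flat screens at their distances, a wall behind.

    The depth map equals each screen's distance inside its projected
    rectangle and ``background_depth_m`` elsewhere.  Screens whose
    projections overlap raise ConfigurationError.
    """
    if not screens:
        raise ConfigurationError("at least one screen is required")
    if background_depth_m <= 0:
        raise ConfigurationError("background depth must be positive")
    width, height = resolution
    camera = PinholeCamera(width=width, height=height, fov_deg=fov_deg)

    rects = [screen_rect_px(camera, s) for s in screens]
    for i in range(len(rects)):
        for j in range(i + 1, len(rects)):
            ax0, ax1, ay0, ay1 = rects[i]
            bx0, bx1, by0, by1 = rects[j]
            if ax0 <= bx1 and bx0 <= ax1 and ay0 <= by1 and by0 <= ay1:
                raise ConfigurationError(
                    f"screens {screens[i].label!r} and {screens[j].label!r} overlap in projection"
                )

    depth = np.full((height, width), float(background_depth_m))
    rgb = np.full((height, width, 3), _WALL_GRAY)
    for screen, (x0, x1, y0, y1) in zip(screens, rects):
        depth[y0 : y1 + 1, x0 : x1 + 1] = screen.distance_m
        rgb[y0 : y1 + 1, x0 : x1 + 1] = _BEZEL
        # bright panel inside a thin bezel
        b = max(1, (min(x1 - x0, y1 - y0) + 1) // 20)
        if x1 - x0 > 2 * b and y1 - y0 > 2 * b:
            rgb[y0 + b : y1 + 1 - b, x0 + b : x1 + 1 - b] = _SCREEN_FILL
    return RGBDScene(rgb=rgb, depth=depth, camera=camera, screens=tuple(screens))


_LETTER_E = np.array(
    [
        [1, 1, 1, 1, 1],
        [1, 0, 0, 0, 0],
        [1, 1, 1, 1, 0],
        [1, 0, 0, 0, 0],
        [1, 1, 1, 1, 1],
    ],
    dtype=bool,
)


def make_plane_scene(
    distance_m: float,
    pattern: str = "checker",
    resolution: Tuple[int, int] = (64, 64),
    fov_deg: float = 60.0,
    seed: Optional[int] = None,
) -> RGBDScene:
    """Fronto-parallel plane with a test pattern; constant depth map.

    Patterns: ``checker`` (8-px tiles), ``letter`` (a block letter filling
    the frame), ``noise`` (seeded uniform RGB noise).
    """
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    width, height = resolution
    camera = PinholeCamera(width=width, height=height, fov_deg=fov_deg)
    depth = np.full((height, width), float(distance_m))

    if pattern == "checker":
        tile = 8
        yy, xx = np.mgrid[0:height, 0:width]
        checks = ((yy // tile + xx // tile) % 2).astype(float)
        rgb = np.repeat((0.15 + 0.7 * checks)[:, :, None], 3, axis=2)
    elif pattern == "letter":
        rgb = np.full((height, width, 3), 0.9)
        glyph = np.kron(_LETTER_E, np.ones((height // 8, width // 8)))
        gh, gw = glyph.shape
        y0 = (height - gh) // 2
        x0 = (width - gw) // 2
        block = rgb[y0 : y0 + gh, x0 : x0 + gw]
        block[glyph > 0] = 0.05
    elif pattern == "noise":
        rng = np.random.default_rng(seed)
        rgb = rng.uniform(0.0, 1.0, size=(height, width, 3))
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return RGBDScene(rgb=rgb, depth=depth, camera=camera)


def write_rgbd(
    scene: RGBDScene,
    rgb_path,
    depth_path,
    meta_path=None,
) -> None:
    """Write RGB as 8-bit PNG and depth as a CSV of meters (one row per raster row).

    The depth CSV uses full-precision float formatting so the round trip is
    exact; the PNG round trip is exact to within 1/255 per channel.
    ``meta_path`` (JSON) records the field of view.
    """
    rgb8 = np.clip(np.round(scene.rgb * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(rgb8, mode="RGB").save(rgb_path)
    np.savetxt(depth_path, scene.depth, fmt="%.17g", delimiter=",")
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps({"fov_deg": scene.camera.fov_deg}))


def read_rgbd(rgb_path, depth_path, meta_path=None, fov_deg: Optional[float] = None) -> RGBDScene:
    """Read an RGB-D pair written by :func:`write_rgbd`.

    Raises ValueError on a dimension mismatch or nonpositive/nonfinite depth.
    """
    rgb = np.asarray(Image.open(rgb_path).convert("RGB"), dtype=float) / 255.0
    depth = np.atleast_2d(np.loadtxt(depth_path, delimiter=","))
    if meta_path is not None:
        fov_deg = float(json.loads(Path(meta_path).read_text())["fov_deg"])
    if fov_deg is None:
        fov_deg = 60.0
    if depth.shape != rgb.shape[:2]:
        raise ValueError(f"rgb {rgb.shape[:2]} and depth {depth.shape} dimensions differ")
    camera = PinholeCamera(width=rgb.shape[1], height=rgb.shape[0], fov_deg=fov_deg)
    return RGBDScene(rgb=rgb, depth=depth, camera=camera)
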