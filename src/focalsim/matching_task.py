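"""Dynamic three-distance Landolt/Sloan matching task.

One trial presents a Landolt ring (gap in one of eight compass
orientations) on one screen, a Sloan letter (one of eight) on a second,
and an eight-column lookup table pairing orientations with letters on the
third.  The subject answers whether the presented ring/letter pair occupies
a single table column ("match").  The screen carrying the table is drawn
uniformly at random each trial, forcing refocus sequences that differ from
trial to trial; stimuli sit at the screen center or a corner.

Because no human sits in the simulator, responses come from a synthetic
blur-dependent observer: each optotype is identified correctly with
probability

    p(r) = 1/8 + 7/8 * logistic(-slope * (ln r - ln threshold)),

where r is the ratio of blur-disk diameter to gap size — chance 1/8 among
eight alternatives at heavy blur, certainty at zero blur, halfway between
at r = threshold.  Table lookup is errorless once both optotypes are
identified, so the match answer (and its errors) follow entirely from
identification.  This observer is a synthetic stand-in used to exercise
the task; it is not a fitted psychometric model of human data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .eye_optics import EyeModel, coc_angular, dioptric_demand, total_focus
from .gaze_sim_io import simulate_gaze_trace, timestamped_path, write_gaze_file
from .lens_and_control import TunableLens, ideal_lens, run_closed_loop
from .scene_synthesis import RGBDScene, ScreenSpec, make_office_scene, screen_rect_px

__all__ = [
    "ORIENTATIONS",
    "SLOAN_LETTERS",
    "TaskConfig",
    "Trial",
    "ObserverModel",
    "TrialRecord",
    "BlockResult",
    "generate_trial",
    "place_stimuli",
    "observe_and_respond",
    "run_block",
]

#: The eight gap orientations of the Landolt ring, as compass directions.
ORIENTATIONS: Tuple[str, ...] = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

#: Eight-letter Sloan subset (standard 5x5 stroke-grid optotypes).
SLOAN_LETTERS: Tuple[str, ...] = ("C", "D", "H", "K", "N", "O", "R", "S")

_SCREEN_LABELS = ("near", "intermediate", "far")

ARCMIN_TO_RAD = math.pi / (180.0 * 60.0)

_COMPASS_UNIT = {
    "N": (0.0, -1.0),
    "NE": (math.sqrt(0.5), -math.sqrt(0.5)),
    "E": (1.0, 0.0),
    "SE": (math.sqrt(0.5), math.sqrt(0.5)),
    "S": (0.0, 1.0),
    "SW": (-math.sqrt(0.5), math.sqrt(0.5)),
    "W": (-1.0, 0.0),
    "NW": (-math.sqrt(0.5), -math.sqrt(0.5)),
}

# 5x5 stroke-grid glyphs (coarse Sloan-style bitmaps; the observer model
# never reads pixels, so these only need to look like their letters).
_GLYPHS: Dict[str, np.ndarray] = {
    letter: np.array([[c == "1" for c in row] for row in rows], dtype=bool)
    for letter, rows in {
        "C": ("11111", "10000", "10000", "10000", "11111"),
        "D": ("11110", "10001", "10001", "10001", "11110"),
        "H": ("10001", "10001", "11111", "10001", "10001"),
        "K": ("10010", "10100", "11000", "10100", "10011"),
        "N": ("10001", "11001", "10101", "10011", "10001"),
        "O": ("01110", "10001", "10001", "10001", "01110"),
        "R": ("11110", "10001", "11110", "10100", "10011"),
        "S": ("11111", "10000", "11111", "00001", "11111"),
    }.items()
}

_INK = 0.05


@dataclass(frozen=True)
class TaskConfig:
    """Tunable task parameters: stimulus size, match prior, placement jitter."""

    gap_arcmin: float = 10.0
    match_prior: float = 0.5
    corner_prob: float = 0.5
    jitter_sd_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.gap_arcmin <= 0:
            raise ValueError("gap_arcmin must be positive")
        if not 0 <= self.match_prior <= 1:
            raise ValueError("match_prior must lie in [0, 1]")


@dataclass(frozen=True)
class Trial:
    """One matching-task presentation (all randomization resolved)."""

    landolt_orientation: str
    sloan_letter: str
    landolt_screen: str
    sloan_screen: str
    table_screen: str
    table: Tuple[Tuple[str, str], ...]  # 8 columns of (orientation, letter)
    is_match: bool
    placements: Mapping[str, str]  # stimulus -> center|corner_tl|corner_tr|corner_bl|corner_br
    gap_arcmin: float = 10.0

    def __post_init__(self) -> None:
        if sorted((self.landolt_screen, self.sloan_screen, self.table_screen)) != sorted(
            _SCREEN_LABELS
        ):
            raise ValueError("screen assignments must be a permutation of near/intermediate/far")
        if len(self.table) != 8:
            raise ValueError("the table must have 8 columns")
        matches = [c for c in self.table if c == (self.landolt_orientation, self.sloan_letter)]
        if bool(matches) != self.is_match:
            raise ValueError("is_match inconsistent with the table contents")


@dataclass(frozen=True)
class ObserverModel:
    """Blur-dependent synthetic observer; chance level fixed at 1/8."""

    slope: float = 4.0
    threshold_ratio: float = 1.0  # blur/gap ratio at the halfway point
    base_rt_s: float = 0.8
    rt_per_refocus_s: float = 0.4
    rt_jitter_sigma: float = 0.15
    refocus_threshold_D: float = 1.0

    def p_identify(self, blur_to_gap_ratio: float) -> float:
        """Identification probability in [1/8, 1], decreasing in blur/gap."""
        if blur_to_gap_ratio < 0:
            raise ValueError("blur/gap ratio must be nonnegative")
        if blur_to_gap_ratio == 0:
            return 1.0
        x = self.slope * (math.log(blur_to_gap_ratio) - math.log(self.threshold_ratio))
        return 1.0 / 8.0 + (7.0 / 8.0) / (1.0 + math.exp(x))


@dataclass(frozen=True)
class TrialRecord:
    """Scored response of one trial."""

    trial_id: int
    onset_s: float
    response_s: float
    reaction_time_s: float
    given_answer: str  # "match" | "no-match"
    correct: bool
    defocus_D: Mapping[str, float]  # per screen label at fixation time


@dataclass
class BlockResult:
    """Aggregate of a block: accuracy, mean reaction time, per-trial records."""

    records: List[TrialRecord] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.mean([r.correct for r in self.records]))

    @property
    def mean_reaction_time_s(self) -> float:
        return float(np.mean([r.reaction_time_s for r in self.records]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [r.trial_id for r in self.records],
                "onset": [r.onset_s for r in self.records],
                "rt_s": [r.reaction_time_s for r in self.records],
                "answer": [r.given_answer for r in self.records],
                "correct": [r.correct for r in self.records],
                "defocus_near_D": [r.defocus_D.get("near", math.nan) for r in self.records],
                "defocus_mid_D": [r.defocus_D.get("intermediate", math.nan) for r in self.records],
                "defocus_far_D": [r.defocus_D.get("far", math.nan) for r in self.records],
            }
        )


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_trial(seed_or_rng, config: Optional[TaskConfig] = None) -> Trial:
    """Draw one trial: uniform table screen, uniform optotypes, balanced match prior.

    The table pairs an orientation permutation with a letter permutation,
    so every orientation appears in exactly one column; on match trials the
    presented pair is planted in its column, on no-match trials it is
    guaranteed absent.  Deterministic given the seed.
    """
    config = config or TaskConfig()
    rng = _as_rng(seed_or_rng)

    table_idx = int(rng.integers(3))
    table_screen = _SCREEN_LABELS[table_idx]
    others = [s for s in _SCREEN_LABELS if s != table_screen]
    if rng.random() < 0.5:
        others.reverse()
    landolt_screen, sloan_screen = others

    orientation = ORIENTATIONS[int(rng.integers(8))]
    letter = SLOAN_LETTERS[int(rng.integers(8))]
    is_match = bool(rng.random() < config.match_prior)

    oris = list(rng.permutation(np.array(ORIENTATIONS)))
    lets = list(rng.permutation(np.array(SLOAN_LETTERS)))
    col = oris.index(orientation)
    if is_match:
        swap = lets.index(letter)
        lets[col], lets[swap] = lets[swap], lets[col]
    elif lets[col] == letter:
        other = int(rng.integers(7))
        other = other if other < col else other + 1
        lets[col], lets[other] = lets[other], lets[col]

    corners = ("corner_tl", "corner_tr", "corner_bl", "corner_br")
    placements = {}
    for stim in ("landolt", "sloan", "table"):
        if rng.random() < config.corner_prob:
            placements[stim] = corners[int(rng.integers(4))]
        else:
            placements[stim] = "center"

    return Trial(
        landolt_orientation=orientation,
        sloan_letter=letter,
        landolt_screen=landolt_screen,
        sloan_screen=sloan_screen,
        table_screen=table_screen,
        table=tuple(zip(oris, lets)),
        is_match=is_match,
        placements=placements,
        gap_arcmin=config.gap_arcmin,
    )


def _draw_landolt(rgb: np.ndarray, cx: float, cy: float, gap_px: float, orientation: str) -> None:
    """Landolt ring: outer diameter 5 gaps, stroke 1 gap, gap slot cut at orientation."""
    r_out = 2.5 * gap_px
    r_in = 1.5 * gap_px
    half = int(math.ceil(r_out)) + 1
    y0 = max(0, int(cy) - half)
    y1 = min(rgb.shape[0], int(cy) + half + 1)
    x0 = max(0, int(cx) - half)
    x1 = min(rgb.shape[1], int(cx) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    rr = np.hypot(dx, dy)
    ux, uy = _COMPASS_UNIT[orientation]
    along = dx * ux + dy * uy
    across = np.abs(dx * (-uy) + dy * ux)
    ring = (rr >= r_in) & (rr <= r_out)
    gap = (along > 0) & (across <= gap_px / 2.0)
    rgb[y0:y1, x0:x1][ring & ~gap] = _INK


def _draw_sloan(rgb: np.ndarray, cx: float, cy: float, gap_px: float, letter: str) -> None:
    """Sloan letter: 5x5 stroke grid, each stroke one gap wide."""
    glyph = _GLYPHS[letter]
    size = 5.0 * gap_px
    top = cy - size / 2.0
    left = cx - size / 2.0
    y0 = max(0, int(math.floor(top)))
    x0 = max(0, int(math.floor(left)))
    y1 = min(rgb.shape[0], int(math.ceil(top + size)) + 1)
    x1 = min(rgb.shape[1], int(math.ceil(left + size)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    gy = np.floor((yy + 0.5 - top) / gap_px).astype(int)
    gx = np.floor((xx + 0.5 - left) / gap_px).astype(int)
    inside = (gy >= 0) & (gy < 5) & (gx >= 0) & (gx < 5)
    ink = np.zeros_like(inside)
    ink[inside] = glyph[gy[inside], gx[inside]]
    rgb[y0:y1, x0:x1][ink] = _INK


def _stimulus_extent_px(kind: str, gap_px: float) -> float:
    return 5.0 * gap_px if kind in ("landolt", "sloan") else 0.0


def _anchor(
    rect: Tuple[int, int, int, int],
    placement: str,
    extent_px: float,
    jitter_sd_frac: float,
    rng: Optional[np.random.Generator],
) -> Tuple[float, float]:
    x0, x1, y0, y1 = rect
    margin = extent_px / 2.0 + 1.0
    lo_x, hi_x = x0 + margin, x1 - margin
    lo_y, hi_y = y0 + margin, y1 - margin
    if lo_x > hi_x or lo_y > hi_y:
        raise ConfigurationError("stimulus exceeds screen bounds")
    if placement == "center":
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    else:
        cx = lo_x if placement.endswith(("tl", "bl")) else hi_x
        cy = lo_y if placement.endswith(("tl", "tr")) else hi_y
    if rng is not None and jitter_sd_frac > 0:
        cx += rng.normal(0.0, jitter_sd_frac * (x1 - x0 + 1))
        cy += rng.normal(0.0, jitter_sd_frac * (y1 - y0 + 1))
    return float(np.clip(cx, lo_x, hi_x)), float(np.clip(cy, lo_y, hi_y))


def place_stimuli(
    scene: RGBDScene,
    trial: Trial,
    jitter_sd_frac: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> RGBDScene:
    """Render the ring, letter and table onto their assigned screens.

    Physical sizes scale with screen distance so the *angular* gap size is
    ``trial.gap_arcmin`` on every screen.  Placement follows the trial's
    center/corner draws, with optional Gaussian jitter (a fraction of the
    screen extent, clipped so the stimulus stays inside its screen).
    Raises ConfigurationError when a stimulus cannot fit on its screen.
    """
    if scene.screens is None:
        raise ConfigurationError("scene carries no screen layout")
    by_label = {s.label: s for s in scene.screens}
    missing = {trial.landolt_screen, trial.sloan_screen, trial.table_screen} - set(by_label)
    if missing:
        raise ConfigurationError(f"scene lacks screens {sorted(missing)}")
    out = scene.copy()
    gap_px = trial.gap_arcmin * ARCMIN_TO_RAD * scene.camera.f_px

    for kind, screen_label in (
        ("landolt", trial.landolt_screen),
        ("sloan", trial.sloan_screen),
        ("table", trial.table_screen),
    ):
        rect = screen_rect_px(scene.camera, by_label[screen_label])
        if kind == "table":
            _draw_table(out.rgb, rect, trial.table, gap_px)
            continue
        extent = _stimulus_extent_px(kind, gap_px)
        cx, cy = _anchor(rect, trial.placements[kind], extent, jitter_sd_frac, rng)
        if kind == "landolt":
            _draw_landolt(out.rgb, cx, cy, gap_px, trial.landolt_orientation)
        else:
            _draw_sloan(out.rgb, cx, cy, gap_px, trial.sloan_letter)
    return out


def _draw_table(
    rgb: np.ndarray,
    rect: Tuple[int, int, int, int],
    table: Sequence[Tuple[str, str]],
    gap_px: float,
) -> None:
    """Eight columns, each a small ring above a letter, scaled to fit the screen."""
    x0, x1, y0, y1 = rect
    w = x1 - x0 + 1
    h = y1 - y0 + 1
    col_w = w / 8.0
    # shrink glyphs until a ring + letter stack fits a column
    g = min(gap_px, col_w / 6.0, h / 12.0)
    if g <= 0:
        raise ConfigurationError("table does not fit on its screen")
    for i, (orientation, letter) in enumerate(table):
        cx = x0 + (i + 0.5) * col_w
        _draw_landolt(rgb, cx, y0 + h * 0.3, g, orientation)
        _draw_sloan(rgb, cx, y0 + h * 0.7, g, letter)


def _identify(rng: np.random.Generator, truth: str, options: Sequence[str], p_correct: float) -> str:
    if rng.random() < p_correct:
        return truth
    others = [o for o in options if o != truth]
    return others[int(rng.integers(len(others)))]


_STANDARD_DISTANCES = {"near": 0.30, "intermediate": 1.0, "far": 6.0}


def _n_refocusses(trial: Trial, threshold_D: float, distances: Mapping[str, float]) -> int:
    path = [trial.landolt_screen, trial.sloan_screen, trial.table_screen]
    demands = [dioptric_demand(distances[s]) for s in path]
    return sum(1 for a, b in zip(demands, demands[1:]) if abs(b - a) > threshold_D)


def observe_and_respond(
    trial: Trial,
    observer: ObserverModel,
    blur_arcmin: Mapping[str, float],
    rng,
    trial_id: int = 0,
    onset_s: float = 0.0,
    defocus_D: Optional[Mapping[str, float]] = None,
    screen_distances: Mapping[str, float] = _STANDARD_DISTANCES,
) -> TrialRecord:
    """Score one trial through the blur-dependent observer.

    ``blur_arcmin`` gives the blur-disk diameter at the ``landolt`` and
    ``sloan`` stimuli (arcmin, same angular unit as the gap).  Each
    optotype is identified with the psychometric probability; the match
    answer follows from looking the identified pair up in the table
    (lookup itself is errorless).  Reaction time is base + an increment
    per focus shift exceeding the refocus threshold, with multiplicative
    lognormal jitter.
    """
    rng = _as_rng(rng)
    for key in ("landolt", "sloan"):
        if blur_arcmin.get(key, 0.0) < 0:
            raise ValueError("blur values must be nonnegative")

    p_ring = observer.p_identify(blur_arcmin.get("landolt", 0.0) / trial.gap_arcmin)
    p_letter = observer.p_identify(blur_arcmin.get("sloan", 0.0) / trial.gap_arcmin)
    seen_orientation = _identify(rng, trial.landolt_orientation, ORIENTATIONS, p_ring)
    seen_letter = _identify(rng, trial.sloan_letter, SLOAN_LETTERS, p_letter)

    column_letter = dict(trial.table)[seen_orientation]
    says_match = column_letter == seen_letter
    answer = "match" if says_match else "no-match"
    correct = says_match == trial.is_match

    shifts = _n_refocusses(trial, observer.refocus_threshold_D, screen_distances)
    rt = (observer.base_rt_s + observer.rt_per_refocus_s * shifts) * math.exp(
        rng.normal(0.0, observer.rt_jitter_sigma)
    )
    return TrialRecord(
        trial_id=trial_id,
        onset_s=onset_s,
        response_s=onset_s + rt,
        reaction_time_s=rt,
        given_answer=answer,
        correct=correct,
        defocus_D=dict(defocus_D or {}),
    )


def run_block(
    n_trials: int,
    eye: EyeModel,
    lens: Optional[TunableLens] = None,
    controller_factory=None,
    observer: Optional[ObserverModel] = None,
    scene: Optional[RGBDScene] = None,
    config: Optional[TaskConfig] = None,
    seed: int = 0,
    dwell_s: float = 0.6,
    dt: float = 0.01,
    gaze_noise_sd_deg: float = 0.0,
    out_dir=None,
) -> BlockResult:
    """Run a block of matching trials through the full simulation loop.

    Per trial: generate -> render stimuli -> simulate gaze visiting the
    ring, letter and table screens -> closed-loop lens control -> defocus
    (hence blur) at each stimulus at its fixation time -> synthetic
    observer response.  ``controller_factory`` builds a fresh controller
    per trial (None = the lens holds its power).  With ``out_dir`` set,
    task responses, the tuning-power log and a gaze file are written as
    timestamped CSVs.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    scene = scene if scene is not None else make_office_scene()
    if scene.screens is None:
        raise ConfigurationError("scene carries no screen layout")
    lens = lens if lens is not None else ideal_lens()
    observer = observer or ObserverModel()
    config = config or TaskConfig()
    by_label = {s.label: s for s in scene.screens}
    distances = {label: s.distance_m for label, s in by_label.items()}

    master = np.random.default_rng(seed)
    result = BlockResult()
    tuning_frames = []
    all_gaze = []
    onset = 0.0
    for trial_id in range(n_trials):
        rng = np.random.default_rng(master.integers(2**31))
        trial = generate_trial(rng, config)
        place_stimuli(scene, trial, jitter_sd_frac=config.jitter_sd_frac, rng=rng)

        path = [trial.landolt_screen, trial.sloan_screen, trial.table_screen]
        schedule = [
            ((by_label[s].azimuth_deg, by_label[s].elevation_deg), dwell_s) for s in path
        ]
        trace = simulate_gaze_trace(
            schedule,
            scene.camera,
            rate_hz=1.0 / dt,
            noise_sd_deg=gaze_noise_sd_deg,
            saccade_duration_s=0.0,
            seed=int(rng.integers(2**31)),
        )
        duration = len(path) * dwell_s
        series = run_closed_loop(
            scene,
            trace,
            controller_factory() if controller_factory is not None else None,
            lens.copy(),
            eye,
            duration_s=duration,
            dt=dt,
        )
        # power at the end of each screen's dwell -> defocus of that screen
        defocus: Dict[str, float] = {}
        for i, label in enumerate(path):
            t_fix = (i + 1) * dwell_s - dt
            power = float(series.loc[(series["t"] - t_fix).abs().idxmin(), "power_D"])
            demand = dioptric_demand(distances[label])
            defocus[label] = abs(demand - total_focus(demand, power, eye))
        blur = {
            "landolt": coc_angular(eye, defocus[trial.landolt_screen]) / ARCMIN_TO_RAD,
            "sloan": coc_angular(eye, defocus[trial.sloan_screen]) / ARCMIN_TO_RAD,
        }
        record = observe_and_respond(
            trial,
            observer,
            blur,
            rng,
            trial_id=trial_id,
            onset_s=onset,
            defocus_D=defocus,
            screen_distances=distances,
        )
        result.records.append(record)
        onset = record.response_s
        if out_dir is not None:
            series.insert(0, "trial_id", trial_id)
            tuning_frames.append(series)
            all_gaze.append(trace)

    if out_dir is not None:
        result.frame().to_csv(timestamped_path(out_dir, "task_responses", ".csv"), index=False)
        pd.concat(tuning_frames).to_csv(timestamped_path(out_dir, "tuning", ".csv"), index=False)
        flat = []
        offset = 0.0
        for trace in all_gaze:
            for s in trace:
                flat.append(
                    type(s)(
                        timestamp_s=s.timestamp_s + offset,
                        gaze_x_px=s.gaze_x_px,
                        gaze_y_px=s.gaze_y_px,
                        azimuth_deg=s.azimuth_deg,
                        elevation_deg=s.elevation_deg,
                        pupil_mm=s.pupil_mm,
                        valid=s.valid,
                        label=s.label,
                    )
                )
            offset = flat[-1].timestamp_s + 1e-3
        write_gaze_file(flat, out_dir)
    return result
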