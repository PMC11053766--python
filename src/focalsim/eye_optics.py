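"""First-order ophthalmic optics.

Dioptric demand, residual accommodation, defocus error and the angular
circle of confusion (CoC) for a simple schematic eye.  All optical powers
are in diopters (D = 1/m), distances in meters, and the pupil diameter in
millimeters (converted to meters internally, once, in :func:`coc_angular`).

The eye is reduced to three numbers:

* ``pupil_diameter_mm`` — sets the blur-disk size per diopter of defocus;
* ``accommodation_amplitude_D`` — the residual accommodation range.  Zero
  models an absolute presbyope; a young adult is ~10 D.
* ``distance_refraction_D`` — spherical refractive error at far (0 for an
  emmetrope, negative for a myope).

The angular CoC uses the thin-lens small-angle relation

    beta = p * |delta_D|

with ``p`` the pupil diameter in meters and ``delta_D`` the dioptric
defocus error, giving ``beta`` in radians.  The relation is exactly linear
in both arguments, which makes the blur pipeline analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

__all__ = [
    "EyeModel",
    "DefocusState",
    "dioptric_demand",
    "accommodation_response",
    "total_focus",
    "defocus_state",
    "coc_angular",
]

Number = Union[float, np.ndarray]

_MM_PER_M = 1000.0


@dataclass(frozen=True)
class EyeModel:
    """Schematic eye: pupil, residual accommodation, far refraction."""

    pupil_diameter_mm: float = 4.0
    accommodation_amplitude_D: float = 0.0
    distance_refraction_D: float = 0.0

    def __post_init__(self) -> None:
        if not self.pupil_diameter_mm > 0:
            raise ValueError(f"pupil_diameter_mm must be > 0, got {self.pupil_diameter_mm}")
        if self.accommodation_amplitude_D < 0:
            raise ValueError(
                f"accommodation_amplitude_D must be >= 0, got {self.accommodation_amplitude_D}"
            )

    @classmethod
    def from_config(cls, cfg: Mapping) -> "EyeModel":
        """Build from the global config keys (pupil_mm, accommodation_amplitude_D,
        distance_refraction_D); missing keys fall back to the defaults."""
        return cls(
            pupil_diameter_mm=float(cfg.get("pupil_mm", cls.pupil_diameter_mm)),
            accommodation_amplitude_D=float(
                cfg.get("accommodation_amplitude_D", cls.accommodation_amplitude_D)
            ),
            distance_refraction_D=float(
                cfg.get("distance_refraction_D", cls.distance_refraction_D)
            ),
        )


@dataclass(frozen=True)
class DefocusState:
    """Dioptric bookkeeping for one object: demand, focus brought to bear,
    and their absolute mismatch."""

    object_demand_D: float
    total_focus_D: float

    @property
    def defocus_error_D(self) -> float:
        return abs(self.object_demand_D - self.total_focus_D)


def dioptric_demand(distance_m: Number) -> Number:
    """Vergence demand 1/d (D) of an object at ``distance_m`` meters.

    Raises ValueError for nonpositive distances (scalar or any array entry).
    """
    arr = np.asarray(distance_m, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("distance must be positive and finite")
    demand = 1.0 / arr
    return float(demand) if np.isscalar(distance_m) or arr.ndim == 0 else demand


def accommodation_response(demand_D: Number, lens_aid_D: Number, eye: EyeModel) -> Number:
    """Accommodation the eye actually brings to bear, in D.

    The eye accommodates optimally within its residual range: the amount
    that would null the defocus, clamped to [0, amplitude].  No lag/lead
    modelling.
    """
    needed = np.asarray(demand_D, dtype=float) - np.asarray(lens_aid_D, dtype=float)
    needed = needed + eye.distance_refraction_D
    resp = np.clip(needed, 0.0, eye.accommodation_amplitude_D)
    return float(resp) if resp.ndim == 0 else resp


def total_focus(demand_D: Number, lens_aid_D: Number, eye: EyeModel) -> Number:
    """Lens power plus achieved accommodation minus the far refractive error."""
    acc = accommodation_response(demand_D, lens_aid_D, eye)
    out = np.asarray(lens_aid_D, dtype=float) + acc - eye.distance_refraction_D
    return float(out) if np.ndim(out) == 0 else out


def defocus_state(demand_D: float, lens_aid_D: float, eye: EyeModel) -> DefocusState:
    return DefocusState(
        object_demand_D=float(demand_D),
        total_focus_D=float(total_focus(demand_D, lens_aid_D, eye)),
    )


def coc_angular(eye: EyeModel, defocus_error_D: Number) -> Number:
    """Angular blur-disk diameter (radians): pupil [m] times defocus [D].

    Monotone nondecreasing and exactly linear in both arguments.
    Raises ValueError for a negative defocus error.
    """
    err = np.asarray(defocus_error_D, dtype=float)
    if np.any(err < 0):
        raise ValueError("defocus_error must be nonnegative")
    beta = (eye.pupil_diameter_mm / _MM_PER_M) * err
    return float(beta) if beta.ndim == 0 else beta
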