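"""Depth-wise reference profiles and the five regression targets.

Histology yields, per measurement location, a proteoglycan optical-density
profile (safranin-O digital densitometry) and a collagen orientation-angle
profile (polarized light microscopy), both expressed versus normalized depth
from the articular surface.  Profiles are resampled to 500 points; the
regression targets are cartilage thickness plus full-thickness and
superficial (first 25% of depth) means of each profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AlignmentError, NirscartError

N_PROFILE_POINTS = 500
SUPERFICIAL_FRACTION = 0.25

#: normalized depth grid: 500 equally spaced points, 0 = articular surface
DEPTH_GRID = np.linspace(0.0, 1.0, N_PROFILE_POINTS)


class OrderingError(NirscartError, ValueError):
    pass


class RangeError(NirscartError, ValueError):
    pass


@dataclass
class DepthProfile:
    """Values sampled on the 500-point normalized depth grid."""

    values: np.ndarray
    kind: str = ""  # "pg" (optical density) or "angle" (degrees)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_PROFILE_POINTS,):
            raise AlignmentError(
                f"profile must have {N_PROFILE_POINTS} points, got {v.shape}"
            )
        self.values = v

    @property
    def depth(self) -> np.ndarray:
        return DEPTH_GRID


@dataclass(frozen=True)
class ReferenceProperties:
    """The five regression targets for one measurement location."""

    thickness: float          # mm
    pg_full: float            # optical density, full thickness mean
    pg_sup: float             # optical density, superficial 25% mean
    angle_full: float         # degrees, full thickness mean
    angle_sup: float          # degrees, superficial 25% mean

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise RangeError("thickness must be positive")
        if self.pg_full < 0 or self.pg_sup < 0:
            raise RangeError("optical density must be non-negative")
        for a in (self.angle_full, self.angle_sup):
            if not 0.0 <= a <= 90.0:
                raise RangeError("orientation angle must lie in [0, 90] degrees")

    def as_dict(self) -> dict:
        return {
            "thickness": self.thickness,
            "pg_full": self.pg_full,
            "pg_sup": self.pg_sup,
            "angle_full": self.angle_full,
            "angle_sup": self.angle_sup,
        }


TARGET_NAMES = ("thickness", "pg_full", "pg_sup", "angle_full", "angle_sup")

TARGET_LABELS = {
    "thickness": "Cartilage thickness (mm)",
    "pg_full": "Full-thickness PG content (OD)",
    "pg_sup": "Superficial PG content (OD)",
    "angle_full": "Full-thickness collagen orientation angle (deg)",
    "angle_sup": "Superficial collagen orientation angle (deg)",
}


def resample_profile(raw_depths, raw_values, kind: str = "") -> DepthProfile:
    """Linearly interpolate a measured profile onto the 500-point grid.

    The input depth axis is rescaled so its span maps to [0, 1].
    """
    d = np.asarray(raw_depths, dtype=float)
    v = np.asarray(raw_values, dtype=float)
    if d.ndim != 1 or d.size < 2 or d.shape != v.shape:
        raise OrderingError("need >= 2 paired (depth, value) samples")
    if np.any(np.diff(d) <= 0):
        raise OrderingError("depths must be strictly increasing")
    x = (d - d[0]) / (d[-1] - d[0])
    return DepthProfile(np.interp(DEPTH_GRID, x, v), kind=kind)


def profile_mean(profile: DepthProfile, fraction: float = 1.0) -> float:
    """Mean of the profile over the first ``fraction`` of depth.

    Uses the first ``ceil(fraction * 500)`` grid points; ``fraction=1`` is the
    full-thickness mean, ``fraction=0.25`` the superficial mean.
    """
    if not 0.0 < fraction <= 1.0:
        raise RangeError("fraction must lie in (0, 1]")
    n = int(np.ceil(fraction * N_PROFILE_POINTS))
    return float(np.mean(profile.values[:n]))


def average_profiles(profiles: Sequence[DepthProfile]) -> DepthProfile:
    """Pointwise mean of profiles sharing the 500-point grid."""
    if not profiles:
        raise AlignmentError("cannot average an empty profile list")
    kinds = {p.kind for p in profiles}
    if len(kinds) > 1:
        raise AlignmentError(f"mixed profile kinds: {kinds}")
    stack = np.stack([p.values for p in profiles])
    return DepthProfile(stack.mean(axis=0), kind=profiles[0].kind)


def extract_references(
    pg_profile: DepthProfile, angle_profile: DepthProfile, thickness: float
) -> ReferenceProperties:
    """Assemble the five regression targets from the two profiles."""
    return ReferenceProperties(
        thickness=float(thickness),
        pg_full=profile_mean(pg_profile, 1.0),
        pg_sup=profile_mean(pg_profile, SUPERFICIAL_FRACTION),
        angle_full=profile_mean(angle_profile, 1.0),
        angle_sup=profile_mean(angle_profile, SUPERFICIAL_FRACTION),
    )
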