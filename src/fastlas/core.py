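"""Core data model: cine series, landmark sets, contour sequences, subject records.

Conventions used throughout the package:

* Image coordinates are ``(row, col)``, 0-based, fractional pixels.
* Physical distances are millimetres, obtained via the per-axis pixel spacing
  ``(row_mm_per_px, col_mm_per_px)`` — spacing may be anisotropic.
* Frame 0 is LV end-diastole; it is the strain reference and the first entry of
  ``frame_times`` is always 0 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from .errors import InvariantError

#: Landmark names per long-axis view.  ``posterior_mid`` is the intersection of
#: the LA long axis with the posterior atrial wall; the other two points are the
#: mitral-annulus (atrioventricular junction) insertion points of that view.
VIEW_POINTS: dict[str, tuple[str, str, str]] = {
    "two_chamber": ("av_anterior", "av_inferior", "posterior_mid"),
    "four_chamber": ("av_septal", "av_lateral", "posterior_mid"),
}

VIEWS = ("two_chamber", "four_chamber", "three_chamber")

#: The two distance lines of each view, named by the AV junction they end on.
VIEW_LINES: dict[str, tuple[str, str]] = {
    "two_chamber": ("anterior", "inferior"),
    "four_chamber": ("septal", "lateral"),
}

#: line name -> AV landmark name
LINE_TO_POINT: dict[str, str] = {
    "anterior": "av_anterior",
    "inferior": "av_inferior",
    "septal": "av_septal",
    "lateral": "av_lateral",
}

MIN_FRAMES = 8


@dataclass
class CineSeries:
    """One long-axis view's 2D+t intensity stack.

    Parameters
    ----------
    view : str
        One of ``two_chamber``, ``four_chamber``, ``three_chamber``.
    frames : ndarray, shape (T, rows, cols)
        Intensity frames ordered by trigger time.
    frame_times : ndarray, shape (T,)
        Milliseconds from cycle start; strictly increasing, first entry 0.
    pixel_spacing : (float, float)
        (row, col) millimetres per pixel.
    rr_interval : float
        Cardiac cycle length in ms.
    """

    view: str
    frames: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: tuple[float, float]
    rr_interval: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.view not in VIEWS:
            raise InvariantError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        if self.frames.ndim != 3:
            raise InvariantError("frames must be a (T, rows, cols) stack of 2D images")
        if self.n_frames < MIN_FRAMES:
            raise InvariantError(f"≥ {MIN_FRAMES} frames required, got {self.n_frames}")
        if self.frame_times.shape != (self.n_frames,):
            raise InvariantError("frame_times length must match frame count")
        if self.frame_times[0] != 0:
            raise InvariantError("first frame time must be 0 ms (LV end-diastole)")
        if np.any(np.diff(self.frame_times) <= 0):
            raise InvariantError("frame_times must be strictly increasing")
        sr, sc = self.pixel_spacing
        if not (sr > 0 and sc > 0):
            raise InvariantError("pixel spacing components must be > 0")
        if not self.rr_interval > 0:
            raise InvariantError("rr_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def reindexed(self, frame_index: int) -> "CineSeries":
        """Roll the series so ``frame_index`` becomes frame 0 (new strain reference)."""
        k = int(frame_index) % self.n_frames
        if k == 0:
            return self
        frames = np.roll(self.frames, -k, axis=0)
        dt = np.diff(np.append(self.frame_times, self.rr_interval))
        times = np.concatenate([[0.0], np.cumsum(np.roll(dt, -k))[:-1]])
        return replace(self, frames=frames, frame_times=times)


@dataclass
class LandmarkSet:
    """The three manually seeded anatomical points of one view at one frame."""

    view: str
    points: dict[str, tuple[float, float]]
    frame_index: int = 0

    def __post_init__(self):
        expected = VIEW_POINTS.get(self.view)
        if expected is None:
            raise InvariantError(f"landmarks only defined for views {list(VIEW_POINTS)}")
        unknown = set(self.points) - set(expected)
        if unknown:
            raise InvariantError(f"unknown point name(s) {sorted(unknown)} for view {self.view!r}")
        missing = set(expected) - set(self.points)
        if missing:
            raise InvariantError(f"missing point(s) {sorted(missing)} for view {self.view!r}")
        coords = [tuple(map(float, self.points[name])) for name in expected]
        self.points = dict(zip(expected, coords))
        for i, a in enumerate(coords):
            for b in coords[i + 1 :]:
                if a == b:
                    raise InvariantError("landmark points must be pairwise distinct")

    def validate_bounds(self, image_shape: tuple[int, int]) -> None:
        rows, cols = image_shape
        for name, (r, c) in self.points.items():
            if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
                raise InvariantError(
                    f"point {name!r} at ({r}, {c}) outside image bounds {image_shape}"
                )

    @property
    def names(self) -> tuple[str, str, str]:
        return VIEW_POINTS[self.view]


@dataclass
class ContourSequence:
    """Per-frame closed polygon tracing the LA endocardium in one view.

    Vertices are (row, col) pixel coordinates; the closing edge is implicit.
    """

    view: str
    polygons: list[np.ndarray]

    def __post_init__(self):
        if self.view not in VIEWS:
            raise InvariantError(f"unknown view {self.view!r}")
        polys = []
        for i, poly in enumerate(self.polygons):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise InvariantError(f"frame {i}: polygon needs ≥ 3 (row, col) vertices")
            if not Polygon(arr).is_valid:
                raise InvariantError(f"frame {i}: polygon is self-intersecting")
            polys.append(arr)
        self.polygons = polys

    @property
    def n_frames(self) -> int:
        return len(self.polygons)


@dataclass
class SubjectRecord:
    """One cohort row: identifiers, body habitus, covariates and outcome."""

    id: str
    bsa: float | None = None  # m^2
    la_diameter: float | None = None  # mm, externally measured
    lge_present: bool | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    follow_up: float = 0.0  # months
    event: bool = False

    def __post_init__(self):
        if self.bsa is not None and not self.bsa > 0:
            raise InvariantError("bsa must be > 0 when supplied")
        if self.follow_up < 0:
            raise InvariantError("follow_up must be ≥ 0")
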