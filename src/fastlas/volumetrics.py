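"""Biplane area-length LA volumetrics, emptying fractions and LGE extent.

The biplane area-length volume from paired 2- and 4-chamber endocardial
contours is

    V = (8 / (3 pi)) * A_2ch * A_4ch / L,

with A the contour areas (mm^2), L the LA long-axis length (mm, the shorter of
the two views) and V converted mm^3 -> ml.  Phasic volumes are read off the
volume-time curve — LAV_max (LV end-systole), LAV_p-ac (before atrial
contraction, same late-diastolic shoulder rule as the strain module) and
LAV_min (LV end-diastole) — and yield the total, passive and active emptying
fractions.  The LGE utility applies the mean + 6 SD remote-myocardium
threshold and reports enhanced myocardium as a percentage of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .core import ContourSequence
from .errors import InvariantError, StatsError
from .strain import LATE_DIASTOLE_FRACTION

BIPLANE_CONSTANT = 8.0 / (3.0 * np.pi)


@dataclass
class VolumeCurve:
    """LAV(t) with the three phasic volumes and optional BSA-indexed variants."""

    lav_ml: np.ndarray
    lav_max: float
    lav_max_frame: int
    lav_p_ac: float
    lav_p_ac_frame: int
    lav_min: float
    lav_min_frame: int
    lavi_max: float | None = None
    lavi_p_ac: float | None = None
    lavi_min: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.lav_ml = np.asarray(self.lav_ml, dtype=float)
        if np.any(self.lav_ml <= 0):
            raise InvariantError("all volumes must be > 0")
        if not self.lav_min <= self.lav_p_ac <= self.lav_max:
            raise InvariantError("require LAV_min ≤ LAV_p-ac ≤ LAV_max")


@dataclass
class LAEFSet:
    """Total, passive and active LA emptying fractions (%)."""

    total: float
    passive: float
    active: float

    def __post_init__(self):
        for v in (self.total, self.passive, self.active):
            if not 0 <= v < 100:
                raise InvariantError("emptying fractions must lie in [0, 100)")
        if self.total < self.passive - 1e-12:
            raise InvariantError("total LAEF must be ≥ passive LAEF")


@dataclass
class LGEResult:
    threshold: float
    extent_percent: float

    def __post_init__(self):
        if not 0 <= self.extent_percent <= 100:
            raise InvariantError("LGE extent must lie in [0, 100] %")


def biplane_volume(area_2ch: float, area_4ch: float, length: float) -> float:
    """Biplane area-length volume in ml from areas (mm^2) and length (mm)."""
    if area_2ch <= 0 or area_4ch <= 0 or length <= 0:
        raise InvariantError("areas and length must be > 0")
    return BIPLANE_CONSTANT * area_2ch * area_4ch / length / 1000.0


def _polygon_area_mm2(vertices_px: np.ndarray, spacing) -> float:
    mm = vertices_px * np.asarray(spacing)
    return Polygon(mm).area


def _long_axis_length_mm(vertices_px: np.ndarray, spacing) -> float:
    """LA long-axis length of one contour: the maximal vertex-to-vertex chord.

    For the near-elliptical LA cavity this equals the posterior-midpoint to
    annulus-midpoint axis; when tracked landmarks are available
    ``volume_curve`` uses them directly instead.
    """
    mm = vertices_px * np.asarray(spacing)
    hull = np.asarray(Polygon(mm).convex_hull.exterior.coords)
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _landmark_length_mm(positions: dict[str, np.ndarray], frame: int, spacing) -> float:
    names = [n for n in positions if n != "posterior_mid"]
    post = positions["posterior_mid"][frame] * np.asarray(spacing)
    mid = np.mean([positions[n][frame] * np.asarray(spacing) for n in names], axis=0)
    return float(np.hypot(*(mid - post)))


def _late_diastolic_shoulder(values: np.ndarray, peak: int) -> tuple[int, list[str]]:
    """Late-diastolic local maximum before the final decrease (frame-index
    window rule matching the strain module's pre-ac detection)."""
    T = values.size
    start = max(int(np.ceil((1 - LATE_DIASTOLE_FRACTION) * T)), peak + 1, 1)
    if start >= T:
        return peak, ["preac_window_empty"]
    candidates = [
        t for t in range(start, T - 1)
        if values[t] >= values[t - 1] and values[t] > values[t + 1]
    ]
    if candidates:
        return candidates[-1], []
    deriv = np.gradient(values)
    t = start + int(np.argmin(np.abs(deriv[start:T])))
    flags = ["no_plateau"] if t in (start, T - 1) else []
    return t, flags


def volume_curve(contours_2ch: ContourSequence, contours_4ch: ContourSequence,
                 spacing_2ch, spacing_4ch, bsa: float | None = None,
                 landmarks_2ch: dict[str, np.ndarray] | None = None,
                 landmarks_4ch: dict[str, np.ndarray] | None = None) -> VolumeCurve:
    """Per-frame biplane volumes and phasic extraction from paired contours.

    Per frame, each view contributes its polygon area (shoelace, mm^2) and LA
    long-axis length — posterior-wall midpoint to the AV-junction chord
    midpoint when tracked landmarks are supplied, else the contour's maximal
    chord; the biplane formula uses the shorter of the two view lengths.
    ``bsa`` (m^2) adds BSA-indexed phasic volumes.
    """
    if contours_2ch.n_frames != contours_4ch.n_frames:
        raise InvariantError(
            f"frame-count mismatch: {contours_2ch.n_frames} vs {contours_4ch.n_frames}")
    T = contours_2ch.n_frames
    lav = np.empty(T)
    for t in range(T):
        a2 = _polygon_area_mm2(contours_2ch.polygons[t], spacing_2ch)
        a4 = _polygon_area_mm2(contours_4ch.polygons[t], spacing_4ch)
        l2 = (_landmark_length_mm(landmarks_2ch, t, spacing_2ch) if landmarks_2ch
              else _long_axis_length_mm(contours_2ch.polygons[t], spacing_2ch))
        l4 = (_landmark_length_mm(landmarks_4ch, t, spacing_4ch) if landmarks_4ch
              else _long_axis_length_mm(contours_4ch.polygons[t], spacing_4ch))
        lav[t] = biplane_volume(a2, a4, min(l2, l4))

    i_max = int(np.argmax(lav))
    i_min = int(np.argmin(lav))
    i_pac, flags = _late_diastolic_shoulder(lav, i_max)

    kwargs = {}
    if bsa is not None:
        if bsa <= 0:
            raise InvariantError("BSA must be > 0 for indexing")
        kwargs = {"lavi_max": lav[i_max] / bsa, "lavi_p_ac": lav[i_pac] / bsa,
                  "lavi_min": lav[i_min] / bsa}
    return VolumeCurve(lav, float(lav[i_max]), i_max, float(lav[i_pac]), i_pac,
                       float(lav[i_min]), i_min, flags=flags, **kwargs)


def compute_laef(vc: VolumeCurve) -> LAEFSet:
    """Total/passive/active emptying fractions from the three phasic volumes.

    total   = (LAV_max − LAV_min) / LAV_max × 100
    passive = (LAV_max − LAV_p-ac) / LAV_max × 100
    active  = (LAV_p-ac − LAV_min) / LAV_p-ac × 100
    """
    if vc.lav_max <= 0 or vc.lav_p_ac <= 0:
        raise InvariantError("LAV_max and LAV_p-ac must be > 0")
    total = (vc.lav_max - vc.lav_min) / vc.lav_max * 100.0
    passive = (vc.lav_max - vc.lav_p_ac) / vc.lav_max * 100.0
    active = (vc.lav_p_ac - vc.lav_min) / vc.lav_p_ac * 100.0
    return LAEFSet(total, passive, active)


def lge_extent(lge_image: np.ndarray, myocardial_mask: np.ndarray,
               remote_roi: np.ndarray, n_sd: float = 6.0) -> LGEResult:
    """Enhanced-myocardium fraction by the mean + ``n_sd``·SD remote threshold.

    ``remote_roi`` must be a subset of ``myocardial_mask`` with ≥ 20 pixels of
    normal (remote) myocardium.
    """
    lge_image = np.asarray(lge_image, dtype=float)
    myo = np.asarray(myocardial_mask, dtype=bool)
    remote = np.asarray(remote_roi, dtype=bool)
    if np.any(remote & ~myo):
        raise InvariantError("remote ROI must be a subset of the myocardial mask")
    if remote.sum() < 20:
        raise InvariantError("remote ROI must contain ≥ 20 pixels")
    remote_vals = lge_image[remote]
    sd = remote_vals.std(ddof=1)
    if sd == 0:
        raise StatsError("zero-variance remote ROI: threshold undefined")
    threshold = float(remote_vals.mean() + n_sd * sd)
    extent = 100.0 * np.count_nonzero(lge_image[myo] > threshold) / myo.sum()
    return LGEResult(threshold, float(extent))
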