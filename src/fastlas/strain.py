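"""Distance curves, strain curves and reservoir/conduit/booster decomposition.

For each long-axis view, two lines are measured per frame: the Euclidean
distance (mm, anisotropic spacing applied per axis) from the posterior-wall
midpoint to each AV-junction point — anterior/inferior on the 2-chamber view,
septal/lateral on the 4-chamber view.  Strain per line is

    eps(t) = (D(t) - D0) * 100 / D0        [%],  D0 = frame-0 distance,

so eps(0) = 0 exactly.  Three phasic values are extracted from the view-mean
curve: reservoir strain eps_s (global maximum), booster/active strain eps_a
(value at the pre-atrial-contraction frame, the late-diastolic shoulder) and
conduit strain eps_e = eps_s - eps_a.  Final per-subject values average the
2- and 4-chamber views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LINE_TO_POINT, VIEW_LINES
from .errors import InvariantError
from .tracking import TrackedLandmarks

#: fraction of the cycle, counted from the end, searched for the
#: pre-atrial-contraction shoulder
LATE_DIASTOLE_FRACTION = 0.4


@dataclass
class DistanceCurves:
    """Per-line posterior-midpoint-to-AV-junction lengths (mm) per frame."""

    view: str
    lengths: dict[str, np.ndarray]  # line name -> (T,) mm
    frame_times: np.ndarray

    def __post_init__(self):
        for name, d in self.lengths.items():
            d = np.asarray(d, dtype=float)
            if np.any(d <= 0):
                raise InvariantError(f"line {name!r}: distances must be > 0")
            self.lengths[name] = d

    @property
    def d0(self) -> dict[str, float]:
        return {name: float(d[0]) for name, d in self.lengths.items()}


@dataclass
class StrainCurve:
    """Per-line strain eps(t) in %, plus the view-mean curve.

    ``strain`` holds the (optionally smoothed) curves used for phase
    detection; ``raw`` keeps the unsmoothed curves so phasic values can be
    read without the moving average's peak-flattening bias.  When smoothing
    is off the two coincide.
    """

    view: str
    strain: dict[str, np.ndarray]  # line name -> (T,) %
    frame_times: np.ndarray
    smoothed: bool = False
    raw: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for name, e in self.strain.items():
            e = np.asarray(e, dtype=float)
            if e[0] != 0:
                raise InvariantError(f"line {name!r}: eps(0) must be 0 exactly")
            self.strain[name] = e
        if self.raw is None:
            self.raw = self.strain

    @property
    def view_mean(self) -> np.ndarray:
        return np.mean(list(self.strain.values()), axis=0)

    @property
    def view_mean_raw(self) -> np.ndarray:
        return np.mean(list(self.raw.values()), axis=0)


@dataclass
class StrainResult:
    """Phasic strain per view and averaged across views.

    eps_s = eps_e + eps_a holds exactly by construction.  ``flags`` collects
    non-fatal conditions (non-physiological ordering, missing plateau,
    single-view input, ...).
    """

    per_view: dict[str, dict[str, float]]  # view -> {es, ee, ea}
    es: float
    ee: float
    ea: float
    peak_frame: dict[str, int] = field(default_factory=dict)
    preac_frame: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def compute_distances(tracked: TrackedLandmarks, pixel_spacing,
                      frame_times=None) -> DistanceCurves:
    """Per-frame line lengths in mm from tracked landmark positions."""
    if tracked.view not in VIEW_LINES:
        raise InvariantError(f"no distance lines defined for view {tracked.view!r}")
    sr, sc = pixel_spacing
    post = tracked.positions["posterior_mid"]
    T = post.shape[0]
    if frame_times is None:
        frame_times = np.arange(T, dtype=float)
    lengths = {}
    for line in VIEW_LINES[tracked.view]:
        av = tracked.positions[LINE_TO_POINT[line]]
        delta = (av - post) * np.array([sr, sc])
        d = np.hypot(delta[:, 0], delta[:, 1])
        bad = np.nonzero(d == 0)[0]
        if bad.size:
            raise InvariantError(
                f"line {line!r}: coincident landmarks at frame {int(bad[0])}"
            )
        lengths[line] = d
    return DistanceCurves(tracked.view, lengths, np.asarray(frame_times, dtype=float))


def _smooth_pinned(e: np.ndarray) -> np.ndarray:
    """3-point moving average with frame 0 pinned at 0 and edge frames averaged
    over their available neighbours."""
    out = e.copy()
    padded = np.concatenate([e[:1], e, e[-1:]])
    out[1:] = (padded[:-2] + padded[1:-1] + padded[2:])[1:] / 3.0
    out[0] = 0.0
    return out


def compute_strain_curve(distances: DistanceCurves, smooth: bool = True) -> StrainCurve:
    """eps(t) = (D(t) - D0) * 100 / D0 per line; optional 3-point smoothing."""
    strain, raw = {}, {}
    for name, d in distances.lengths.items():
        d0 = d[0]
        e = (d - d0) * 100.0 / d0
        e[0] = 0.0
        raw[name] = e
        strain[name] = _smooth_pinned(e) if smooth else e
    return StrainCurve(distances.view, strain, distances.frame_times,
                       smoothed=smooth, raw=raw)


def _find_preac_frame(curve: np.ndarray, times: np.ndarray, peak: int,
                      window_fraction: float = LATE_DIASTOLE_FRACTION):
    """Pre-atrial-contraction frame within the late-diastolic window.

    Primary rule: the LAST local maximum of the (smoothed) curve within the
    window — non-strict on the left so the final frame of a flat diastasis
    plateau qualifies.  Fallback when no such maximum exists (e.g. a straight
    decay with no plateau): the window frame minimizing \\|d eps/dt\\|, flagged.
    """
    T = curve.size
    cycle = times[-1] + (times[-1] - times[-2]) if T > 1 else 1.0
    start = int(np.searchsorted(times, (1 - window_fraction) * cycle))
    start = max(start, peak + 1, 1)
    if start >= T:
        return None, ["preac_window_empty"]
    candidates = [
        t for t in range(start, T - 1)
        if curve[t] >= curve[t - 1] and curve[t] > curve[t + 1]
    ]
    if candidates:
        return candidates[-1], []
    deriv = np.gradient(curve, times)
    t = start + int(np.argmin(np.abs(deriv[start:T])))
    flags = ["no_plateau"] if t in (start, T - 1) else []
    return t, flags


def decompose_phases(curve: StrainCurve) -> tuple[dict[str, float], int, int | None, list[str]]:
    """Phasic values (es, ee, ea) of one view from its view-mean strain curve.

    Returns ``(values, peak_frame, preac_frame, flags)``; ``ea``/``ee`` are NaN
    (with a flag) when the curve is monotone with no interior maximum.
    """
    mean = curve.view_mean
    raw = curve.view_mean_raw
    peak = int(np.argmax(mean))
    es = float(raw[peak])  # value off the unsmoothed curve: no peak flattening
    flags: list[str] = []
    if peak == mean.size - 1 or peak == 0:
        flags.append("monotone_curve_ea_undefined")
        return {"es": es, "ee": float("nan"), "ea": float("nan")}, peak, None, flags
    preac, f = _find_preac_frame(mean, curve.frame_times, peak)
    flags.extend(f)
    if preac is None:
        return {"es": es, "ee": float("nan"), "ea": float("nan")}, peak, None, flags
    ea = float(raw[preac])
    ee = es - ea
    if not (es >= ea >= 0):
        flags.append("non_physiological_ordering")
    return {"es": es, "ee": ee, "ea": ea}, peak, preac, flags


def aggregate_views(two_chamber: StrainCurve | None,
                    four_chamber: StrainCurve | None) -> StrainResult:
    """Average the per-view phasic strains into the final subject values.

    Per-view strain is the mean of that view's two line strains (decomposition
    is applied to the view-mean curve); the final value is the arithmetic mean
    of the two views for each of eps_s, eps_e, eps_a.
    """
    if two_chamber is None and four_chamber is None:
        raise InvariantError("at least one view is required")
    per_view: dict[str, dict[str, float]] = {}
    peak_frames: dict[str, int] = {}
    preac_frames: dict[str, int] = {}
    flags: list[str] = []
    for curve in (two_chamber, four_chamber):
        if curve is None:
            continue
        values, peak, preac, f = decompose_phases(curve)
        per_view[curve.view] = values
        peak_frames[curve.view] = peak
        if preac is not None:
            preac_frames[curve.view] = preac
        flags.extend(f"{curve.view}:{x}" for x in f)
    if len(per_view) == 1:
        flags.append("single_view")
    es = float(np.mean([v["es"] for v in per_view.values()]))
    ea = float(np.mean([v["ea"] for v in per_view.values()]))
    ee = es - ea
    return StrainResult(per_view, es, ee, ea, peak_frames, preac_frames, flags)


def analyze_views(tracked_2ch: TrackedLandmarks | None, spacing_2ch,
                  tracked_4ch: TrackedLandmarks | None, spacing_4ch,
                  frame_times_2ch=None, frame_times_4ch=None,
                  smooth: bool = True) -> StrainResult:
    """Convenience pipeline: tracked landmarks of both views -> StrainResult."""
    curves = []
    for tracked, spacing, times in ((tracked_2ch, spacing_2ch, frame_times_2ch),
                                    (tracked_4ch, spacing_4ch, frame_times_4ch)):
        if tracked is None:
            curves.append(None)
            continue
        dist = compute_distances(tracked, spacing, times)
        curves.append(compute_strain_curve(dist, smooth=smooth))
    return aggregate_views(*curves)
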