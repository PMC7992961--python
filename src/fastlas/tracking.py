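"""Semi-automated landmark tracking by normalized cross-correlation template matching.

The three seeded points of each view (the two AV-junction points and the
posterior-wall midpoint) are propagated independently across all cardiac
phases.  A square template extracted around the seed at frame 0 is matched,
frame by frame, against a search window centred on the point's position in the
previous frame; the integer-pixel NCC peak is refined to sub-pixel precision by
a parabolic fit of the 3x3 score neighbourhood.  Frames whose best score falls
below a threshold are flagged for manual adjustment, mirroring the
semi-automated workflow.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template as _skimage_match_template

from .core import CineSeries, LandmarkSet
from .errors import InvariantError, TrackingBoundsError, ZeroVarianceError


@dataclass
class TrackerConfig:
    """Tunable parameters of the landmark tracker.

    Defaults size the template to ~2 cm at 1.4 mm spacing (15x15 px) with a
    25x25 px search window; normalized cross-correlation is the similarity
    metric.
    """

    template_half_size: int = 7
    search_half_size: int = 12
    subpixel: bool = True
    template_policy: str = "fixed_reference"  # or "adaptive"
    min_score: float = 0.5
    retrack_after_adjustment: bool = True
    #: re-match each frame with the frame-0 template rescaled by that frame's
    #: estimated line-length scale; removes the inward NCC bias that a
    #: fixed-scale template suffers on dilating tissue
    scale_compensation: bool = True
    scale_compensation_passes: int = 2

    def __post_init__(self):
        if self.search_half_size < self.template_half_size:
            raise InvariantError("search window must be ≥ template half-size")
        if not (0 < self.min_score <= 1):
            raise InvariantError("min_score must lie in (0, 1]")
        if self.template_policy not in ("fixed_reference", "adaptive"):
            raise InvariantError("template_policy must be fixed_reference or adaptive")


@dataclass
class TrackedLandmarks:
    """Per-frame sub-pixel positions, match scores and adjustment flags."""

    view: str
    positions: dict[str, np.ndarray]  # name -> (T, 2) fractional (row, col)
    scores: dict[str, np.ndarray]  # name -> (T,) NCC peak score, frame 0 = 1
    adjusted: dict[str, np.ndarray]  # name -> (T,) bool, manual replacement
    low_score: dict[str, np.ndarray] = field(default_factory=dict)  # flagged frames

    def __post_init__(self):
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.ndim != 2 or pos.shape[1] != 2:
                raise InvariantError(f"positions for {name!r} must be (T, 2)")
            self.positions[name] = pos
            s = np.asarray(self.scores[name], dtype=float)
            if np.any(s < -1 - 1e-9) or np.any(s > 1 + 1e-9):
                raise InvariantError("match scores must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    def needs_adjustment(self, name: str) -> np.ndarray:
        return self.low_score.get(name, np.zeros(self.n_frames, bool))


def match_template(template: np.ndarray, window: np.ndarray):
    """NCC match of ``template`` inside the strictly larger ``window``.

    Returns
    -------
    displacement : (int, int)
        (row, col) shift of the best match relative to the centred alignment
        of template inside window.
    surface : ndarray
        Full NCC score surface (one score per valid integer placement).
    """
    template = np.asarray(template, dtype=float)
    window = np.asarray(window, dtype=float)
    if window.shape[0] <= template.shape[0] or window.shape[1] <= template.shape[1]:
        raise InvariantError("window must be strictly larger than template in both dimensions")
    if np.std(template) == 0:
        raise ZeroVarianceError("flat template patch: normalized correlation undefined")
    surface = _skimage_match_template(window, template, pad_input=False)
    peak = np.unravel_index(np.argmax(surface), surface.shape)
    center = ((window.shape[0] - template.shape[0]) // 2, (window.shape[1] - template.shape[1]) // 2)
    displacement = (int(peak[0] - center[0]), int(peak[1] - center[1]))
    return displacement, surface


# design matrix of the 2D quadratic z = a0 + ay*y + ax*x + ayy*y^2 + axx*x^2
# + axy*xy over the 3x3 peak neighbourhood, pre-factorised once
_QY, _QX = np.meshgrid([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], indexing="ij")
_QUAD_PINV = np.linalg.pinv(np.column_stack([
    np.ones(9), _QY.ravel(), _QX.ravel(), _QY.ravel() ** 2, _QX.ravel() ** 2,
    (_QY * _QX).ravel()]))


def refine_subpixel(surface: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Parabolic sub-pixel refinement of an integer score peak.

    Least-squares fit of a full 2D quadratic to the 3x3 score neighbourhood;
    the stationary point gives a fractional offset in (-1, 1) per axis.  A
    peak on the surface border cannot be refined and returns (0, 0) with a
    warning; so does a degenerate (non-concave) neighbourhood.
    """
    surface = np.asarray(surface, dtype=float)
    r, c = int(peak[0]), int(peak[1])
    if r <= 0 or c <= 0 or r >= surface.shape[0] - 1 or c >= surface.shape[1] - 1:
        warnings.warn("score peak on surface border; sub-pixel refinement skipped", stacklevel=2)
        return (0.0, 0.0)
    z = surface[r - 1:r + 2, c - 1:c + 2].ravel()
    _, ay, ax, ayy, axx, axy = _QUAD_PINV @ z
    hessian = np.array([[2 * ayy, axy], [axy, 2 * axx]])
    if np.linalg.det(hessian) <= 0 or ayy >= 0:  # saddle/flat/convex: skip
        return (0.0, 0.0)
    dr, dc = np.linalg.solve(hessian, [-ay, -ax])
    if max(abs(dr), abs(dc)) >= 1:
        return (0.0, 0.0)
    dr = 0.0 if abs(dr) < 1e-12 else float(dr)  # snap numerical dust
    dc = 0.0 if abs(dc) < 1e-12 else float(dc)
    return (dr, dc)


def _sample_scaled_template(frame: np.ndarray, center: tuple[float, float],
                            half: int, scale: float) -> np.ndarray:
    """Frame-0 patch around ``center`` magnified by ``scale``.

    Samples the reference frame at ``center + u / scale`` over the template
    grid, i.e. the patch as it would appear after the tissue dilated by
    ``scale`` about the landmark.
    """
    from scipy.ndimage import map_coordinates

    u = np.arange(-half, half + 1, dtype=float) / scale
    rr = center[0] + u[:, None] + np.zeros((1, u.size))
    cc = center[1] + np.zeros((u.size, 1)) + u[None, :]
    return map_coordinates(frame, [rr, cc], order=3, mode="nearest")


def _extract_patch(frame: np.ndarray, center: tuple[int, int], half: int,
                   frame_idx: int, point: str) -> np.ndarray:
    r, c = center
    if (r - half < 0 or c - half < 0 or r + half >= frame.shape[0]
            or c + half >= frame.shape[1]):
        raise TrackingBoundsError(frame_idx, point)
    return frame[r - half: r + half + 1, c - half: c + half + 1]


def track_landmarks(series: CineSeries, seeds: LandmarkSet,
                    config: TrackerConfig | None = None) -> TrackedLandmarks:
    """Propagate the three seeded points across every frame of the series.

    The seeds must sit on frame 0 (LV end-diastole).  With the default
    ``fixed_reference`` policy the frame-0 template of each point is matched
    against each subsequent frame's search window, centred on the point's
    previous-frame position (motion prior); ``adaptive`` re-extracts the
    template from the last tracked frame.
    """
    config = config or TrackerConfig()
    if seeds.view != series.view:
        raise InvariantError(f"seed view {seeds.view!r} does not match series {series.view!r}")
    if seeds.frame_index != 0:
        raise InvariantError(
            "seeds must be placed on frame 0 (LV end-diastole); "
            "re-index the series with CineSeries.reindexed first"
        )
    seeds.validate_bounds(series.shape)

    T = series.n_frames
    th, sh = config.template_half_size, config.search_half_size
    positions: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    low: dict[str, np.ndarray] = {}

    for name, seed in seeds.points.items():
        pos = np.zeros((T, 2))
        sc = np.ones(T)
        pos[0] = seed
        seed_int = (int(round(seed[0])), int(round(seed[1])))
        frac = (seed[0] - seed_int[0], seed[1] - seed_int[1])  # sub-pixel seed residual
        template = _extract_patch(series.frames[0], seed_int, th, 0, name)
        anchor = seed_int  # integer track of the template centre
        for t in range(1, T):
            if config.template_policy == "adaptive" and t > 1:
                template = _extract_patch(series.frames[t - 1], anchor, th, t - 1, name)
            window = _extract_patch(series.frames[t], anchor, sh, t, name)
            disp, surface = match_template(template, window)
            peak = (disp[0] + (surface.shape[0] - 1) // 2, disp[1] + (surface.shape[1] - 1) // 2)
            off = refine_subpixel(surface, peak) if config.subpixel else (0.0, 0.0)
            anchor = (anchor[0] + disp[0], anchor[1] + disp[1])
            pos[t] = (anchor[0] + off[0] + frac[0], anchor[1] + off[1] + frac[1])
            sc[t] = float(surface[peak])
        positions[name] = pos
        scores[name] = sc
        low[name] = sc < config.min_score

    if config.scale_compensation and config.template_policy == "fixed_reference":
        _scale_compensation_pass(series, seeds, config, positions, scores)
        for name in seeds.points:
            low[name] = scores[name] < config.min_score

    adjusted = {name: np.zeros(T, bool) for name in seeds.points}
    return TrackedLandmarks(series.view, positions, scores, adjusted, low)


def _scale_compensation_pass(series: CineSeries, seeds: LandmarkSet,
                             config: TrackerConfig,
                             positions: dict[str, np.ndarray],
                             scores: dict[str, np.ndarray]) -> None:
    """Re-match every frame with the frame-0 template magnified by the
    frame's line-length scale estimated from the current positions."""
    T = series.n_frames
    th, sh = config.template_half_size, config.search_half_size
    spacing = np.asarray(series.pixel_spacing)
    post = "posterior_mid"
    av_names = [n for n in seeds.points if n != post]
    if post not in seeds.points or not av_names:
        return
    for _ in range(config.scale_compensation_passes):
        scales = np.ones(T)
        for t in range(1, T):
            ratios = []
            for n in av_names:
                d0 = np.linalg.norm((positions[n][0] - positions[post][0]) * spacing)
                dt = np.linalg.norm((positions[n][t] - positions[post][t]) * spacing)
                if d0 > 0:
                    ratios.append(dt / d0)
            if ratios:
                scales[t] = float(np.mean(ratios))
        for name, seed in seeds.points.items():
            pos, sc = positions[name], scores[name]
            for t in range(1, T):
                s = float(np.clip(scales[t], 0.3, 3.0))
                if abs(s - 1.0) < 5e-3:
                    continue  # no measurable dilation: first pass is already exact
                template = _sample_scaled_template(series.frames[0], seed, th, s)
                anchor = (int(round(pos[t, 0])), int(round(pos[t, 1])))
                window = _extract_patch(series.frames[t], anchor, sh, t, name)
                disp, surface = match_template(template, window)
                peak = (disp[0] + (surface.shape[0] - 1) // 2,
                        disp[1] + (surface.shape[1] - 1) // 2)
                off = refine_subpixel(surface, peak) if config.subpixel else (0.0, 0.0)
                pos[t] = (anchor[0] + disp[0] + off[0], anchor[1] + disp[1] + off[1])
                sc[t] = float(surface[peak])


def apply_manual_adjustment(tracked: TrackedLandmarks, frame: int, point: str,
                            new_position: tuple[float, float],
                            series: CineSeries | None = None,
                            config: TrackerConfig | None = None) -> TrackedLandmarks:
    """Replace one automatic position with a manual one, flagging the frame.

    When ``series`` is supplied and ``config.retrack_after_adjustment`` is on,
    frames after the corrected one are re-tracked from the new position using
    the frame-0 template (positions before ``frame`` are untouched).
    """
    if point not in tracked.positions:
        raise InvariantError(f"unknown point {point!r}")
    T = tracked.n_frames
    if not 0 <= frame < T:
        raise InvariantError(f"frame {frame} out of range [0, {T})")
    out = copy.deepcopy(tracked)
    if series is not None:
        rows, cols = series.shape
        r, c = new_position
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise InvariantError(f"adjusted position ({r}, {c}) outside image bounds")
    out.positions[point][frame] = new_position
    out.adjusted[point][frame] = True
    out.low_score[point][frame] = False

    config = config or TrackerConfig()
    if series is not None and config.retrack_after_adjustment and frame < T - 1:
        th, sh = config.template_half_size, config.search_half_size
        seed0 = tracked.positions[point][0]
        seed_int = (int(round(seed0[0])), int(round(seed0[1])))
        frac = (seed0[0] - seed_int[0], seed0[1] - seed_int[1])
        template = _extract_patch(series.frames[0], seed_int, th, 0, point)
        anchor = (int(round(new_position[0] - frac[0])), int(round(new_position[1] - frac[1])))
        for t in range(frame + 1, T):
            window = _extract_patch(series.frames[t], anchor, sh, t, point)
            disp, surface = match_template(template, window)
            peak = (disp[0] + (surface.shape[0] - 1) // 2, disp[1] + (surface.shape[1] - 1) // 2)
            off = refine_subpixel(surface, peak) if config.subpixel else (0.0, 0.0)
            anchor = (anchor[0] + disp[0], anchor[1] + disp[1])
            out.positions[point][t] = (anchor[0] + off[0] + frac[0], anchor[1] + off[1] + frac[1])
            out.scores[point][t] = float(surface[peak])
            out.low_score[point][t] = out.scores[point][t] < config.min_score
            out.adjusted[point][t] = False
    return out
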