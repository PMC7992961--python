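"""Synthetic deforming-atrium phantoms and survival-cohort simulation.

The imaging phantom renders 2- and 4-chamber cine stacks of an idealised left
atrium: a bright elliptical blood pool with a dark wall, overlaid with
band-limited Gaussian speckle, deformed by an analytic similarity scaling
about the posterior-wall midpoint.  Because every material point at distance d
from that midpoint moves to ``d * s(t)``, each posterior-midpoint-to-AV
distance line obeys ``D(t) = D0 * (1 + eps(t)/100)`` exactly, with the global
strain-time curve ``eps(t)`` prescribed as a C^1 piecewise half-cosine:
rise 0 -> eps_s at the reservoir peak, decay to the diastasis plateau eps_a,
plateau, then smooth return to 0 at end-cycle (atrial contraction).  The
cavity volume follows ``V(t) = V0 * s(t)^3`` analytically, giving exact
ground truth for strain, landmark trajectories, distance lines, contours and
biplane volumes.

The cohort simulator draws phasic strain values and covariates and generates
event times from a proportional-hazards model with prescribed per-unit
log-hazard coefficients, for validating the survival-statistics layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import CineSeries, ContourSequence, LandmarkSet, VIEW_POINTS
from .errors import GeometryError, InvariantError

# intensity model (arbitrary units, ~[0, 100] dynamic range)
_BACKGROUND = 35.0
_BLOOD_POOL = 90.0
_WALL = 12.0
_SPECKLE_SD = 9.0
_SPECKLE_CORR_PX = 1.6


@dataclass
class PhantomSpec:
    """Geometry, deformation and texture of one synthetic-atrium exam.

    Strain magnitudes default to the HCM cohort scale (eps_s 20.4 %, eps_a
    11.0 %); geometry and sampling mirror a routine bSSFP long-axis
    acquisition (1.4 x 1.3 mm spacing, 25 phases).
    """

    image_size: tuple[int, int] = (112, 112)
    pixel_spacing: tuple[float, float] = (1.4, 1.3)
    n_frames: int = 25
    rr_interval: float = 850.0  # ms
    la_length: float = 52.0  # mm, posterior wall to annulus plane
    la_width: float = 40.0  # mm, 2-chamber cavity width
    la_width_4ch: float | None = None  # mm; defaults to la_width
    av_separation: float = 30.0  # mm between the two AV-junction points
    es: float = 20.4  # target reservoir strain, %
    ea: float = 11.0  # target booster strain (diastasis plateau), %
    time_of_peak: float = 0.4  # reservoir peak, fraction of cycle
    diastasis: tuple[float, float] = (0.70, 0.85)  # plateau window, cycle fraction
    per_view_offsets: tuple[float, float] = (0.0, 0.0)  # added to eps_s per view
    texture_seed: int = 0
    noise_sigma: float = 2.0  # per-frame acquisition noise, intensity units
    margin_px: int = 20  # clearance kept around landmarks at peak strain

    def __post_init__(self):
        if not 0 <= self.ea <= self.es:
            raise InvariantError("require 0 ≤ eps_a ≤ eps_s")
        if not 0 < self.time_of_peak < 1:
            raise InvariantError("time_of_peak must lie in (0, 1)")
        td, tc = self.diastasis
        if not self.time_of_peak < td < tc < 1:
            raise InvariantError("diastasis window must satisfy peak < start < end < 1")
        if self.n_frames < 8:
            raise InvariantError("n_frames must be ≥ 8")

    @property
    def widths(self) -> tuple[float, float]:
        return self.la_width, self.la_width_4ch if self.la_width_4ch else self.la_width


@dataclass
class PhantomTruth:
    """Exact per-frame ground truth of one phantom exam."""

    landmarks: dict[str, dict[str, np.ndarray]]  # view -> name -> (T, 2) px
    distances: dict[str, dict[str, np.ndarray]]  # view -> line -> (T,) mm
    strain: dict[str, np.ndarray]  # view -> (T,) %
    es: float
    ee: float
    ea: float
    per_view: dict[str, dict[str, float]]
    lav_ml: np.ndarray  # (T,) biplane/ellipsoid cavity volume
    peak_frame: int
    preac_frame: int
    frame_times: np.ndarray
    contours: dict[str, ContourSequence] = field(default_factory=dict)

    def seed_landmarks(self, view: str) -> LandmarkSet:
        pts = {name: tuple(self.landmarks[view][name][0]) for name in VIEW_POINTS[view]}
        return LandmarkSet(view, pts, frame_index=0)


def strain_time_curve(t: np.ndarray, es: float, ea: float, time_of_peak: float,
                      diastasis: tuple[float, float]) -> np.ndarray:
    """C^1 piecewise half-cosine strain profile on cycle fractions ``t``.

    Segments: rise 0 -> es on [0, tp]; decay es -> ea on [tp, td]; plateau ea
    on [td, tc]; return ea -> 0 on [tc, 1].  All segment derivatives vanish at
    the junctions, so the curve is continuously differentiable.
    """
    t = np.asarray(t, dtype=float)
    tp, (td, tc) = time_of_peak, diastasis
    out = np.empty_like(t)
    rise = t <= tp
    out[rise] = es * (1 - np.cos(np.pi * t[rise] / tp)) / 2
    decay = (t > tp) & (t <= td)
    out[decay] = ea + (es - ea) * (1 + np.cos(np.pi * (t[decay] - tp) / (td - tp))) / 2
    plateau = (t > td) & (t <= tc)
    out[plateau] = ea
    fall = t > tc
    out[fall] = ea * (1 + np.cos(np.pi * (t[fall] - tc) / (1 - tc))) / 2
    return out


def _render_reference(spec: PhantomSpec, width_mm: float, rng: np.random.Generator):
    """Frame-0 image (cavity + wall + speckle) and the key points, in px."""
    rows, cols = spec.image_size
    sr, sc = spec.pixel_spacing
    r_mm = np.arange(rows)[:, None] * sr
    c_mm = np.arange(cols)[None, :] * sc
    center = (rows * sr / 2.0, cols * sc / 2.0)
    a, b = spec.la_length / 2.0, width_mm / 2.0

    q = ((r_mm - center[0]) / a) ** 2 + ((c_mm - center[1]) / b) ** 2
    base = np.full((rows, cols), _BACKGROUND)
    base[q < 1.45] = _WALL  # 3-4 mm dark wall band around the cavity
    base[q < 1.0] = _BLOOD_POOL
    base = gaussian_filter(base, 1.0)

    speckle = gaussian_filter(rng.standard_normal((rows, cols)), _SPECKLE_CORR_PX)
    speckle *= _SPECKLE_SD / speckle.std()
    image = base + speckle

    # landmarks in mm then px: posterior midpoint at the bottom pole, AV
    # junctions flanking the annulus near the top pole
    p_mm = (center[0] + a, center[1])
    row_av = center[0] - 0.92 * a
    half_sep = spec.av_separation / 2.0
    av_left_mm = (row_av, center[1] - half_sep)
    av_right_mm = (row_av, center[1] + half_sep)

    def to_px(pt):
        return np.array([pt[0] / sr, pt[1] / sc])

    return image, to_px(p_mm), to_px(av_left_mm), to_px(av_right_mm), center, (a, b)


def _warp_about(image: np.ndarray, pivot_px: np.ndarray, scale: float) -> np.ndarray:
    """Similarity scaling of the image about ``pivot_px`` by ``scale``.

    Per-axis pixel scaling by the same scalar equals an isotropic scaling in
    mm space regardless of spacing anisotropy, so mm distances from the pivot
    scale exactly by ``scale``.
    """
    if scale == 1.0:
        return image.copy()
    rows, cols = image.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    src_r = pivot_px[0] + (rr - pivot_px[0]) / scale
    src_c = pivot_px[1] + (cc - pivot_px[1]) / scale
    return map_coordinates(image, [src_r, src_c], order=3, mode="nearest")


def _ellipse_polygon(center_mm, a, b, spacing, n_vertices=64) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = center_mm[0] + a * np.cos(th)
    c = center_mm[1] + b * np.sin(th)
    return np.column_stack([r / spacing[0], c / spacing[1]])


def make_la_phantom(spec: PhantomSpec, n_contour_vertices: int = 64
                    ) -> tuple[CineSeries, CineSeries, PhantomTruth]:
    """Render the 2- and 4-chamber cine stacks and their exact ground truth."""
    rng_texture = np.random.default_rng(spec.texture_seed)
    rng_noise = np.random.default_rng(spec.texture_seed + 1)
    t_frac = np.arange(spec.n_frames) / spec.n_frames
    times = t_frac * spec.rr_interval
    w2, w4 = spec.widths
    views = ("two_chamber", "four_chamber")

    series = {}
    truth_landmarks: dict[str, dict[str, np.ndarray]] = {}
    truth_dist: dict[str, dict[str, np.ndarray]] = {}
    truth_strain: dict[str, np.ndarray] = {}
    per_view_vals: dict[str, dict[str, float]] = {}
    contours: dict[str, ContourSequence] = {}
    view_scales = {}

    for view, width, off in zip(views, (w2, w4), spec.per_view_offsets):
        es_v = spec.es + off
        factor = es_v / spec.es if spec.es > 0 else 1.0
        ea_v = spec.ea * factor
        eps = strain_time_curve(t_frac, es_v, ea_v, spec.time_of_peak, spec.diastasis) \
            if es_v > 0 else np.zeros(spec.n_frames)
        s = 1 + eps / 100.0
        view_scales[view] = s

        image0, p_px, av_l, av_r, center_mm, (a, b) = _render_reference(
            spec, width, rng_texture)

        # bounds check at peak strain: landmarks plus tracking clearance
        s_max = float(s.max())
        rows, cols = spec.image_size
        for pt in (av_l, av_r):
            peak_pt = p_px + (pt - p_px) * s_max
            if (peak_pt[0] < spec.margin_px or peak_pt[1] < spec.margin_px
                    or peak_pt[0] > rows - 1 - spec.margin_px
                    or peak_pt[1] > cols - 1 - spec.margin_px):
                raise GeometryError(
                    f"{view}: AV junction leaves the usable image at peak strain "
                    f"(scale {s_max:.2f}); enlarge the image or reduce eps_s"
                )

        frames = np.stack([_warp_about(image0, p_px, float(sk)) for sk in s])
        if spec.noise_sigma > 0:
            frames = frames + rng_noise.normal(0, spec.noise_sigma, frames.shape)
        series[view] = CineSeries(view, frames, times, spec.pixel_spacing,
                                  spec.rr_interval)

        names = VIEW_POINTS[view]  # (av_x, av_y, posterior_mid)
        lm = {
            names[0]: p_px + (av_l - p_px) * s[:, None],
            names[1]: p_px + (av_r - p_px) * s[:, None],
            names[2]: np.tile(p_px, (spec.n_frames, 1)),
        }
        truth_landmarks[view] = lm

        sr, sc = spec.pixel_spacing
        d0 = {}
        for line_name, av0 in zip(("anterior", "inferior") if view == "two_chamber"
                                  else ("septal", "lateral"), (av_l, av_r)):
            delta_mm = (av0 - p_px) * np.array([sr, sc])
            d0[line_name] = math.hypot(*delta_mm)
        truth_dist[view] = {k: v * s for k, v in d0.items()}
        truth_strain[view] = eps
        per_view_vals[view] = {"es": es_v, "ee": es_v - ea_v, "ea": ea_v}

        p_mm = np.array([center_mm[0] + a, center_mm[1]])
        polys = []
        for sk in s:
            ctr = p_mm + (np.array(center_mm) - p_mm) * sk
            polys.append(_ellipse_polygon(ctr, a * sk, b * sk, spec.pixel_spacing,
                                          n_contour_vertices))
        contours[view] = ContourSequence(view, polys)

    # exact biplane (ellipsoid) cavity volume from the per-view geometries
    a0 = spec.la_length / 2.0
    s2, s4 = view_scales["two_chamber"], view_scales["four_chamber"]
    area2 = np.pi * (a0 * s2) * (w2 / 2.0 * s2)
    area4 = np.pi * (a0 * s4) * (w4 / 2.0 * s4)
    length = 2 * a0 * np.minimum(s2, s4)
    lav_ml = (8.0 / (3.0 * np.pi)) * area2 * area4 / length / 1000.0

    mean_strain = (truth_strain["two_chamber"] + truth_strain["four_chamber"]) / 2
    peak_frame = int(np.argmax(mean_strain))
    in_plateau = (t_frac >= spec.diastasis[0]) & (t_frac <= spec.diastasis[1])
    preac_frame = int(np.nonzero(in_plateau)[0][-1]) if in_plateau.any() else peak_frame

    es = float(np.mean([v["es"] for v in per_view_vals.values()]))
    ea = float(np.mean([v["ea"] for v in per_view_vals.values()]))
    truth = PhantomTruth(
        landmarks=truth_landmarks, distances=truth_dist, strain=truth_strain,
        es=es, ee=es - ea, ea=ea, per_view=per_view_vals, lav_ml=lav_ml,
        peak_frame=peak_frame, preac_frame=preac_frame, frame_times=times,
        contours=contours,
    )
    return series["two_chamber"], series["four_chamber"], truth


# ---------------------------------------------------------------------------
# survival-cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distributional recipe for a simulated HCM-scale cohort.

    Strain means/SDs default to the patient cohort scale (eps_s 20.4 ± 7.6 %,
    eps_a 11.0 ± 4.2 %, correlation 0.5; eps_e = eps_s − eps_a by identity).
    ``log_hr`` maps column names to true per-unit log-hazard coefficients of
    the proportional-hazards model generating event times; covariates are
    centred before entering the linear predictor.
    """

    n: int = 500
    es_mean: float = 20.4
    es_sd: float = 7.6
    ea_mean: float = 11.0
    ea_sd: float = 4.2
    corr_es_ea: float = 0.5
    covariates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"age": (49.0, 12.0), "lvef": (64.0, 7.0)})
    log_hr: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.006  # events per month at the covariate means
    censoring_rate: float = 0.6  # target overall censored fraction (incl. cap)
    admin_cap: float = 100.0  # months, administrative end of follow-up
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise InvariantError("cohort size must be ≥ 2")
        if not 0 <= self.censoring_rate < 1:
            raise InvariantError("censoring rate must lie in [0, 1)")
        cov = np.array([[self.es_sd ** 2, self.corr_es_ea * self.es_sd * self.ea_sd],
                        [self.corr_es_ea * self.es_sd * self.ea_sd, self.ea_sd ** 2]])
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise InvariantError("strain correlation matrix is not positive definite") from exc


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table (id, time, event, strains, covariates).

    Event times are exponential with subject hazard
    ``baseline_hazard * exp(sum_c beta_c * (x_c - mean_c))``; censoring is the
    minimum of an independent exponential (rate tuned to the requested
    censoring fraction) and the administrative cap.  Strain values are
    truncated at 0 and eps_a at eps_s so the phasic identity holds row-wise.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    cov = np.array([[spec.es_sd ** 2, spec.corr_es_ea * spec.es_sd * spec.ea_sd],
                    [spec.corr_es_ea * spec.es_sd * spec.ea_sd, spec.ea_sd ** 2]])
    strains = rng.multivariate_normal([spec.es_mean, spec.ea_mean], cov, size=spec.n)
    es = np.clip(strains[:, 0], 0, None)
    ea = np.clip(strains[:, 1], 0, es)
    ee = es - ea

    df = pd.DataFrame({"id": [f"S{i:04d}" for i in range(spec.n)],
                       "es": es, "ee": ee, "ea": ea})
    means = {"es": spec.es_mean, "ea": spec.ea_mean,
             "ee": spec.es_mean - spec.ea_mean}
    for name, (mu, sd) in spec.covariates.items():
        df[name] = rng.normal(mu, sd, spec.n)
        means[name] = mu

    eta = np.zeros(spec.n)
    for name, beta in spec.log_hr.items():
        if name not in df.columns:
            raise InvariantError(f"log_hr refers to unknown column {name!r}")
        eta += beta * (df[name].to_numpy() - means.get(name, df[name].mean()))

    hazard = spec.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    lam_c = _censoring_rate_to_lambda(spec.censoring_rate, spec.baseline_hazard,
                                      spec.admin_cap)
    if lam_c > 0:
        t_cens = np.minimum(rng.exponential(1.0 / lam_c, spec.n), spec.admin_cap)
    else:
        t_cens = np.full(spec.n, spec.admin_cap)
    df["time"] = np.minimum(t_event, t_cens)
    df["event"] = (t_event <= t_cens).astype(int)
    return df


def _censoring_rate_to_lambda(target: float, lam0: float, cap: float) -> float:
    """Exponential censoring rate whose overall censored fraction (random +
    administrative, evaluated at the baseline hazard) matches ``target``.

    The administrative cap alone censors ``exp(-lam0*cap)``; a target below
    that floor is unreachable and falls back to cap-only censoring with a
    warning.
    """
    import warnings as _warnings

    from scipy.optimize import brentq

    def censored_fraction(lam_c: float) -> float:
        lam = lam0 + lam_c
        return lam_c / lam * (1 - np.exp(-lam * cap)) + np.exp(-lam * cap)

    floor = censored_fraction(0.0)
    if target <= floor:
        if target < floor - 0.02:
            _warnings.warn(
                f"censoring_rate {target:.2f} below administrative floor "
                f"{floor:.2f}; using cap-only censoring")
        return 0.0
    return float(brentq(lambda lc: censored_fraction(lc) - target, 1e-12, 1e3))
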