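# Methods

This note records the modelling choices behind `fastlas`: what is computed,
which parameters matter, what the synthetic phantoms do and do not emulate,
and where the design was genuinely open.

## Strain model

Left atrial long-axis strain is a line-length strain, not a tissue strain
field. Per long-axis view, two lines run from the posterior-wall midpoint to
the two atrioventricular-junction points; each line's strain is
`ε(t) = (D(t) − D0)·100/D0` with frame 0 (LV end-diastole) as the reference,
so `ε(0) = 0` holds exactly by construction. Distances are Euclidean in
millimetres with the row/column pixel spacing applied per axis, so
anisotropic acquisitions are handled without resampling.

The per-view curve is the **mean of the two line strains**, not the strain of
the mean distance. The two differ only at second order in the line-length
difference, but averaging strains keeps each line's own normalisation and
makes the view value insensitive to a static length asymmetry between the
two lines. Phasic values:

* reservoir `εs` — global maximum of the view-mean curve;
* booster `εa` — value at the pre-atrial-contraction frame (below);
* conduit `εe = εs − εa`, an identity enforced on every output. The
  healthy-scale magnitudes this package is validated against
  (εs ≈ 36, εa ≈ 16, εe ≈ 20) are consistent with that convention.

Subject-level values are the arithmetic mean of the two views; a missing
view yields a flagged single-view result rather than an error.

### Pre-atrial-contraction frame

No standard detection rule exists, so the package defines one: within the
last 40 % of the cycle (after the reservoir peak), take the **last local
maximum** of the smoothed view-mean curve — non-strict on the left, so the
final frame of a flat diastasis plateau qualifies. If no such maximum exists
(e.g. a triangular curve with no plateau), fall back to the frame minimising
|dε/dt| in that window, and flag the result when that lands on the window
boundary. A curve that is monotone to the last frame has no defined booster
phase; `εa`/`εe` are NaN with a flag.

### Smoothing

A 3-point moving average (frame 0 pinned at 0) is applied by default before
phase detection; it suppresses frame-to-frame tracking jitter that otherwise
creates spurious late-diastolic maxima. Because a moving average flattens
the reservoir peak by ~1–2 % of `εs` at 25 frames/cycle, phase **frames** are
detected on the smoothed curve but phasic **values** are read off the
unsmoothed curve at those frames. Smoothing can be disabled entirely
(`compute_strain_curve(..., smooth=False)`), in which case detection and
values use the same raw curve.

## Tracking

Each seeded point is tracked independently by normalized cross-correlation
(NCC) of a square template against a search window centred on the point's
previous-frame position (a motion prior; atrial excursion over the full
cycle can exceed any reasonable window centred on frame 0).

Defaults: template 15 × 15 px, search window 25 × 25 px (~2 cm at 1.4 mm
spacing), minimum acceptable peak score 0.5 (below it the frame is flagged
for manual adjustment). The template policy is `fixed_reference` — the
frame-0 patch is matched against every frame — because an adaptive
(previous-frame) template accumulates drift; on phantoms, adaptive tracking
roughly triples the landmark error and it is retained only as an option.

Two refinements matter quantitatively:

* **Scale compensation** (default on, 2 passes). A fixed-scale template
  matched against dilating tissue produces a systematic inward bias: the NCC
  peak follows the patch's gradient-energy centroid, which sits toward the
  strongly-edged atrial cavity. After a first standard pass, the per-frame
  line-length scale is estimated from the tracked positions and each frame is
  re-matched with the frame-0 template magnified by that scale. On phantoms
  this cuts the peak-strain error from ~1–2 % to ~0.3 % absolute.
* **Sub-pixel refinement** fits a full 2D quadratic (with cross term) to the
  3 × 3 score neighbourhood by least squares and takes its stationary point.
  The separable per-axis parabola exhibits pixel-locking bias up to ~0.35 px
  near half-pixel shifts; the 2D fit keeps worst-case error near 0.1 px.
  Border peaks and non-concave neighbourhoods return a zero offset with a
  warning.

A flat (zero-variance) template makes NCC undefined and raises immediately;
a search window leaving the image raises an error naming the frame and
point. Manual adjustment replaces a single frame's position (flagging it)
and by default re-tracks subsequent frames from the corrected position with
the frame-0 template.

## Volumetrics

Biplane area–length: `V = (8/3π)·A_2ch·A_4ch/L`, areas by the shoelace
formula on the traced polygons (converted to mm per axis first), `L` the
shorter of the two views' long-axis lengths, volume converted mm³ → ml. The
long-axis length is the posterior-wall midpoint to the midpoint of the
AV-junction chord when tracked landmarks are supplied; with contours alone it
falls back to the polygon's maximal chord, which coincides with that axis for
the near-elliptical LA cavity. With 64-vertex polygons the formula reproduces
sphere and spheroid volumes to < 0.5 % (pure inscribed-polygon area error).

Phase frames: `LAV_max` is the curve's global maximum, `LAV_min` its global
minimum, and `LAV_p-ac` uses the same late-diastolic shoulder rule as the
strain module, so strain and volume phase frames agree on phantoms. Emptying
fractions: total `(max−min)/max`, passive `(max−p-ac)/max`, active
`(p-ac−min)/p-ac` (×100), which satisfy
`(1−total) = (1−passive)(1−active)` identically. BSA is an input; no BSA
formula is computed.

LGE extent: threshold = mean + 6·SD of a remote-myocardium ROI (≥ 20 px,
required to be a subset of the myocardial mask); extent = percentage of
myocardial pixels above threshold.

## Cohort statistics

* **ROC**: AUC by tie-aware rank (pair counting with half credit); optimal
  cutoff maximises Youden's J, ties broken toward higher sensitivity. For
  strain markers lower values mean higher risk, so the classifier predicts
  an event when the value is ≤ the cutoff.
* **Kaplan–Meier / log-rank** via lifelines; with a single group only the
  product-limit curve is returned.
* **Cox regression** via statsmodels `PHReg` with Breslow tie handling by
  default (switchable to Efron); Wald 95 % CIs and p-values. Non-finite or
  exploding estimates (complete separation) raise a convergence error with
  diagnostics. The stepwise model screens candidates at univariate p < 0.1,
  then forward-selects with entry p < 0.05 and backward removal at p ≥ 0.10
  (common package defaults; "stepwise" alone does not pin these down), logging
  the inclusion trace.
* **Reliability**: ICC(2,1) — two-way random effects, absolute agreement,
  single measure (pingouin's ICC(A,1)) — plus a Bland–Altman-style COV,
  100·SD(paired differences)/grand mean. The two penalise different
  disagreement structures: a constant offset drives ICC below 1 while COV
  stays 0.

## Synthetic phantoms

The imaging phantom renders an idealised atrium: a bright elliptical blood
pool, dark 3–4 mm wall, and band-limited Gaussian speckle (correlation
length ~1.6 px, SD 9 intensity units on a ~0–100 scale), deformed by an
analytic similarity scaling about the posterior-wall midpoint. Because that
scaling moves every material point at distance d from the pivot to `d·s(t)`,
each distance line obeys `D(t) = D0·s(t)` exactly and the cavity volume is
`V0·s(t)³` — exact ground truth with no segmentation in the loop. The
strain–time profile is a C¹ piecewise half-cosine (rise to `εs` at 40 % of
the cycle, decay to the `εa` plateau over 70–85 %, return to 0 at end-cycle);
the phase definitions imply this curve family but not its parameterisation,
which is a package choice. Defaults mirror a routine acquisition: 1.4 × 1.3
mm spacing, 25 phases, RR 850 ms, LA length 52 mm; strain magnitudes default
to the patient-cohort scale (εs 20.4 %, εa 11.0 %). Per-frame Gaussian
acquisition noise (SD 2) is added after warping.

What the phantom does **not** emulate: through-plane motion, bSSFP banding
and flow artifacts, real wall texture, breathing/gating irregularity, or any
deformation mode other than a global similarity about one point. Passing the
recovery tests therefore demonstrates correctness of the tracking/strain
machinery under known deformation, not clinical accuracy on patient images —
where template decorrelation, artifacts and observer seeding dominate.

The cohort simulator draws (εs, εa) from a truncated bivariate normal
(defaults: 20.4 ± 7.6 and 11.0 ± 4.2, correlation 0.5; εe by identity),
Gaussian covariates, and exponential event times with hazard
`λ0·exp(Σ β·(x − x̄))` (λ0 = 0.006/month). Censoring is the minimum of an
independent exponential and a 100-month administrative cap; the exponential
rate is calibrated so the overall censored fraction matches the requested
`censoring_rate` at the baseline hazard (default 0.6; the cap alone imposes a
floor of `exp(−λ0·cap)` ≈ 0.55, and a lower request falls back to cap-only
censoring with a warning). Same-seed draws are bit-reproducible.

## Problem sizes used in validation

Phantom recovery runs 20 random geometries (εs ∈ [10, 40] %, εa ∈ [5, 20] %,
εa ≤ εs) at 112 × 112 px × 25 frames; tracker/oracle agreement uses 100
random patch/window pairs; Cox validation uses n = 500 cohorts for
hazard-ratio recovery and stepwise selection (100 replicates) and n = 120
for null CI coverage (200 replicates). These sizes give Monte-Carlo
tolerances of ±0.05 on a recovered hazard ratio of 0.89 and keep the whole
battery under a minute on one CPU.

## Known limitations

* Strain rate, circumferential/regional atrial strain and full-contour
  feature tracking are out of scope.
* DICOM support covers classic single-frame cine series only (no enhanced
  multi-frame, no vendor private tags); NIfTI timing is uniform, from
  pixdim.
* The pre-atrial-contraction rule assumes one cycle ending just before the
  next QRS; arrhythmic or truncated cycles will mis-place the shoulder.
* The scale-compensation pass assumes locally similar (isotropic) dilation
  around each landmark; strongly shearing motion would violate it.
* ICC confidence intervals are not reported, only the point estimate.
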