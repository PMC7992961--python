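"""Readers and writers: NIfTI/DICOM cine, JSON landmarks and contours, CSV tables.

File schemas
------------
Landmarks (JSON)::

    {"view": "two_chamber", "frame_index": 0,
     "points": {"av_anterior": [r, c], "av_inferior": [r, c], "posterior_mid": [r, c]}}

Contours (JSON)::

    {"view": "four_chamber", "polygons": [[[r, c], ...], ...]}   # one polygon per frame

Cohort tables are CSV with at least ``id``, ``time`` and ``event`` columns; any
other column is treated as a covariate.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CineSeries, ContourSequence, LandmarkSet, MIN_FRAMES
from .errors import FormatError, InvariantError

log = logging.getLogger("fastlas")


def setup_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# cine series
# ---------------------------------------------------------------------------

def read_cine(path, view: str, spacing_override=None, rr_interval=None) -> CineSeries:
    """Read a 2D+t cine from a NIfTI file or a DICOM series directory.

    ``spacing_override`` (row mm, col mm) replaces missing header spacing;
    without it, absent spacing is an error.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, view, spacing_override, rr_interval)
    return _read_nifti(path, view, spacing_override, rr_interval)


def _read_nifti(path: Path, view, spacing_override, rr_interval) -> CineSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise FormatError("expected a 2D+t NIfTI (rows, cols, 1, T)")
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise FormatError("expected a 2D+t NIfTI volume")
    if data.shape[-1] < MIN_FRAMES:
        raise InvariantError(f"≥ {MIN_FRAMES} frames required, got {data.shape[-1]}")
    frames = np.moveaxis(data, -1, 0)

    zooms = img.header.get_zooms()
    if spacing_override is not None:
        spacing = tuple(map(float, spacing_override))
    elif len(zooms) >= 2 and zooms[0] > 0 and zooms[1] > 0:
        spacing = (float(zooms[0]), float(zooms[1]))
    else:
        raise FormatError("NIfTI header lacks pixel spacing; pass spacing_override")

    dt = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else None
    _, t_unit = img.header.get_xyzt_units()
    if dt is not None and t_unit == "sec":
        dt *= 1000.0
    if dt is None:
        if rr_interval is None:
            raise FormatError("NIfTI header lacks frame timing; pass rr_interval")
        dt = float(rr_interval) / frames.shape[0]
    times = np.arange(frames.shape[0]) * dt
    rr = float(rr_interval) if rr_interval is not None else dt * frames.shape[0]
    return CineSeries(view, frames, times, spacing, rr)


def write_cine(series: CineSeries, path) -> None:
    """Write a CineSeries as 2D+t NIfTI (uniform frame timing from the mean dt)."""
    import nibabel as nib

    dt = float(np.mean(np.diff(series.frame_times))) if series.n_frames > 1 else 1.0
    data = np.moveaxis(series.frames, 0, -1)[:, :, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.diag([*series.pixel_spacing, 8.0, 1.0]))
    img.header.set_zooms((*series.pixel_spacing, 8.0, dt))
    img.header.set_xyzt_units("mm", "msec")
    nib.save(img, str(path))


def _read_dicom_series(path: Path, view, spacing_override, rr_interval) -> CineSeries:
    """Classic single-frame cine DICOM series, ordered by trigger time."""
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM clutter in the directory
            log.debug("skipping non-DICOM file %s", p.name)
    if len(datasets) < MIN_FRAMES:
        raise InvariantError(f"≥ {MIN_FRAMES} frames required, got {len(datasets)}")

    def sort_key(ds):
        tt = getattr(ds, "TriggerTime", None)
        return (0, float(tt)) if tt is not None else (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    shapes = {(ds.Rows, ds.Columns) for ds in datasets}
    if len(shapes) != 1:
        raise FormatError(f"mixed image shapes in series: {sorted(shapes)}")
    frames = np.stack([ds.pixel_array.astype(float) for ds in datasets])

    ds0 = datasets[0]
    if spacing_override is not None:
        spacing = tuple(map(float, spacing_override))
    elif getattr(ds0, "PixelSpacing", None) is not None:
        spacing = (float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
    else:
        raise FormatError("DICOM series lacks PixelSpacing; pass spacing_override")

    tts = [getattr(ds, "TriggerTime", None) for ds in datasets]
    if all(t is not None for t in tts):
        times = np.asarray([float(t) for t in tts])
        times = times - times[0]
    else:
        if rr_interval is None:
            raise FormatError("DICOM series lacks TriggerTime; pass rr_interval")
        times = np.arange(len(datasets)) * float(rr_interval) / len(datasets)
    if rr_interval is not None:
        rr = float(rr_interval)
    elif getattr(ds0, "NominalInterval", None):
        rr = float(ds0.NominalInterval)
    else:
        rr = float(times[-1] + np.median(np.diff(times)))
    return CineSeries(view, frames, times, spacing, rr)


# ---------------------------------------------------------------------------
# landmarks and contours
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        view = obj["view"]
        points = {k: tuple(map(float, v)) for k, v in obj["points"].items()}
        frame_index = int(obj.get("frame_index", 0))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed landmark file {path}: {exc}") from exc
    return LandmarkSet(view=view, points=points, frame_index=frame_index)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    obj = {
        "view": landmarks.view,
        "frame_index": landmarks.frame_index,
        "points": {k: list(v) for k, v in landmarks.points.items()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def read_contours(path) -> ContourSequence:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return ContourSequence(obj["view"], [np.asarray(p, dtype=float) for p in obj["polygons"]])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed contour file {path}: {exc}") from exc


def write_contours(contours: ContourSequence, path) -> None:
    obj = {"view": contours.view, "polygons": [p.tolist() for p in contours.polygons]}
    with open(path, "w") as fh:
        json.dump(obj, fh)


# ---------------------------------------------------------------------------
# cohort tables and reports
# ---------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = ("id", "time", "event")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; requires id/time/event columns, validates time ≥ 0."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing required column(s): {missing}")
    if (df["time"] < 0).any():
        raise InvariantError("follow-up times must be ≥ 0")
    if not df["event"].isin([0, 1, True, False]).all():
        raise InvariantError("event column must be 0/1")
    return df


def write_report(rows: list[dict], path) -> None:
    """Per-subject results CSV (strain per view and mean, volumes, LAEFs)."""
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
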