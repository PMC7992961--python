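"""Plain matplotlib plots: strain curves, volume curves, Kaplan-Meier steps."""

from __future__ import annotations

import numpy as np

from .cohort_stats import SurvivalFit
from .strain import StrainCurve
from .volumetrics import VolumeCurve


def plot_strain_curve(curve: StrainCurve, ax=None):
    """Per-line strain-time curves plus the view-mean (bold)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for name, e in curve.strain.items():
        ax.plot(curve.frame_times, e, alpha=0.6, label=name)
    ax.plot(curve.frame_times, curve.view_mean, "k-", lw=2, label="view mean")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("strain (%)")
    ax.set_title(curve.view.replace("_", "-"))
    ax.legend(fontsize=8)
    return ax


def plot_volume_curve(vc: VolumeCurve, frame_times=None, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = frame_times if frame_times is not None else np.arange(vc.lav_ml.size)
    ax.plot(t, vc.lav_ml, "-o", ms=3)
    for frame, label in ((vc.lav_max_frame, "max"), (vc.lav_p_ac_frame, "p-ac"),
                         (vc.lav_min_frame, "min")):
        ax.axvline(t[frame], color="grey", ls=":", lw=0.8)
        ax.annotate(label, (t[frame], vc.lav_ml[frame]), fontsize=8)
    ax.set_xlabel("time")
    ax.set_ylabel("LAV (ml)")
    return ax


def plot_km(fit: SurvivalFit, ax=None):
    """Step-style Kaplan-Meier curves per group with the log-rank p."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for group, df in fit.curves.items():
        ax.step(df["time"], df["survival"], where="post", label=str(group))
    if fit.p_value is not None:
        ax.set_title(f"log-rank p = {fit.p_value:.3g}")
    ax.set_xlabel("time")
    ax.set_ylabel("event-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax
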