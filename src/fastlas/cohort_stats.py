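"""Cohort-level statistics: ROC cutoffs, Kaplan-Meier/log-rank, Cox models,
and test-retest reliability (ICC, COV).

These are the outcome-analysis tools applied to per-subject strain values:
Youden-optimal ROC cutoffs for dichotomising a strain marker, Kaplan-Meier
survival by marker group with the log-rank test, univariate Cox proportional
hazards screening feeding a forward stepwise multivariate model, and
intra-/inter-observer reliability as ICC(2,1) (two-way random effects,
absolute agreement, single measure) plus a Bland-Altman-style coefficient of
variation (SD of paired differences over the grand mean).

Kaplan-Meier/log-rank computations are delegated to lifelines and Cox fits to
statsmodels' ``PHReg`` (Breslow tie handling by default, switchable to Efron);
ICC uses pingouin's two-way ANOVA decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .errors import ConvergenceError, StatsError

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass
class ROCResult:
    """AUC and the Youden-optimal cutoff with its operating point."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    lower_is_risk: bool

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise StatsError("AUC must lie in [0, 1]")


@dataclass
class SurvivalFit:
    """Per-group Kaplan-Meier step functions and the log-rank test."""

    curves: dict  # group -> DataFrame(time, survival)
    chi2: float | None
    p_value: float | None


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95 % CIs and p-values; one row per covariate.

    For stepwise output, ``screening`` holds the univariate pass and ``trace``
    the inclusion/removal log.
    """

    table: pd.DataFrame  # index covariate; coef, se, hr, ci_lower, ci_upper, p
    screening: pd.DataFrame | None = None
    trace: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index)


@dataclass
class ReliabilityResult:
    icc: float
    cov_percent: float

    def __post_init__(self):
        if self.icc > 1 + 1e-9:
            raise StatsError("ICC cannot exceed 1")
        if self.cov_percent < 0:
            raise StatsError("COV must be ≥ 0")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_cutoff(values, events, lower_is_risk: bool = True) -> ROCResult:
    """AUC (pair counting with half credit for ties) and Youden-optimal cutoff.

    With ``lower_is_risk`` the classifier predicts an event when the value is
    ≤ the cutoff (impaired strain); otherwise when ≥.  Ties in Youden's J are
    broken toward higher sensitivity.
    """
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.all() or not events.any():
        raise StatsError("ROC needs at least one event and one non-event")

    score = -values if lower_is_risk else values
    from scipy.stats import rankdata

    ranks = rankdata(score)  # midranks give the tie-corrected pair count
    n1, n0 = events.sum(), (~events).sum()
    auc = (ranks[events].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    best = None
    for c in np.unique(values):
        pred = values <= c if lower_is_risk else values >= c
        sens = np.count_nonzero(pred & events) / n1
        spec = np.count_nonzero(~pred & ~events) / n0
        j = sens + spec - 1
        key = (j, sens)
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    _, cutoff, sens, spec = best
    return ROCResult(float(auc), cutoff, float(sens), float(spec), lower_is_risk)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def km_logrank(times, events, group_labels) -> SurvivalFit:
    """Product-limit survival per group; log-rank test when ≥ 2 groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(group_labels)
    if np.any(times < 0):
        raise StatsError("times must be ≥ 0")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size == 0 or counts.min() == 0:
        raise StatsError("every group must contain at least one subject")

    curves = {}
    for g in labels:
        m = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
    if labels.size < 2:
        return SurvivalFit(curves, None, None)
    res = multivariate_logrank_test(times, groups, events)
    return SurvivalFit(curves, float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _fit_cox(df: pd.DataFrame, covariates: list[str], time_col: str,
             event_col: str, ties: str) -> pd.DataFrame:
    X = df[covariates].to_numpy(dtype=float)
    if np.any(np.std(X, axis=0) == 0):
        flat = [c for c in covariates if df[c].std() == 0]
        raise StatsError(f"constant covariate(s): {flat}")
    model = PHReg(df[time_col].to_numpy(dtype=float), X,
                  status=df[event_col].to_numpy(dtype=int), ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=False)
    coef, se = np.asarray(fit.params), np.asarray(fit.bse)
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(se))) or np.any(np.abs(coef) > 50):
        raise ConvergenceError(
            f"Cox fit did not converge for {covariates} "
            f"(coef={coef}, se={se}); possible complete separation")
    p = np.asarray(fit.pvalues)
    return pd.DataFrame(
        {"coef": coef, "se": se, "hr": np.exp(coef),
         "ci_lower": np.exp(coef - Z_95 * se), "ci_upper": np.exp(coef + Z_95 * se),
         "p": p},
        index=covariates)


def cox_univariate(cohort: pd.DataFrame, covariate: str, time_col: str = "time",
                   event_col: str = "event", ties: str = "breslow") -> CoxResult:
    """Univariate Cox partial-likelihood fit; HR with Wald 95 % CI and p."""
    if cohort[event_col].sum() < 1:
        raise StatsError("at least one event is required")
    return CoxResult(_fit_cox(cohort, [covariate], time_col, event_col, ties))


def cox_stepwise(cohort: pd.DataFrame, candidate_covariates: list[str],
                 time_col: str = "time", event_col: str = "event",
                 screen_p: float = 0.1, entry_p: float = 0.05,
                 removal_p: float = 0.10, ties: str = "breslow") -> CoxResult:
    """Univariate screening at p < ``screen_p``, then forward stepwise Wald
    selection (entry p < ``entry_p``, removal p ≥ ``removal_p``).
    """
    if len(candidate_covariates) < 2:
        raise StatsError("stepwise selection needs ≥ 2 candidates")
    trace: list[str] = []
    rows = []
    for c in candidate_covariates:
        try:
            row = _fit_cox(cohort, [c], time_col, event_col, ties).iloc[0]
        except (StatsError, ConvergenceError) as exc:
            trace.append(f"screen {c}: failed ({exc})")
            continue
        rows.append(row.rename(c))
    screening = pd.DataFrame(rows)
    survivors = [c for c in screening.index if screening.loc[c, "p"] < screen_p]
    trace.append(f"screened at p<{screen_p}: {survivors}")
    if not survivors:
        warnings.warn("no candidate passed univariate screening; empty model")
        empty = screening.iloc[:0]
        return CoxResult(empty, screening, trace)

    included: list[str] = []
    while True:
        best = None
        for c in survivors:
            if c in included:
                continue
            try:
                tab = _fit_cox(cohort, included + [c], time_col, event_col, ties)
            except (StatsError, ConvergenceError):
                continue
            p = tab.loc[c, "p"]
            if best is None or p < best[0]:
                best = (p, c)
        if best is None or best[0] >= entry_p:
            break
        included.append(best[1])
        trace.append(f"enter {best[1]} (p={best[0]:.4g})")
        while len(included) > 1:  # backward check after each entry
            tab = _fit_cox(cohort, included, time_col, event_col, ties)
            worst = tab["p"].idxmax()
            if tab.loc[worst, "p"] >= removal_p and worst != best[1]:
                included.remove(worst)
                trace.append(f"remove {worst} (p={tab.loc[worst, 'p']:.4g})")
            else:
                break
    if not included:
        warnings.warn("no candidate met the entry criterion; empty model")
        return CoxResult(screening.iloc[:0], screening, trace)
    final = _fit_cox(cohort, included, time_col, event_col, ties)
    return CoxResult(final, screening, trace)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def reliability(meas_a, meas_b) -> ReliabilityResult:
    """ICC(2,1) and coefficient of variation for paired repeated measurements.

    ICC is the two-way random-effects, absolute-agreement, single-measure
    form; COV = 100 * SD(paired differences) / mean of all measurements.
    """
    a = np.asarray(meas_a, dtype=float)
    b = np.asarray(meas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired 1-D measurement arrays required")
    n = a.size
    if n < 3:
        raise StatsError("reliability needs ≥ 3 paired measurements")

    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "value": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc_table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="value")
    by_type = icc_table.set_index("Type")["ICC"]
    # two-way random, absolute agreement, single measure: McGraw-Wong ICC(A,1),
    # labelled ICC2 in older pingouin releases
    icc = float(by_type.get("ICC(A,1)", by_type.get("ICC2")))

    grand_mean = np.concatenate([a, b]).mean()
    if grand_mean == 0:
        raise StatsError("zero grand mean: COV undefined")
    cov = 100.0 * np.std(a - b, ddof=1) / abs(grand_mean)
    return ReliabilityResult(icc, float(cov))
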