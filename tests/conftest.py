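import numpy as np
import pytest

from fastlas import PhantomSpec, make_la_phantom, track_landmarks


@pytest.fixture(scope="session")
def default_phantom():
    """One rendered exam (both views) with ground truth, shared across tests."""
    spec = PhantomSpec(es=20.0, ea=11.0, texture_seed=0)
    two, four, truth = make_la_phantom(spec)
    return spec, two, four, truth


@pytest.fixture(scope="session")
def tracked_phantom(default_phantom):
    """Default-config tracking of the shared phantom, both views."""
    _, two, four, truth = default_phantom
    tr2 = track_landmarks(two, truth.seed_landmarks("two_chamber"))
    tr4 = track_landmarks(four, truth.seed_landmarks("four_chamber"))
    return tr2, tr4


@pytest.fixture(scope="session")
def static_phantom():
    spec = PhantomSpec(es=0.0, ea=0.0, texture_seed=2)
    two, four, truth = make_la_phantom(spec)
    return spec, two, four, truth


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force / closed-form)
# ---------------------------------------------------------------------------

def brute_force_ncc(template: np.ndarray, window: np.ndarray):
    """Exhaustive normalized cross-correlation over all integer placements."""
    th, tw = template.shape
    wh, ww = window.shape
    tz = template - template.mean()
    tnorm = np.sqrt((tz ** 2).sum())
    surface = np.full((wh - th + 1, ww - tw + 1), -np.inf)
    for i in range(surface.shape[0]):
        for j in range(surface.shape[1]):
            patch = window[i:i + th, j:j + tw]
            pz = patch - patch.mean()
            denom = tnorm * np.sqrt((pz ** 2).sum())
            surface[i, j] = (tz * pz).sum() / denom if denom > 0 else 0.0
    peak = np.unravel_index(np.argmax(surface), surface.shape)
    center = ((wh - th) // 2, (ww - tw) // 2)
    return (peak[0] - center[0], peak[1] - center[1]), surface


def brute_force_auc(values, events, lower_is_risk=True):
    """Pair counting over all event x non-event pairs, half credit for ties."""
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=bool)
    ev, nev = values[events], values[~events]
    total = 0.0
    for a in ev:
        for b in nev:
            riskier = a < b if lower_is_risk else a > b
            total += 1.0 if riskier else (0.5 if a == b else 0.0)
    return total / (ev.size * nev.size)


def anova_icc21(a, b):
    """ICC(2,1) straight from the two-way ANOVA table (n subjects, k=2 raters)."""
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ms_err = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)


def breslow_partial_loglik(beta, times, events, x):
    """Hand-written Breslow partial log-likelihood for a single covariate."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = (times == t) & (events == 1)
        ll += beta * x[d].sum() - d.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll
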