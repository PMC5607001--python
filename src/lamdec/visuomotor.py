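"""Visuomotor index: placing units on the increased/decreased/perimovement continuum.

The index of a unit is the trial-by-trial Pearson correlation between
reaction time and its baseline-subtracted mean firing rate in the -600 to
-200 ms epoch before movement onset (window start truncated to -RT for
trials faster than 600 ms, so pre-cue activity never enters).  The
baseline is the hold-period rate in the 200 ms before cue onset.  Both
reach directions are pooled.

Significance uses a 90% bootstrap percentile confidence interval (p < .05
per tail): units whose CI lies above zero are *increased*, below zero
*decreased*, and units with an interval covering zero are *perimovement*.
A Jeffreys-Zellner-Siow Bayes factor for a nonzero correlation provides an
independent check that perimovement units are not merely weak
increased/decreased units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .session_io import TrialRecord

__all__ = [
    "VisuomotorResult",
    "TuningResult",
    "premovement_window_rates",
    "visuomotor_index",
    "correlation_bayes_factor",
    "tuning_preference",
]

INDEX_WINDOW = (-600, -200)  # ms relative to movement onset
BASELINE_WINDOW = (-200, 0)  # ms relative to cue onset


@dataclass
class VisuomotorResult:
    unit_id: int
    index_r: float
    ci_low: float
    ci_high: float
    category: str  # increased | decreased | perimovement
    bayes_factor: float
    n_trials: int
    low_power: bool = False  # fewer than 30 usable trials
    degenerate: bool = False  # zero rate variance, index undefined


@dataclass
class TuningResult:
    unit_id: int
    preferred: int  # -1 left, +1 right
    p_value: float


def _counts(spike_times: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Spike counts in half-open [lo, hi) per trial."""
    return (
        np.searchsorted(spike_times, hi, side="left")
        - np.searchsorted(spike_times, lo, side="left")
    ).astype(float)


def premovement_window_rates(
    spike_times: np.ndarray, trials: Sequence[TrialRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial baseline-subtracted mean rate in the pre-movement epoch.

    Returns ``(rates_hz, rts_ms)`` over non-change-of-mind trials.  The
    epoch is [-600, -200) ms before movement, its start truncated to -RT
    for RT < 600 ms; the hold-period baseline ([-200, 0) before cue) is
    subtracted per trial.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=np.int64))
    use = [t for t in trials if not t.change_of_mind]
    move = np.array([t.move_on_ms for t in use], dtype=np.int64)
    cue = np.array([t.cue_on_ms for t in use], dtype=np.int64)
    rt = np.array([t.rt_ms for t in use], dtype=np.int64)

    start = move + np.maximum(INDEX_WINDOW[0], -rt)
    stop = move + INDEX_WINDOW[1]
    width_s = (stop - start) / 1000.0
    ok = width_s > 0
    rate = np.full(len(use), np.nan)
    rate[ok] = _counts(spike_times, start[ok], stop[ok]) / width_s[ok]

    b0 = cue + BASELINE_WINDOW[0]
    b1 = cue + BASELINE_WINDOW[1]
    baseline = _counts(spike_times, b0, b1) / ((b1 - b0) / 1000.0)
    return rate - baseline, rt.astype(float)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.sum(xc * yc, axis=1)
    den = np.sqrt(np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def visuomotor_index(
    spike_times: np.ndarray,
    trials: Sequence[TrialRecord],
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    unit_id: int = -1,
    method: str = "pearson",
    compute_bayes_factor: bool = True,
) -> VisuomotorResult:
    """Compute the visuomotor index and category of one unit.

    ``method`` is ``"pearson"`` (default) or ``"spearman"`` (rank variant).
    The 90% CI comes from ``n_boot`` percentile-bootstrap resamples of
    trials.  Units with under 30 trials are flagged ``low_power``; a
    zero-variance rate leaves the index undefined and the unit labelled
    perimovement with ``degenerate=True``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rate, rt = premovement_window_rates(spike_times, trials)
    keep = ~np.isnan(rate)
    rate, rt = rate[keep], rt[keep]
    n = rate.size
    low_power = n < 30
    if n < 3 or np.ptp(rate) == 0 or np.ptp(rt) == 0:
        return VisuomotorResult(unit_id, math.nan, math.nan, math.nan, "perimovement",
                                math.nan, n, low_power=low_power, degenerate=True)
    r, ci_low, ci_high, category = index_from_rates(rate, rt, n_boot=n_boot, rng=rng, method=method)
    bf = correlation_bayes_factor(r=r, n=n) if compute_bayes_factor else math.nan
    return VisuomotorResult(unit_id, r, ci_low, ci_high, category, bf, n,
                            low_power=low_power)


def index_from_rates(
    rate: np.ndarray,
    rt: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    method: str = "pearson",
) -> tuple[float, float, float, str]:
    """Index, 90% bootstrap CI, and category from paired rate/RT samples.

    This is the statistical core of :func:`visuomotor_index`, usable
    directly when per-trial window rates are already in hand.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rate = np.asarray(rate, dtype=float)
    rt = np.asarray(rt, dtype=float)
    n = rate.size
    if method == "spearman":
        rate = stats.rankdata(rate)
        rt_used = stats.rankdata(rt)
    elif method == "pearson":
        rt_used = rt
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    r = float(_rowwise_pearson(rate[None, :], rt_used[None, :])[0])

    idx = rng.integers(0, n, size=(n_boot, n))
    if method == "spearman":
        xb = np.apply_along_axis(stats.rankdata, 1, rate[idx])
        yb = np.apply_along_axis(stats.rankdata, 1, rt_used[idx])
        boot = _rowwise_pearson(xb, yb)
    else:
        boot = _rowwise_pearson(rate[idx], rt_used[idx])
    boot = boot[np.isfinite(boot)]
    ci_low, ci_high = np.percentile(boot, [5.0, 95.0])

    if ci_low > 0:
        category = "increased"
    elif ci_high < 0:
        category = "decreased"
    else:
        category = "perimovement"
    return r, float(ci_low), float(ci_high), category


def correlation_bayes_factor(
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    *,
    r: float | None = None,
    n: int | None = None,
    scale: float = 1.0 / math.sqrt(2.0),
) -> float:
    """JZS Bayes factor for a nonzero correlation versus zero.

    Evidence ratio BF10 for H1 (correlation != 0, Zellner-Siow g-prior on
    the standardized slope with the given ``scale``) against H0
    (correlation = 0).  Either pass the two samples or ``r`` and ``n``
    directly.  Values >> 1 favor a nonzero correlation.
    """
    if r is None or n is None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 10:
            raise ValueError("need paired samples with n >= 10")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("degenerate variance: Bayes factor undefined")
        n = x.size
        r = float(np.corrcoef(x, y)[0, 1])
    if n < 3:
        raise ValueError("need n >= 3")
    r2 = min(r * r, 1.0 - 1e-12)
    s2 = scale * scale

    # log marginal-likelihood ratio integrand over the g-prior mixing
    # variable; integrate on a log-spaced grid after factoring out the peak
    g = np.logspace(-8, 10, 4001)
    logf = (
        0.5 * (n - 2) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p((1.0 - r2) * g)
        - 1.5 * np.log(g)
        - n * s2 / (2.0 * g)
    )
    peak = np.max(logf)
    integral = np.trapezoid(np.exp(logf - peak), g)
    log_bf = peak + math.log(integral) + 0.5 * math.log(n * s2 / 2.0) - 0.5 * math.log(math.pi)
    return float(math.exp(log_bf)) if log_bf < 700 else float("inf")


def tuning_preference(
    spike_times: np.ndarray,
    trials: Sequence[TrialRecord],
    unit_id: int = -1,
) -> TuningResult:
    """Preferred reach direction from the perimovement epoch.

    Two-sample t-test on per-trial mean rates in [move - 150, move + 50) ms
    for left versus right reaches; the preferred side is the one with the
    larger mean.  Requires at least two trials per side.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=np.int64))
    use = [t for t in trials if not t.change_of_mind]
    move = np.array([t.move_on_ms for t in use], dtype=np.int64)
    choice = np.array([t.choice for t in use])
    rate = _counts(spike_times, move - 150, move + 50) / 0.2
    left, right = rate[choice == -1], rate[choice == 1]
    if left.size < 2 or right.size < 2:
        raise ValueError("need at least two trials per reach direction")
    t, p = stats.ttest_ind(left, right)
    preferred = -1 if left.mean() >= right.mean() else 1
    return TuningResult(unit_id=unit_id, preferred=preferred, p_value=float(p))
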