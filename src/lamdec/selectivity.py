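"""Choice selectivity: magnitude, build-up slope, and discrimination time.

The choice-selectivity signal of a unit is ``|mean rate on left-choice
trials - mean rate on right-choice trials|`` as a function of time, with
the same absolute difference measured during the hold period subtracted
before averaging across units.  Its build-up slope in the 150-350 ms
post-cue epoch grows with stimulus coherence for decision-related units.

*Discrimination time* is the earliest post-cue time at which selectivity
departs from the hold-period level for at least 50 consecutive
milliseconds -- at the population level via a paired t-test across units
with Benjamini-Hochberg false-discovery-rate correction over time bins,
and at the single-unit level via the 95th percentile of bootstrapped
hold-period selectivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .rates import RateMatrix

__all__ = [
    "SelectivityTimecourse",
    "DiscriminationTime",
    "SlopeResult",
    "unit_selectivity",
    "choice_selectivity_signal",
    "selectivity_slope",
    "population_discrimination_time",
    "unit_discrimination_time",
    "premovement_magnitude_test",
    "latency_rt_slope",
]


def _quiet(fn, *args, **kwargs):
    """NaN-aware reductions over all-masked slices are expected; silence the
    numpy warning they emit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return fn(*args, **kwargs)

HOLD_WINDOW = (-500, 0)  # ms before cue onset, reference epoch for timing tests
MIN_RUN_MS = 50


@dataclass
class SelectivityTimecourse:
    label: dict
    time_axis: np.ndarray
    mean: np.ndarray  # across units
    sem: np.ndarray
    n_units: int
    omitted_units: int  # units missing a choice in this condition


@dataclass
class DiscriminationTime:
    latency_ms: float
    bootstrap_se_ms: float
    defined: bool


@dataclass
class SlopeResult:
    coherences: np.ndarray
    slopes: np.ndarray  # selectivity build-up slope per coherence (spk/s^2)
    second_level_slope: float  # spk/s^2 per 100% coherence
    shuffle_p: float
    clipped: bool


def _choice_means(values: np.ndarray, choices: np.ndarray, weights: np.ndarray | None = None):
    """NaN-aware per-choice mean traces, optionally with resampling weights."""
    out = {}
    for ch in (-1, 1):
        rows = values[choices == ch]
        if rows.shape[0] == 0:
            return None
        if weights is None:
            out[ch] = _quiet(np.nanmean, rows, axis=0)
        else:
            w = weights[choices == ch]
            mask = ~np.isnan(rows)
            num = w @ np.nan_to_num(rows)
            den = w @ mask
            with np.errstate(invalid="ignore", divide="ignore"):
                out[ch] = num / den
    return out


def unit_selectivity(
    matrix: RateMatrix,
    trial_sel: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float] | None:
    """Selectivity trace ``|L - R|(t)`` and its hold-period value for one unit.

    Returns ``None`` if either choice is absent in the selected trials.
    The hold value is the mean of the trace over [-500, 0) ms before cue
    (cue-aligned matrices only; NaN otherwise).
    """
    values = matrix.values if trial_sel is None else matrix.values[trial_sel]
    choices = matrix.choices if trial_sel is None else matrix.choices[trial_sel]
    means = _choice_means(values, choices, weights)
    if means is None:
        return None
    sel = np.abs(means[-1] - means[1])
    if matrix.alignment == "cue":
        h = (matrix.time_axis >= HOLD_WINDOW[0]) & (matrix.time_axis < HOLD_WINDOW[1])
        hold = float(_quiet(np.nanmean, sel[h]))
    else:
        hold = math.nan
    return sel, hold


def choice_selectivity_signal(
    matrices: Sequence[RateMatrix],
    grouping: str | None = None,
    rt_bins: Sequence[tuple[int, int]] | None = None,
) -> list[SelectivityTimecourse]:
    """Population choice-selectivity signal, hold-difference subtracted.

    ``grouping`` is ``None`` (all trials pooled), ``"coherence"``, or
    ``"rt"`` (requires ``rt_bins``).  Per condition, each unit contributes
    its ``|L - R|(t)`` minus its hold-period ``|L - R|``; the timecourse is
    the across-unit mean with SEM over units.  Units missing a choice in a
    condition are omitted and counted.
    """
    time_axis = matrices[0].time_axis
    if grouping is None:
        conditions = [({"all": True}, None)]
    elif grouping == "coherence":
        levels = np.unique(np.concatenate([m.coherences for m in matrices]))
        conditions = [({"coherence": float(c)}, ("coherence", c)) for c in levels]
    elif grouping == "rt":
        if rt_bins is None:
            raise ValueError("rt grouping requires rt_bins")
        conditions = [({"rt_bin": b}, ("rt", b)) for b in rt_bins]
    else:
        raise ValueError("grouping must be None, 'coherence', or 'rt'")

    out = []
    for label, cond in conditions:
        traces = []
        omitted = 0
        for m in matrices:
            if cond is None:
                sel = None
            elif cond[0] == "coherence":
                sel = m.coherences == cond[1]
            else:
                lo, hi = cond[1]
                sel = (m.rts >= lo) & (m.rts < hi)
            res = unit_selectivity(m, sel)
            if res is None:
                omitted += 1
                continue
            trace, hold = res
            traces.append(trace - (hold if math.isfinite(hold) else 0.0))
        if not traces:
            continue
        arr = np.vstack(traces)
        n = np.sum(~np.isnan(arr), axis=0)
        mean = _quiet(np.nanmean, arr, axis=0)
        sd = _quiet(np.nanstd, arr, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        out.append(SelectivityTimecourse(label, time_axis, mean, sem, len(traces), omitted))
    return out


def _ols_slope(t_ms: np.ndarray, y: np.ndarray) -> float:
    """Slope of y (Hz) against time in seconds, NaN-aware."""
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return math.nan
    t = t_ms[ok] / 1000.0
    return float(np.polyfit(t, y[ok], 1)[0])


def selectivity_slope(
    matrices: Sequence[RateMatrix],
    window_ms: tuple[int, int] = (150, 350),
    n_shuffle: int = 200,
    rng: np.random.Generator | int | None = None,
) -> SlopeResult:
    """Coherence dependence of the selectivity build-up rate.

    For each coherence level the population selectivity signal is
    regressed on time within ``window_ms`` (post-cue); the resulting
    slopes are then regressed on coherence, reported per 100% coherence.
    Significance comes from shuffling coherence labels across each unit's
    per-coherence curves (one-sided, larger-than-null).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    time_axis = matrices[0].time_axis
    levels = np.unique(np.concatenate([m.coherences for m in matrices]))
    win = (time_axis >= window_ms[0]) & (time_axis < window_ms[1])
    t_win = time_axis[win]

    # per-coherence truncation at (median RT - 100): beyond it most trials
    # are masked and the |L - R| noise floor inflates, biasing the slope
    clipped = False
    trunc = {}
    for c in levels:
        rts = np.concatenate([m.rts[m.coherences == c] for m in matrices])
        trunc[float(c)] = np.median(rts) - 100 if rts.size else window_ms[1]
        if trunc[float(c)] < window_ms[1]:
            clipped = True

    # units x coherence x window-bins selectivity curves
    curves = np.full((len(matrices), levels.size, int(win.sum())), np.nan)
    for i, m in enumerate(matrices):
        for j, c in enumerate(levels):
            res = unit_selectivity(m, m.coherences == c)
            if res is not None:
                trace = res[0][win].copy()
                trace[t_win >= trunc[float(c)]] = np.nan
                curves[i, j] = trace

    def second_level(cu: np.ndarray) -> tuple[np.ndarray, float]:
        pop = _quiet(np.nanmean, cu, axis=0)  # coherence x bins
        slopes = np.array([_ols_slope(t_win, pop[j]) for j in range(levels.size)])
        ok = np.isfinite(slopes)
        beta = float(np.polyfit(levels[ok] / 100.0, slopes[ok], 1)[0]) if ok.sum() >= 2 else math.nan
        return slopes, beta

    slopes, beta = second_level(curves)
    null = np.empty(n_shuffle)
    for k in range(n_shuffle):
        perm = curves[np.arange(len(matrices))[:, None],
                      np.argsort(rng.random((len(matrices), levels.size)), axis=1)]
        null[k] = second_level(perm)[1]
    p = float((1 + np.sum(null >= beta)) / (n_shuffle + 1))
    return SlopeResult(levels, slopes, beta, p, clipped)


def _selectivity_stack(
    matrices: Sequence[RateMatrix],
    rt_bin: tuple[int, int] | None,
    weights: list[np.ndarray] | None = None,
):
    traces, holds = [], []
    for i, m in enumerate(matrices):
        sel = None if rt_bin is None else (m.rts >= rt_bin[0]) & (m.rts < rt_bin[1])
        w = None if weights is None else weights[i]
        res = unit_selectivity(m, sel, w)
        if res is None:
            continue
        trace, hold = res
        if math.isfinite(hold):
            traces.append(trace)
            holds.append(hold)
    if not traces:
        return None
    return np.vstack(traces), np.array(holds)


def _first_sustained(sig: np.ndarray, time_axis: np.ndarray, min_run: int) -> float:
    """First time beginning a run of >= min_run consecutive True bins."""
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= min_run:
            return float(time_axis[i - min_run + 1])
    return math.nan


def population_discrimination_time(
    matrices: Sequence[RateMatrix],
    rt_bin: tuple[int, int] | None = None,
    alpha: float = 0.05,
    min_run_ms: int = MIN_RUN_MS,
    n_surrogates: int = 50,
    rng: np.random.Generator | int | None = None,
    min_units: int = 5,
) -> DiscriminationTime:
    """Population discrimination time for a set of cue-aligned units.

    At each 1-ms post-cue bin a paired t-test compares units' selectivity
    to their own hold-period selectivity; p-values are BH-FDR corrected
    over bins, and the latency is the first bin starting >= 50 consecutive
    significant milliseconds.  The error bar is the SD of latencies over
    ``n_surrogates`` trial-resampled surrogate rate sets per unit.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    time_axis = matrices[0].time_axis

    def latency(weights=None) -> float:
        stack = _selectivity_stack(matrices, rt_bin, weights)
        if stack is None:
            return math.nan
        traces, holds = stack
        diffs = traces - holds[:, None]
        post = time_axis >= 0
        d = diffs[:, post]
        n_ok = np.sum(np.isfinite(d), axis=0)
        testable = n_ok >= max(min_units, 2)
        mean = _quiet(np.nanmean, d, axis=0)
        sd = _quiet(np.nanstd, d, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = mean / (sd / np.sqrt(n_ok))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=np.maximum(n_ok - 1, 1))
        p = np.where(testable & np.isfinite(p), p, 1.0)
        padj = stats.false_discovery_control(p, method="bh")
        sig = padj < alpha
        return _first_sustained(sig, time_axis[post], min_run_ms)

    lat = latency()
    if math.isnan(lat):
        return DiscriminationTime(math.nan, math.nan, False)

    se = math.nan
    if n_surrogates > 0:
        boot = []
        for _ in range(n_surrogates):
            weights = []
            for m in matrices:
                w = np.zeros(m.values.shape[0])
                # resample within choice to keep both reach directions present
                for ch in (-1, 1):
                    idx = np.flatnonzero(m.choices == ch)
                    if idx.size:
                        draw = rng.integers(0, idx.size, size=idx.size)
                        np.add.at(w, idx[draw], 1.0)
                weights.append(w)
            boot.append(latency(weights))
        boot = np.asarray(boot)
        if np.isfinite(boot).sum() >= 2:
            se = float(np.nanstd(boot, ddof=1))
    return DiscriminationTime(lat, se, True)


def unit_discrimination_time(
    matrix: RateMatrix,
    n_boot: int = 200,
    min_run_ms: int = MIN_RUN_MS,
    rng: np.random.Generator | int | None = None,
) -> DiscriminationTime:
    """Single-unit discrimination time.

    The unit's selectivity must exceed the 95th percentile of its
    bootstrapped hold-period selectivity for at least 50 consecutive ms;
    the latency is the start of that run.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    res = unit_selectivity(matrix)
    if res is None:
        return DiscriminationTime(math.nan, math.nan, False)
    sel, _ = res
    post = matrix.time_axis >= 0

    def resample_weights() -> np.ndarray:
        w = np.zeros(matrix.values.shape[0])
        for ch in (-1, 1):
            idx = np.flatnonzero(matrix.choices == ch)
            draw = rng.integers(0, idx.size, size=idx.size)
            np.add.at(w, idx[draw], 1.0)
        return w

    boots = [unit_selectivity(matrix, None, resample_weights()) for _ in range(n_boot)]
    hold_boot = np.array([b[1] if b is not None else np.nan for b in boots])
    thresh = float(np.nanpercentile(hold_boot, 95.0))
    lat = _first_sustained(sel[post] > thresh, matrix.time_axis[post], min_run_ms)
    if math.isnan(lat):
        return DiscriminationTime(math.nan, math.nan, False)
    boot_lat = np.array(
        [
            _first_sustained(b[0][post] > thresh, matrix.time_axis[post], min_run_ms)
            for b in boots
            if b is not None
        ]
    )
    ok = np.isfinite(boot_lat)
    se = float(np.std(boot_lat[ok], ddof=1)) if ok.sum() >= 2 else math.nan
    return DiscriminationTime(lat, se, True)


def latency_rt_slope(latencies_ms: np.ndarray, rt_bin_centers_ms: np.ndarray):
    """Regression of discrimination time on RT-bin center (ms per ms of RT)."""
    ok = np.isfinite(latencies_ms)
    if ok.sum() < 2:
        raise ValueError("need at least two defined latencies")
    return stats.linregress(np.asarray(rt_bin_centers_ms)[ok], np.asarray(latencies_ms)[ok])


def premovement_magnitude_test(
    matrices: Sequence[RateMatrix],
    window_ms: tuple[int, int] = (-100, 0),
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Coherence modulation of selectivity magnitude just before movement.

    For each (movement-aligned) unit, the mean selectivity in
    ``window_ms`` is computed per coherence level and regressed on
    coherence.  Returns ``(median_slope, p)`` where the slope is in Hz per
    100% coherence and ``p`` is a sign test of per-unit slopes against
    coherence-shuffled slopes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    slopes, null_slopes = [], []
    for m in matrices:
        win = (m.time_axis >= window_ms[0]) & (m.time_axis < window_ms[1])
        levels = np.unique(m.coherences)
        vals = np.full(levels.size, np.nan)
        for j, c in enumerate(levels):
            res = unit_selectivity(m, m.coherences == c)
            if res is not None:
                vals[j] = _quiet(np.nanmean, res[0][win])
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        x = levels[ok] / 100.0
        y = vals[ok]
        slopes.append(float(np.polyfit(x, y, 1)[0]))
        null_slopes.append(float(np.polyfit(x, rng.permutation(y), 1)[0]))
    slopes = np.asarray(slopes)
    null_slopes = np.asarray(null_slopes)
    if slopes.size == 0:
        return math.nan, math.nan
    greater = int(np.sum(slopes > null_slopes))
    ties = int(np.sum(slopes == null_slopes))
    n_eff = slopes.size - ties
    p = float(stats.binomtest(greater, n_eff, 0.5).pvalue) if n_eff else 1.0
    return float(np.median(slopes)), p
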