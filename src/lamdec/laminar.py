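"""Depth-resolved decision signals: index-vs-depth fits and
superficial-vs-deep choice decoding.

The 16-contact laminar probe spans the cortical depth at 150-um spacing
(contact 1 most superficial).  Three analyses quantify laminar
organization:

* the visuomotor index averaged per electrode (over units, then over
  sessions) is fit with a cubic polynomial of depth, with a permutation
  test (index values shuffled across units) on the fit's R^2;
* per-depth discrimination times are rank-correlated with depth;
* a pooled-variance Gaussian naive-Bayes (linear) classifier decodes
  choice from 50-ms boxcar spike counts, retrained every 2 ms, separately
  for superficial (electrodes 1-8) and deep (9-16) unit pools of the same
  size; the latency at which accuracy first exceeds 55% gives the
  superficial "latency benefit" t_deep - t_superficial, tested by
  bootstrapping sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .session_io import SessionBundle
from .visuomotor import VisuomotorResult

__all__ = [
    "LaminarProfile",
    "DecodingResult",
    "depth_profile",
    "laminar_decode",
    "decoding_latency_benefit",
    "pooled_gaussian_decode",
]

SUPERFICIAL_ELECTRODES = range(1, 9)
DEEP_ELECTRODES = range(9, 17)


@dataclass
class LaminarProfile:
    depths_mm: np.ndarray  # per-electrode mean depth
    mean_index: np.ndarray  # per-electrode index, averaged over units then sessions
    cubic_coeffs: np.ndarray  # (a, b, c, d) of a x^3 + b x^2 + c x + d
    r_squared: float
    permutation_p: float
    discrimination_time_ms: np.ndarray | None = None
    time_depth_spearman_r: float = math.nan
    time_depth_spearman_p: float = math.nan


@dataclass
class DecodingResult:
    session_id: str
    time_axis: np.ndarray
    accuracy_superficial: np.ndarray
    accuracy_deep: np.ndarray
    n_units_used: int
    latency_superficial_ms: float = math.nan
    latency_deep_ms: float = math.nan


def depth_profile(
    sessions: Sequence[SessionBundle],
    results: Sequence[Sequence[VisuomotorResult]],
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    discrimination_times: np.ndarray | None = None,
) -> LaminarProfile:
    """Visuomotor index as a function of cortical depth, pooled over sessions.

    ``results[s]`` holds the per-unit index results of ``sessions[s]``.
    Electrode-wise averages (units, then sessions) are fit with a cubic in
    depth; the permutation null shuffles index values across units within
    session, destroying any index-depth relationship, and recomputes R^2
    ``n_permutations`` times.  Optionally rank-correlates per-electrode
    discrimination times with depth.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions with depth information")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # rows: (session, electrode, depth, index)
    rows = []
    for bundle, res in zip(sessions, results):
        unit_map = {u.unit_id: u for u in bundle.units}
        for r in res:
            if math.isfinite(r.index_r):
                u = unit_map[r.unit_id]
                rows.append((bundle.session_id, u.electrode_index, u.depth_mm, r.index_r))
    if not rows:
        raise ValueError("no finite index values")
    sess = np.array([r[0] for r in rows])
    elec = np.array([r[1] for r in rows])
    depth = np.array([r[2] for r in rows])
    index = np.array([r[3] for r in rows])

    def electrode_profile(idx_vals: np.ndarray):
        electrodes = np.unique(elec)
        means, depths = [], []
        for e in electrodes:
            per_session = []
            for s in np.unique(sess):
                m = (elec == e) & (sess == s)
                if m.any():
                    per_session.append(idx_vals[m].mean())
            means.append(np.mean(per_session))
            depths.append(depth[elec == e].mean())
        return np.asarray(depths), np.asarray(means)

    def cubic_r2(x: np.ndarray, y: np.ndarray):
        if np.ptp(x) == 0:
            raise ValueError("all depths equal; fit skipped")
        coeffs = np.polyfit(x, y, 3)
        fitted = np.polyval(coeffs, x)
        ss_res = np.sum((y - fitted) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        return coeffs, 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    depths, means = electrode_profile(index)
    coeffs, r2 = cubic_r2(depths, means)

    null = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = index.copy()
        for s in np.unique(sess):
            m = sess == s
            perm[m] = rng.permutation(perm[m])
        _, null[k] = cubic_r2(*electrode_profile(perm))
    perm_p = float((1 + np.sum(null >= r2)) / (n_permutations + 1))

    sp_r = sp_p = math.nan
    if discrimination_times is not None:
        ok = np.isfinite(discrimination_times)
        if ok.sum() >= 3:
            res = stats.spearmanr(depths[ok], np.asarray(discrimination_times)[ok])
            sp_r, sp_p = float(res.statistic), float(res.pvalue)

    return LaminarProfile(
        depths_mm=depths,
        mean_index=means,
        cubic_coeffs=coeffs,
        r_squared=float(r2),
        permutation_p=perm_p,
        discrimination_time_ms=discrimination_times,
        time_depth_spearman_r=sp_r,
        time_depth_spearman_p=sp_p,
    )


def pooled_gaussian_decode(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Linear Gaussian classifier, vectorized over time bins.

    ``X_*`` has shape (trials, features, bins); class-conditional means are
    Gaussian with a variance pooled across classes per feature (a
    naive-Bayes rule whose equal-covariance assumption makes the decision
    boundary linear).  Class priors are uniform so that chance performance
    stays at 50% under class imbalance.  Returns predicted labels
    (trials, bins).
    """
    classes = np.unique(y_train)
    assert classes.size == 2
    eps = 1e-9
    mus = []
    var = np.zeros(X_train.shape[1:])
    for c in classes:
        Xc = X_train[y_train == c]
        mus.append(Xc.mean(axis=0))
        var += (y_train == c).sum() * Xc.var(axis=0)
    var = var / len(y_train) + eps
    scores = [-0.5 * np.sum((X_test - mu) ** 2 / var, axis=1) for mu in mus]
    return classes[(scores[1] > scores[0]).astype(int)]


def _boxcar_counts(
    bundle: SessionBundle, unit_ids: Sequence[int], trials, time_axis: np.ndarray, bin_ms: int
) -> np.ndarray:
    """Spike counts in (t - bin_ms, t] per (trial, unit, time point), cue-aligned."""
    X = np.empty((len(trials), len(unit_ids), time_axis.size))
    for j, uid in enumerate(unit_ids):
        st = bundle.spike_times(uid)
        for i, tr in enumerate(trials):
            t_abs = tr.cue_on_ms + time_axis
            X[i, j] = np.searchsorted(st, t_abs, "right") - np.searchsorted(st, t_abs - bin_ms, "right")
    return X


def laminar_decode(
    bundle: SessionBundle,
    bin_ms: int = 50,
    step_ms: int = 2,
    t_range: tuple[int, int] = (-100, 500),
    folds: int = 10,
    equalization_repeats: int = 10,
    rng: np.random.Generator | int | None = None,
    rt_range: tuple[int, int] = (300, 1000),
) -> DecodingResult:
    """Cross-validated choice decoding from superficial vs deep unit pools.

    Same trials for both compartments (RTs restricted to 300-1000 ms); the
    larger pool is subsampled to the smaller's size ``equalization_repeats``
    times and accuracies averaged over folds and repeats.  Fold assignment
    is stratified by choice.  Sessions need more than 10 units; a
    compartment with no units raises.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(bundle.units) <= 10:
        raise ValueError("session has too few units for decoding (need > 10)")
    sup = [u.unit_id for u in bundle.units if u.electrode_index in SUPERFICIAL_ELECTRODES]
    deep = [u.unit_id for u in bundle.units if u.electrode_index in DEEP_ELECTRODES]
    if not sup or not deep:
        raise ValueError("a compartment has no units; session skipped")

    trials = [
        t
        for t in bundle.analysis_trials()
        if rt_range[0] <= t.rt_ms <= rt_range[1]
    ]
    y = np.array([t.choice for t in trials])
    time_axis = np.arange(t_range[0], t_range[1], step_ms)
    n_use = min(len(sup), len(deep))

    # stratified fold assignment
    fold_of = np.empty(len(trials), dtype=int)
    for c in (-1, 1):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % folds

    acc = {}
    for name, pool in (("sup", sup), ("deep", deep)):
        reps = equalization_repeats if len(pool) > n_use else 1
        rep_acc = np.zeros(time_axis.size)
        for _ in range(reps):
            chosen = list(rng.choice(pool, size=n_use, replace=False)) if len(pool) > n_use else pool
            X = _boxcar_counts(bundle, chosen, trials, time_axis, bin_ms)
            correct = np.zeros(time_axis.size)
            for f in range(folds):
                test = fold_of == f
                pred = pooled_gaussian_decode(X[~test], y[~test], X[test])
                correct += (pred == y[test, None]).sum(axis=0)
            rep_acc += correct / len(trials)
        acc[name] = rep_acc / reps

    return DecodingResult(
        session_id=bundle.session_id,
        time_axis=time_axis,
        accuracy_superficial=acc["sup"],
        accuracy_deep=acc["deep"],
        n_units_used=n_use,
    )


def _threshold_latency(
    time_axis: np.ndarray,
    accuracy: np.ndarray,
    threshold: float,
    min_run_bins: int,
    search_from: float = 0.0,
) -> float:
    """First post-cue time with accuracy above threshold for a sustained run.

    The search starts at ``search_from`` (cue onset by default: choice
    information cannot precede the stimulus, and the 50-ms feature window
    makes pre-cue noise excursions long-lived).
    """
    sel = time_axis >= search_from
    ta, above = time_axis[sel], accuracy[sel] > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run_bins:
            return float(ta[i - min_run_bins + 1])
    return math.nan


def decoding_latency_benefit(
    traces: Sequence[DecodingResult],
    threshold: float = 0.55,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = None,
    min_run_ms: int = 30,
) -> tuple[float, float, list[DecodingResult]]:
    """Superficial-vs-deep decoding latency benefit across sessions.

    Per session, the latency is the first time accuracy rises above
    ``threshold`` (sustained for ``min_run_ms`` to suppress single-bin
    noise crossings).  The benefit is the bootstrap mean (sessions
    resampled with replacement) of t_deep - t_superficial; p is the
    fraction of bootstrap benefits below zero.  Sessions whose trace never
    crosses are excluded and returned for inspection.
    """
    if len(traces) < 5:
        raise ValueError("need at least five sessions")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    diffs, excluded = [], []
    for tr in traces:
        step = int(tr.time_axis[1] - tr.time_axis[0])
        k = max(1, min_run_ms // step)
        tr.latency_superficial_ms = _threshold_latency(tr.time_axis, tr.accuracy_superficial, threshold, k)
        tr.latency_deep_ms = _threshold_latency(tr.time_axis, tr.accuracy_deep, threshold, k)
        if math.isfinite(tr.latency_superficial_ms) and math.isfinite(tr.latency_deep_ms):
            diffs.append(tr.latency_deep_ms - tr.latency_superficial_ms)
        else:
            excluded.append(tr)
    diffs = np.asarray(diffs)
    if diffs.size < 5:
        raise ValueError("fewer than five sessions with defined latencies")
    draws = diffs[rng.integers(0, diffs.size, size=(n_boot, diffs.size))].mean(axis=1)
    return float(draws.mean()), float(np.mean(draws < 0)), excluded
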