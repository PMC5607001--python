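"""Unsupervised population structure: PCA, loading-uniformity tests,
gap-statistic clustering, and the trial-alignment-offset RT correlation.

Firing-rate vectors (units x concatenated time-by-condition bins) are
"softmax" normalized -- each unit divided by its across-condition rate
range -- before principal component analysis, so high-rate units do not
dominate the covariance.  Whether loadings cluster or form a continuum is
tested two ways: a chi-square test of octant occupancy against uniformity
and the PAIRS nearest-neighbor-angle test against an isotropic Gaussian
null.  K-means cluster counts are selected with the gap statistic.

The alignment-offset method measures RT covariation without assuming a
response direction: each trial's rate is iteratively cross-correlated
with the leave-one-out trial average, the peak lag taken as the trial's
temporal offset, and the offsets correlated with RT (sign-corrected for
units whose perimovement rate sits below an early reference epoch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .rates import RateMatrix

__all__ = [
    "PopulationMatrix",
    "AlignmentResult",
    "build_population_matrix",
    "softmax_pca",
    "loading_uniformity_tests",
    "kmeans_with_gap",
    "trial_alignment_offsets",
    "offset_rt_correlation",
]


@dataclass
class PopulationMatrix:
    values: np.ndarray  # units x features, range-normalized
    unit_ids: np.ndarray
    ranges: np.ndarray  # per-unit normalization divisor
    dropped_units: list[int]  # constant (zero-range) rows removed


@dataclass
class AlignmentResult:
    unit_id: int
    offsets_ms: np.ndarray  # per-trial temporal offset
    n_iterations: int
    converged: bool
    rts: np.ndarray


def build_population_matrix(
    preferred_traces: Sequence[np.ndarray],
    nonpreferred_traces: Sequence[np.ndarray],
    unit_ids: Sequence[int] | None = None,
) -> PopulationMatrix:
    """Concatenate per-unit preferred/non-preferred mean traces and
    range-normalize each unit across all conditions."""
    rows = [np.concatenate([p, n]) for p, n in zip(preferred_traces, nonpreferred_traces)]
    X = np.vstack(rows)
    unit_ids = np.arange(X.shape[0]) if unit_ids is None else np.asarray(unit_ids)
    rng_ = np.nanmax(X, axis=1) - np.nanmin(X, axis=1)
    keep = rng_ > 0
    dropped = [int(u) for u in unit_ids[~keep]]
    X = X[keep] / rng_[keep, None]
    return PopulationMatrix(X, unit_ids[keep], rng_[keep], dropped)


def softmax_pca(matrix: PopulationMatrix, k: int):
    """PCA of the normalized population matrix.

    Returns ``(components, loadings, variance_fractions)`` where
    ``loadings`` are the per-unit scores on the first ``k`` axes and
    ``variance_fractions`` are all explained-variance ratios (summing
    to 1 over the full spectrum).
    """
    X = matrix.values
    if X.shape[0] < k:
        raise ValueError("need at least k units")
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    return pca.components_[:k], scores[:, :k], pca.explained_variance_ratio_


def loading_uniformity_tests(
    loadings: np.ndarray,
    k_neighbors: int = 3,
    n_null: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """Test 2-D PC loadings for angular structure.

    Returns ``(chi2_p, pairs_median_angle, pairs_p)``.  The chi-square test
    compares octant counts of the loading angles to uniform occupancy
    (skipped -> NaN below 40 units).  PAIRS computes, per unit, the mean
    angle to its ``k_neighbors`` angularly nearest neighbors; the median
    over units is compared two-sidedly to medians from ``n_null`` standard
    2-D Gaussian samples of equal size.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    L = np.asarray(loadings, dtype=float)[:, :2]
    n = L.shape[0]

    def octant_chi2_p(pts: np.ndarray) -> float:
        ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
        counts = np.histogram(ang, bins=np.linspace(0, 2 * np.pi, 9))[0]
        return float(stats.chisquare(counts).pvalue)

    chi2_p = octant_chi2_p(L) if n >= 40 else math.nan

    def pairs_stat(pts: np.ndarray) -> float:
        unit = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cos = np.clip(unit @ unit.T, -1.0, 1.0)
        ang = np.arccos(cos)
        np.fill_diagonal(ang, np.inf)
        nearest = np.sort(ang, axis=1)[:, :k_neighbors]
        return float(np.median(nearest.mean(axis=1)))

    observed = pairs_stat(L)
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = pairs_stat(rng.standard_normal((n, 2)))
    lo = np.mean(null <= observed)
    hi = np.mean(null >= observed)
    pairs_p = float(min(1.0, 2.0 * min(lo + 1.0 / n_null, hi + 1.0 / n_null)))
    return chi2_p, observed, pairs_p


def _gap_wk(X: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        mu = X.mean(axis=0)
        return float(np.sum((X - mu) ** 2))
    km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(X)
    return float(km.inertia_)


def kmeans_with_gap(
    X: np.ndarray,
    k_range: Sequence[int] = range(1, 7),
    B_reference: int = 50,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, np.ndarray]:
    """Choose the cluster count by the gap statistic and return labels.

    The reference null is uniform over the bounding box in the data's
    principal-axis rotation.  The chosen ``k`` is the smallest value whose
    gap is within one standard error of the maximum gap -- the first k at
    which the separation from the reference distribution has roughly
    saturated.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    ks = list(k_range)
    seed = int(rng.integers(0, 2**31 - 1))

    # reference draws: uniform box in the PCA rotation
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Z = Xc @ Vt.T
    lo, hi = Z.min(axis=0), Z.max(axis=0)

    log_wk = np.array([math.log(_gap_wk(X, k, seed)) for k in ks])
    log_wk_ref = np.empty((B_reference, len(ks)))
    for b in range(B_reference):
        Zb = rng.uniform(lo, hi, size=Z.shape)
        Xb = Zb @ Vt + mu
        log_wk_ref[b] = [math.log(_gap_wk(Xb, k, seed + b + 1)) for k in ks]
    gap = log_wk_ref.mean(axis=0) - log_wk
    s = log_wk_ref.std(axis=0, ddof=0) * math.sqrt(1.0 + 1.0 / B_reference)

    imax = int(np.argmax(gap))
    chosen = ks[imax]
    for i in range(imax):
        if gap[i] >= gap[imax] - s[imax]:
            chosen = ks[i]
            break
    if chosen == 1:
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        labels = KMeans(n_clusters=chosen, n_init=5, random_state=seed).fit_predict(X)
    return chosen, labels


def trial_alignment_offsets(
    matrix: RateMatrix,
    max_lag_ms: int = 300,
    variance_criterion: float = 0.01,
    max_iterations: int = 25,
    unit_id: int | None = None,
) -> AlignmentResult:
    """Iteratively align single trials to the trial-averaged rate.

    Each trial's (movement-aligned) rate is cross-correlated with the
    leave-one-out average; the peak lag within ``+-max_lag_ms`` becomes the
    trial's offset and the trial is shifted before the average is
    recomputed.  Iteration stops when the average's variance changes by
    less than ``variance_criterion`` (relative) or at the iteration cap.
    """
    vals = matrix.values
    n_tr, n_bins = vals.shape
    if n_tr < 30:
        raise ValueError("need at least 30 trials for alignment")
    filled = np.nan_to_num(vals - np.nanmean(vals))  # demean, mask -> 0
    lags = np.arange(-max_lag_ms, max_lag_ms + 1)
    offsets = np.zeros(n_tr, dtype=int)
    prev_var = None
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iterations + 1):
        shifted = np.empty_like(filled)
        for i in range(n_tr):
            shifted[i] = np.roll(filled[i], offsets[i])
        total = shifted.sum(axis=0)
        template_full = (total - shifted) / (n_tr - 1)  # leave-one-out templates

        # peak cross-correlation lag of each (unshifted) trial against its
        # leave-one-out template; cc(L) = sum_t trial[t] * template[t + L]
        new_off = np.empty(n_tr, dtype=int)
        for i in range(n_tr):
            cc_full = signal.correlate(filled[i], template_full[i], mode="full")
            cc = cc_full[n_bins - 1 - lags]
            new_off[i] = int(lags[np.argmax(cc)])
        offsets = new_off
        shifted = np.vstack([np.roll(filled[i], offsets[i]) for i in range(n_tr)])
        var = float(np.var(shifted.mean(axis=0)))
        if prev_var is not None and prev_var > 0 and abs(var - prev_var) / prev_var < variance_criterion:
            converged = True
            break
        prev_var = var

    return AlignmentResult(
        unit_id=matrix.unit_id if unit_id is None else unit_id,
        offsets_ms=offsets.astype(float),
        n_iterations=n_iter,
        converged=converged,
        rts=matrix.rts.astype(float),
    )


def offset_rt_correlation(
    result: AlignmentResult, matrix: RateMatrix
) -> tuple[float, float]:
    """Correlate alignment offsets with RT; sign-correct for decreased units.

    Returns ``(r, sign_corrected_r)``.  If the unit's rate in the 100 ms
    before movement is below its rate in the -800..-700 ms reference epoch
    (i.e., the unit decreased), the correlation's sign is flipped.
    """
    off, rt = result.offsets_ms, result.rts
    if np.ptp(off) == 0:
        return math.nan, math.nan
    r = float(np.corrcoef(off, rt)[0, 1])
    with np.errstate(invalid="ignore"):
        peri = np.nanmean(matrix.window_mean(-100, 0))
        ref = np.nanmean(matrix.window_mean(-800, -700))
    sign = -1.0 if (np.isfinite(peri) and np.isfinite(ref) and peri < ref) else 1.0
    return r, sign * r
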