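"""Trial-wise rate regression: are choice/RT effects kinematic artifacts?

At each time bin the single-trial firing rate is regressed on task
predictors (coherence, choice, chosen color, RT, the RT x coherence and
RT x choice interactions) and nuisance kinematic predictors (hand and eye
position at that bin, hand speed).  All predictors are z-scored before
fitting, so coefficients are comparable across predictors; 95% confidence
intervals at each bin flag significant coefficients, and counting
significant units per bin against the 5% binomial chance band shows
whether task coefficients outlast the kinematic ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .rates import RateMatrix
from .session_io import TrialRecord

__all__ = ["RegressionFit", "PREDICTORS", "fit_trialwise_regression", "significant_predictor_counts"]

PREDICTORS = [
    "coherence",
    "choice",
    "chosen_color",
    "rt",
    "hand_x",
    "hand_y",
    "eye_x",
    "eye_y",
    "hand_speed",
    "rt_x_coherence",
    "rt_x_choice",
]


@dataclass
class RegressionFit:
    unit_id: int
    time_axis: np.ndarray  # bin centers, alignment of the input rates
    predictors: list[str]  # columns actually fitted (constant excluded)
    beta: np.ndarray  # (bins, predictors)
    ci_low: np.ndarray
    ci_high: np.ndarray
    intercept: np.ndarray
    dropped: list[str]  # zero-variance predictors removed
    condition_warning: bool  # design matrix condition number > 1e4 at any bin


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _trace_at(trial: TrialRecord, name: str, t_abs: float) -> float:
    arr = getattr(trial, name)
    if arr is None or trial.kin_t_ms is None:
        return math.nan
    return float(np.interp(t_abs, trial.kin_t_ms, arr))


def fit_trialwise_regression(
    matrix: RateMatrix,
    trials: Sequence[TrialRecord],
    step_ms: int = 25,
) -> RegressionFit:
    """Per-bin OLS of single-trial rate on z-scored task + kinematic predictors.

    ``matrix`` should be movement-aligned 50-ms-boxcar rates; ``trials``
    must carry kinematic traces (synthetic ones suffice).  Bins are taken
    every ``step_ms`` along the matrix's time axis.  Requires at least ten
    trials per predictor; zero-variance predictors are dropped and
    reported.
    """
    by_id = {t.trial_id: t for t in trials}
    use = [by_id[tid] for tid in matrix.trial_ids]
    n = len(use)
    if n < 10 * len(PREDICTORS):
        raise ValueError(f"need >= {10 * len(PREDICTORS)} trials for {len(PREDICTORS)} predictors")

    coh = np.array([t.coherence_C for t in use])
    choice = np.array([t.choice for t in use], dtype=float)
    color = np.array([t.chosen_color for t in use], dtype=float)
    rt = np.array([t.rt_ms for t in use], dtype=float)
    speed = np.array([t.hand_speed for t in use])

    bins = matrix.time_axis[:: max(1, step_ms)]
    static = {
        "coherence": coh,
        "choice": choice,
        "chosen_color": color,
        "rt": rt,
        "hand_speed": speed,
        "rt_x_coherence": rt * coh,
        "rt_x_choice": rt * choice,
    }

    kept = list(PREDICTORS)
    dropped = []
    for name in list(static):
        if np.ptp(static[name]) == 0:
            kept.remove(name)
            dropped.append(name)

    beta = np.full((bins.size, len(kept)), np.nan)
    lo = np.full_like(beta, np.nan)
    hi = np.full_like(beta, np.nan)
    intercept = np.full(bins.size, np.nan)
    cond_warn = False

    anchor = "move_on_ms" if matrix.alignment == "move" else "cue_on_ms"
    for b, t_rel in enumerate(bins):
        cols = []
        names_b = []
        for name in kept:
            if name in static:
                x = static[name]
            else:
                x = np.array([_trace_at(tr, name, getattr(tr, anchor) + t_rel) for tr in use])
            if not np.all(np.isfinite(x)) or np.ptp(x) == 0:
                continue
            cols.append(_zscore(x))
            names_b.append(name)
        y = matrix.values[:, matrix.time_axis == t_rel].ravel()
        ok = np.isfinite(y)
        if ok.sum() < 10 * len(names_b):
            continue
        X = sm.add_constant(np.column_stack(cols)[ok])
        if np.linalg.cond(X) > 1e4:
            cond_warn = True
        res = sm.OLS(y[ok], X).fit()
        ci = res.conf_int(alpha=0.05)
        intercept[b] = res.params[0]
        for j, name in enumerate(names_b):
            col = kept.index(name)
            beta[b, col] = res.params[j + 1]
            lo[b, col] = ci[j + 1, 0]
            hi[b, col] = ci[j + 1, 1]

    return RegressionFit(
        unit_id=matrix.unit_id,
        time_axis=bins,
        predictors=kept,
        beta=beta,
        ci_low=lo,
        ci_high=hi,
        intercept=intercept,
        dropped=dropped,
        condition_warning=cond_warn,
    )


def significant_predictor_counts(fits: Sequence[RegressionFit]):
    """Per-bin counts of units whose 95% CI excludes zero, per predictor.

    Returns ``(time_axis, counts, fractions, n_units)`` with ``counts`` a
    dict predictor -> array over bins.  The 5% binomial band is the chance
    reference.  Requires at least ten units.
    """
    if len(fits) < 10:
        raise ValueError("need at least ten units")
    time_axis = fits[0].time_axis
    counts: dict[str, np.ndarray] = {}
    denom: dict[str, np.ndarray] = {}
    for f in fits:
        for j, name in enumerate(f.predictors):
            sig = (f.ci_low[:, j] > 0) | (f.ci_high[:, j] < 0)
            fin = np.isfinite(f.ci_low[:, j])
            counts[name] = counts.get(name, np.zeros(time_axis.size)) + np.where(fin, sig, 0)
            denom[name] = denom.get(name, np.zeros(time_axis.size)) + fin
    fractions = {
        k: np.divide(counts[k], denom[k], out=np.full(time_axis.size, np.nan), where=denom[k] > 0)
        for k in counts
    }
    return time_axis, counts, fractions, len(fits)
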