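"""Psychometric and chronometric characterization of a session.

Accuracy versus coherence is fit with a cumulative Weibull,

    p(c) = 1 - 0.5 exp(-(c / alpha)^gamma),

whose threshold ``alpha`` is the coherence at 81.6% correct and whose
``gamma`` sets the slope.  Mean reaction time is regressed on the natural
log of coherence, RT(c) = intercept + a_c * ln(c), with a negative slope
``a_c`` expected when harder stimuli slow the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .session_io import TrialRecord

__all__ = [
    "PsychometricFit",
    "ChronometricFit",
    "checkerboard_coherence",
    "weibull_probability",
    "fit_psychometric",
    "fit_chronometric",
]


@dataclass
class PsychometricFit:
    alpha: float  # % coherence at 81.6% correct
    gamma: float  # slope
    r_squared: float
    boundary: bool = False  # all-correct / all-error data, fit pinned at a bound

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class ChronometricFit:
    intercept_ms: float
    slope_ac: float  # ms per ln(% coherence)
    r_squared: float


def checkerboard_coherence(n_red: int, n_green: int) -> tuple[float, float]:
    """Coherence C = 100|R-G|/(R+G) and signed coherence SC = 100(R-G)/(R+G).

    Positive SC means more red squares.
    """
    total = n_red + n_green
    if total <= 0:
        raise ValueError("checkerboard must contain at least one square")
    sc = 100.0 * (n_red - n_green) / total
    return abs(sc), sc


def weibull_probability(c: float | np.ndarray, fit: PsychometricFit) -> float | np.ndarray:
    """Probability correct at coherence ``c`` (percent) under the fitted Weibull."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("coherence must be non-negative")
    out = 1.0 - 0.5 * np.exp(-((c / fit.alpha) ** fit.gamma))
    return float(out) if out.ndim == 0 else out


def _per_level(trials: Sequence[TrialRecord]):
    trials = [t for t in trials if not t.change_of_mind]
    levels = sorted({t.coherence_C for t in trials})
    c = np.array(levels)
    p = np.array([np.mean([t.correct for t in trials if t.coherence_C == lv]) for lv in levels])
    n = np.array([sum(t.coherence_C == lv for t in trials) for lv in levels], dtype=float)
    rt = np.array([np.mean([t.rt_ms for t in trials if t.coherence_C == lv]) for lv in levels])
    return c, p, n, rt


def fit_psychometric(trials: Sequence[TrialRecord]) -> PsychometricFit:
    """Weighted least-squares Weibull fit to per-level proportions correct.

    Levels are weighted by their trial counts.  A multi-start over gamma
    guards against local minima.  Requires at least two coherence levels.
    """
    c, p, n, _ = _per_level(trials)
    if c.size < 2:
        raise ValueError("need at least two coherence levels")
    w = np.sqrt(n / n.sum())

    def resid(theta):
        alpha, gamma = theta
        return w * (p - (1.0 - 0.5 * np.exp(-((c / alpha) ** gamma))))

    best = None
    alpha0 = float(np.median(c[c > 0])) if np.any(c > 0) else 10.0
    for g0 in (0.5, 1.0, 2.0, 4.0):
        try:
            sol = optimize.least_squares(
                resid, x0=[alpha0, g0], bounds=([1e-3, 1e-2], [500.0, 20.0])
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    alpha, gamma = best.x
    fitted = 1.0 - 0.5 * np.exp(-((c / alpha) ** gamma))
    ss_res = float(np.sum((w * (p - fitted)) ** 2))
    ss_tot = float(np.sum((w * (p - np.average(p, weights=w**2))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    boundary = bool(np.all(p >= 1.0 - 1e-12) or np.all(p <= 0.5 + 1e-12))
    return PsychometricFit(alpha=float(alpha), gamma=float(gamma), r_squared=r2, boundary=boundary)


def fit_chronometric(trials: Sequence[TrialRecord]) -> ChronometricFit:
    """OLS of per-level mean RT (correct and error trials) on ln coherence."""
    c, _, _, rt = _per_level(trials)
    pos = c > 0
    if np.sum(pos) < 2:
        raise ValueError("need at least two nonzero coherence levels")
    res = stats.linregress(np.log(c[pos]), rt[pos])
    return ChronometricFit(
        intercept_ms=float(res.intercept),
        slope_ac=float(res.slope),
        r_squared=float(res.rvalue**2),
    )
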