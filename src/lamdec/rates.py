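"""Masked, aligned, boxcar-smoothed firing-rate matrices and PSTHs/PMTHs.

Spike trains are binned at 1 ms and convolved with a *causal* boxcar: the
rate at time ``t`` is ``(1000 / w) x (#spikes in the half-open window
(t - w, t])``, so a spike influences only bins at or after its own time.
The boxcar is 75 ms for single-unit displays and 50 ms for population
analyses.

Masking conventions (cells set to NaN and excluded from every average):

* cue-aligned: spikes from 100 ms before movement onward are removed and
  bins at ``t >= rt - 100`` are masked, so perimovement activity cannot
  leak into stimulus-aligned averages;
* movement-aligned: spikes before cue onset are removed and bins at
  ``t < -rt`` are masked.

Change-of-mind trials are dropped before any averaging.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .session_io import TrialRecord

__all__ = ["RateMatrix", "PSTH", "smoothed_rates", "condition_psth", "overlapping_rt_bins"]

DEFAULT_WINDOWS = {"cue": (-700, 1000), "move": (-1000, 300)}


@dataclass
class RateMatrix:
    """Trials x 1-ms-bin firing rates (Hz) for one unit, NaN where masked."""

    unit_id: int
    alignment: str  # "cue" | "move"
    time_axis: np.ndarray  # int ms relative to the alignment event
    values: np.ndarray  # (n_trials, n_bins), NaN = masked
    boxcar_ms: int
    trial_ids: np.ndarray
    rts: np.ndarray
    coherences: np.ndarray
    choices: np.ndarray

    def window_mean(self, t0: int, t1: int) -> np.ndarray:
        """Per-trial mean rate over [t0, t1), NaN-aware."""
        sel = (self.time_axis >= t0) & (self.time_axis < t1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values[:, sel], axis=1)


@dataclass
class PSTH:
    label: dict
    time_axis: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # unmasked trial count per bin


def smoothed_rates(
    spike_times: np.ndarray,
    trials: Sequence[TrialRecord],
    alignment: str = "cue",
    boxcar_ms: int = 50,
    window: tuple[int, int] | None = None,
    unit_id: int = -1,
    drop_change_of_mind: bool = True,
) -> RateMatrix:
    """Build the masked rate matrix of one unit.

    ``spike_times`` are sorted session-clock times (ms).  Trials lacking
    the alignment event are dropped.
    """
    if boxcar_ms <= 0:
        raise ValueError("boxcar_ms must be positive")
    if alignment not in ("cue", "move"):
        raise ValueError("alignment must be 'cue' or 'move'")
    t0, t1 = window if window is not None else DEFAULT_WINDOWS[alignment]
    time_axis = np.arange(t0, t1, dtype=np.int64)
    spike_times = np.asarray(spike_times, dtype=np.int64)

    use = [t for t in trials if not (drop_change_of_mind and t.change_of_mind)]
    values = np.full((len(use), time_axis.size), np.nan)
    w = boxcar_ms
    for i, tr in enumerate(use):
        anchor = tr.cue_on_ms if alignment == "cue" else tr.move_on_ms
        rel = spike_times - anchor
        if alignment == "cue":
            rel = rel[rel < tr.rt_ms - 100]  # strip perimovement spikes
        else:
            rel = rel[rel >= -tr.rt_ms]  # strip pre-cue spikes
        # causal boxcar: count spikes in (t-w, t]
        hi = np.searchsorted(rel, time_axis, side="right")
        lo = np.searchsorted(rel, time_axis - w, side="right")
        values[i] = (1000.0 / w) * (hi - lo)
        if alignment == "cue":
            values[i, time_axis >= tr.rt_ms - 100] = np.nan
        else:
            values[i, time_axis < -tr.rt_ms] = np.nan

    return RateMatrix(
        unit_id=unit_id,
        alignment=alignment,
        time_axis=time_axis,
        values=values,
        boxcar_ms=boxcar_ms,
        trial_ids=np.array([t.trial_id for t in use], dtype=np.int64),
        rts=np.array([t.rt_ms for t in use], dtype=np.int64),
        coherences=np.array([t.coherence_C for t in use]),
        choices=np.array([t.choice for t in use], dtype=np.int64),
    )


def overlapping_rt_bins() -> list[tuple[int, int]]:
    """The overlapping RT bins used to sort trials: 325-425, 350-450, ...
    stepped by 25 ms, plus a final broad 500-1000 ms bin."""
    bins = [(s, s + 100) for s in range(325, 500, 25)]
    bins.append((500, 1000))
    return bins


def condition_psth(
    matrix: RateMatrix,
    grouping: str = "coherence",
    rt_bins: Sequence[tuple[int, int]] | None = None,
    truncate_at_median_rt: bool = True,
) -> list[PSTH]:
    """Condition-averaged PSTHs from a rate matrix.

    ``grouping`` is ``"coherence"`` (coherence x choice) or ``"rt"``
    (overlapping RT bin x choice; a trial may enter several bins).  When
    cue-aligned, each condition's mean is truncated (NaN) beyond that
    condition's median RT.  Empty conditions are omitted.
    """
    if grouping not in ("coherence", "rt"):
        raise ValueError("grouping must be 'coherence' or 'rt'")
    out: list[PSTH] = []
    if grouping == "coherence":
        conditions = [
            ({"coherence": c, "choice": ch}, (matrix.coherences == c) & (matrix.choices == ch))
            for c in np.unique(matrix.coherences)
            for ch in (-1, 1)
        ]
    else:
        rt_bins = overlapping_rt_bins() if rt_bins is None else rt_bins
        conditions = [
            (
                {"rt_bin": (lo, hi), "choice": ch},
                (matrix.rts >= lo) & (matrix.rts < hi) & (matrix.choices == ch),
            )
            for lo, hi in rt_bins
            for ch in (-1, 1)
        ]
    for label, sel in conditions:
        if not np.any(sel):
            continue
        vals = matrix.values[sel]
        n = np.sum(~np.isnan(vals), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(vals, axis=0)
            sd = np.nanstd(vals, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        if truncate_at_median_rt and matrix.alignment == "cue":
            med = np.median(matrix.rts[sel])
            cut = matrix.time_axis > med
            mean = np.where(cut, np.nan, mean)
            sem = np.where(cut, np.nan, sem)
        out.append(PSTH(label=label, time_axis=matrix.time_axis, mean=mean, sem=sem, n=n))
    return out
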