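"""Shared test constructions: direct-from-intensity rate matrices.

Building ``RateMatrix`` objects straight from Poisson counts (or
deterministic intensities) isolates the estimator under test from the
session generator, and gives exact control over onsets, selectivity
magnitudes, and masking.
"""

from __future__ import annotations

import numpy as np

from lamdec.rates import RateMatrix

COHERENCE_LEVELS = (4.0, 12.0, 23.6, 38.7, 57.3, 76.9, 90.2)


def boxcar_causal(counts: np.ndarray, w: int) -> np.ndarray:
    """Causal boxcar rate from 1-ms counts: (1000/w) x counts in (t-w, t]."""
    c = np.cumsum(counts, axis=-1)
    out = np.empty(counts.shape, dtype=float)
    out[..., :w] = c[..., :w]
    out[..., w:] = c[..., w:] - c[..., :-w]
    return out * (1000.0 / w)


def make_matrices(
    rng: np.random.Generator,
    n_units: int = 30,
    n_trials: int = 120,
    base_hz: float = 20.0,
    step_hz: float = 0.0,
    onset_ms: int = 150,
    ramp_hz_s_per_coh: float = 0.0,
    coh_levels: tuple[float, ...] = (90.2,),
    t_range: tuple[int, int] = (-600, 600),
    boxcar_ms: int = 50,
    rt_ms: int = 900,
    poisson: bool = True,
) -> list[RateMatrix]:
    """Cue-aligned matrices with a choice-selective step and/or ramp.

    Right-choice (+1) trials gain ``step_hz`` plus a ramp of
    ``ramp_hz_s_per_coh x C/100`` Hz/s from ``onset_ms``.  With
    ``poisson=False`` the intensity itself is stored (noise-free).
    RTs are uniform at ``rt_ms`` so no masking occurs inside the window.
    """
    t_axis = np.arange(*t_range)
    post = np.clip((t_axis - onset_ms) / 1000.0, 0.0, None)
    step_on = (t_axis >= onset_ms).astype(float)
    mats = []
    for u in range(n_units):
        coh = np.array(coh_levels)[rng.integers(0, len(coh_levels), n_trials)]
        choices = np.where(rng.random(n_trials) < 0.5, -1, 1)
        lam = np.full((n_trials, t_axis.size), base_hz)
        right = choices == 1
        lam[right] += step_hz * step_on + ramp_hz_s_per_coh * (coh[right, None] / 100.0) * post
        if poisson:
            vals = boxcar_causal(rng.poisson(lam / 1000.0), boxcar_ms)
        else:
            vals = lam.copy()
        mats.append(
            RateMatrix(
                unit_id=u,
                alignment="cue",
                time_axis=t_axis,
                values=vals,
                boxcar_ms=boxcar_ms,
                trial_ids=np.arange(n_trials),
                rts=np.full(n_trials, rt_ms),
                coherences=coh,
                choices=choices,
            )
        )
    return mats
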