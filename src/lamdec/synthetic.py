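"""Synthetic-session generator with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes of a premotor-cortex reaction-time discrimination session:

* **Behavior** comes from a drift-diffusion model (DDM).  A decision
  variable ``V`` follows ``dV = mu dt + dW`` (unit-variance noise per
  second, Euler step 1 ms) between absorbing bounds at ``A`` (red choice)
  and 0 (green choice); drift is signed by the signed coherence of the
  checkerboard cue.  Reaction time is the first-passage time plus a
  Gaussian non-decision time.  This yields Weibull-shaped accuracy versus
  coherence and mean RT decreasing with log coherence.

* **Firing rates** follow three archetypes.  *Increased* units ramp up
  from baseline starting ~150 ms after cue onset; *decreased* units ramp
  down; *perimovement* units are flat until a burst ~150 ms before
  movement.  The ramp has two parts: a coherence-independent visuomotor
  ramp (``rt_ramp_hz_s``, sign defines the archetype) whose pre-movement
  average therefore covaries with RT -- the quantity the visuomotor index
  measures -- and a choice-selective ramp whose slope grows in proportion
  to coherence (``choice_ramp_hz_s_per_coh``), which gives the
  characteristic coherence-dependent build-up of choice selectivity.
  Decreased and perimovement units express choice only as a constant
  firing-rate difference in the last 100 ms before movement.

* **Spikes** are drawn from an inhomogeneous Poisson process by thinning.
  :func:`generate_session` additionally imposes a short dead time so that
  synthetic well-isolated units satisfy the <1.5% ISI-violation criterion.

Archetype prevalence varies with cortical depth (increased units enriched
superficially), matching the laminar organization the depth analyses are
designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .session_io import (
    SessionBundle,
    SpikeRecord,
    TrialRecord,
    UnitRecord,
    classify_isolation,
)

__all__ = [
    "DDMParams",
    "ArchetypeSpec",
    "GeneratorConfig",
    "RateProfile",
    "default_depth_rule",
    "simulate_behavior",
    "simulate_ddm_trials",
    "rate_profile",
    "simulate_spike_trains",
    "generate_session",
]

#: the seven coherence levels of the default stimulus set, from red square
#: counts {117,126,139,156,177,199,214} on a 225-square board
DEFAULT_COHERENCES = tuple(100.0 * abs(2 * r - 225) / 225 for r in (117, 126, 139, 156, 177, 199, 214))

ARCHETYPES = ("increased", "decreased", "perimovement")


@dataclass
class DDMParams:
    """Forward drift-diffusion parameters.

    ``drift_per_coherence`` maps coherence (percent) to the unsigned drift
    magnitude mu (evidence units / s); at simulation time the drift takes
    the sign of the trial's signed coherence.  Bounds are at ``bound_A``
    (red) and 0 (green) with starting point ``start_z``; ``drift_sd_sv`` is
    trial-to-trial drift variability, ``ndt_t0_ms``/``ndt_sd_st0_ms`` the
    non-decision time mean/SD and ``d_ms`` a constant non-decision-time
    shift applied to red choices.
    """

    drift_per_coherence: Mapping[float, float]
    bound_A: float = 1.0
    start_z: float = 0.5
    drift_sd_sv: float = 0.5
    ndt_t0_ms: float = 300.0
    ndt_sd_st0_ms: float = 40.0
    d_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.start_z < self.bound_A:
            raise ValueError("require 0 < start_z < bound_A")
        if self.ndt_t0_ms < 0:
            raise ValueError("require ndt_t0_ms >= 0")

    @classmethod
    def default(cls, coherences: Sequence[float] = DEFAULT_COHERENCES, gain: float = 12.0) -> "DDMParams":
        """Drift proportional to coherence: mu(C) = gain * C / 100.

        The default gain puts the synthetic discrimination threshold near
        12% coherence, a realistic value for this task.
        """
        return cls(drift_per_coherence={c: gain * c / 100.0 for c in coherences})


@dataclass
class ArchetypeSpec:
    """Rate-profile parameters for one firing-rate archetype.

    ``rt_ramp_hz_s`` is the coherence-independent ramp slope (Hz/s) whose
    sign defines the archetype (+ increased, - decreased, 0 perimovement);
    ``choice_ramp_hz_s_per_coh`` is the choice-selectivity ramp slope per
    100% coherence (the preferred direction gains half of it, the
    non-preferred loses half); ``choice_gain_hz`` is the constant
    preferred-vs-non-preferred difference switched on ``choice_onset_ms``
    before movement (used by decreased/perimovement archetypes).
    """

    archetype: str
    baseline_hz: float
    cue_latency_ms: float = 150.0
    rt_ramp_hz_s: float = 0.0
    choice_ramp_hz_s_per_coh: float = 0.0
    perimovement_burst_hz: float = 0.0
    burst_onset_ms: float = -150.0
    choice_gain_hz: float = 0.0
    choice_onset_ms: float = -100.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be >= 0")

    @classmethod
    def default(cls, archetype: str) -> "ArchetypeSpec":
        if archetype == "increased":
            return cls("increased", baseline_hz=15.0, rt_ramp_hz_s=65.0,
                       choice_ramp_hz_s_per_coh=50.0)
        if archetype == "decreased":
            return cls("decreased", baseline_hz=38.0, rt_ramp_hz_s=-95.0,
                       choice_gain_hz=10.0)
        return cls("perimovement", baseline_hz=10.0, perimovement_burst_hz=25.0,
                   choice_gain_hz=10.0)


def default_depth_rule(electrode_index: int) -> dict[str, float]:
    """Archetype probabilities at one electrode (1 superficial .. 16 deep).

    Linearly interpolates from an increased-enriched superficial mix to a
    perimovement/decreased-enriched deep mix.
    """
    f = (electrode_index - 1) / 15.0
    sup = np.array([0.72, 0.08, 0.20])
    deep = np.array([0.18, 0.32, 0.50])
    p = (1 - f) * sup + f * deep
    p = p / p.sum()
    return dict(zip(ARCHETYPES, p))


@dataclass
class GeneratorConfig:
    """Study conditions of a synthetic session."""

    n_trials: int = 400
    coherence_levels: Sequence[float] = DEFAULT_COHERENCES
    units_per_archetype: tuple[int, int, int] = (8, 2, 6)  # increased, decreased, perimovement
    depth_rule: Callable[[int], Mapping[str, float]] | None = None
    seed: int = 0
    hold_period_distribution: str = "uniform"  # "uniform" (400-900) or "truncexp" (400-800)
    change_of_mind_rate: float = 0.025
    refractory_ms: float = 3.0
    insertion_depth_mm: float = 0.3
    electrode_spacing_mm: float = 0.15
    deep_extra_latency_ms: float = 0.0  # added cue latency for electrodes 9-16
    archetype_overrides: Mapping[str, ArchetypeSpec] | None = None
    inter_trial_ms: int = 1500
    max_decision_ms: int = 5000

    def __post_init__(self) -> None:
        rule = self.depth_rule or default_depth_rule
        for e in (1, 8, 16):
            p = rule(e)
            if not math.isclose(sum(p.values()), 1.0, abs_tol=1e-9):
                raise ValueError("depth_rule probabilities must sum to 1 at every depth")


# ------------------------------------------------------------------ behavior

def simulate_ddm_trials(
    mu: np.ndarray,
    bound_A: float,
    start_z: float,
    rng: np.random.Generator,
    dt_ms: float = 1.0,
    max_ms: int = 5000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Euler-Maruyama first-passage simulation of ``dV = mu dt + dW``.

    One path per entry of ``mu``.  Returns ``(hit_upper, decision_ms,
    n_resampled)`` where ``hit_upper`` is True when the path absorbed at
    ``bound_A`` (red) and ``decision_ms`` is the absorption time.  Paths not
    absorbed within ``max_ms`` are resampled and counted.

    Between Euler points the path is a Brownian bridge, so each step also
    crosses an unreached bound with probability
    ``exp(-2 (b - v0)(b - v1) / dt)``; sampling these events removes the
    discretization bias that otherwise inflates absorption probabilities.
    """
    mu = np.asarray(mu, dtype=float)
    n = mu.size
    dt = dt_ms / 1000.0
    sq = math.sqrt(dt)
    hit_upper = np.zeros(n, dtype=bool)
    decision = np.zeros(n, dtype=np.int64)
    n_resampled = 0
    chunk = 512
    for i in range(n):
        while True:  # resample loop for the (rare) non-absorbing path
            v = start_z
            t = 0
            done = False
            while t < max_ms:
                m = min(chunk, max_ms - t)
                path = v + np.cumsum(mu[i] * dt + sq * rng.standard_normal(m))
                v0 = np.concatenate(([v], path[:-1]))
                v1 = path
                with np.errstate(over="ignore"):
                    p_up = np.exp(-2.0 * np.maximum(bound_A - v0, 0) * np.maximum(bound_A - v1, 0) / dt)
                    p_dn = np.exp(-2.0 * np.maximum(v0, 0) * np.maximum(v1, 0) / dt)
                up = (v1 >= bound_A) | (rng.random(m) < p_up)
                dn = (v1 <= 0.0) | (rng.random(m) < p_dn)
                crossed = up | dn
                if crossed.any():
                    j = int(np.argmax(crossed))
                    if up[j] and dn[j]:  # both bridges fired in one step: pick by odds
                        hit_upper[i] = bool(rng.random() < p_up[j] / (p_up[j] + p_dn[j]))
                    else:
                        hit_upper[i] = bool(up[j])
                    decision[i] = t + j + 1
                    done = True
                    break
                v = path[-1]
                t += m
            if done:
                break
            n_resampled += 1
    return hit_upper, decision, n_resampled


def _hold_durations(config: GeneratorConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.hold_period_distribution == "uniform":
        return rng.integers(400, 901, size=n)
    if config.hold_period_distribution == "truncexp":
        tau = 150.0
        u = rng.random(n)
        x = -tau * np.log1p(-u * (1.0 - math.exp(-400.0 / tau)))
        return (400.0 + x).astype(np.int64)
    raise ValueError(f"unknown hold_period_distribution {config.hold_period_distribution!r}")


def simulate_behavior(
    ddm: DDMParams,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate one session of behavior: choices, RTs, and event times.

    Coherence level, dominant color, and target configuration (which side
    is red) are randomized independently per trial.  ``correct`` is True
    when the chosen color matches the sign of the signed coherence.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_trials
    levels = np.asarray(list(config.coherence_levels), dtype=float)
    c = levels[rng.integers(0, levels.size, size=n)]
    color_sign = np.where(rng.random(n) < 0.5, 1, -1)  # +1 = more red
    sc = color_sign * c
    red_on_right = np.where(rng.random(n) < 0.5, 1, -1)

    mu0 = np.array([ddm.drift_per_coherence[v] for v in c])
    mu = color_sign * (mu0 + ddm.drift_sd_sv * rng.standard_normal(n))
    hit_red, decision_ms, _ = simulate_ddm_trials(
        mu, ddm.bound_A, ddm.start_z, rng, max_ms=config.max_decision_ms
    )

    ndt = ddm.ndt_t0_ms + ddm.ndt_sd_st0_ms * rng.standard_normal(n)
    ndt = np.maximum(ndt + np.where(hit_red, ddm.d_ms, 0.0), 50.0)
    rt = decision_ms + np.round(ndt).astype(np.int64)

    holds = _hold_durations(config, rng, n)
    trials: list[TrialRecord] = []
    clock = 0
    for i in range(n):
        chosen_color = 1 if hit_red[i] else -1
        choice = chosen_color * red_on_right[i]
        target_on = clock
        cue_on = target_on + int(holds[i])
        move_on = cue_on + int(rt[i])
        trials.append(
            TrialRecord(
                trial_id=i,
                coherence_C=float(c[i]),
                signed_coherence_SC=float(sc[i]),
                choice=int(choice),
                chosen_color=int(chosen_color),
                correct=bool(chosen_color == (1 if sc[i] > 0 else -1)),
                target_on_ms=target_on,
                cue_on_ms=cue_on,
                move_on_ms=move_on,
                rt_ms=int(rt[i]),
            )
        )
        clock = move_on + config.inter_trial_ms
    return trials


# --------------------------------------------------------------------- rates

class RateProfile:
    """Piecewise firing-rate intensity ``lambda(t)`` for one unit on one trial.

    Callable on session-clock times (ms, scalar or array); ``max_rate``
    bounds the intensity over the trial span, as required for thinning.
    """

    def __init__(self, spec: ArchetypeSpec, trial: TrialRecord, preferred: int):
        self.spec = spec
        self.trial = trial
        self.preferred = int(preferred)
        self.span = (trial.cue_on_ms - 900, trial.move_on_ms + 250)
        self.max_rate = float(np.max(self(np.arange(self.span[0], self.span[1], 5.0))))

    def __call__(self, t_ms: np.ndarray | float) -> np.ndarray:
        s = self.spec
        tr = self.trial
        t = np.asarray(t_ms, dtype=float)
        sign = 1.0 if tr.choice == self.preferred else -1.0
        dt_s = np.clip((t - tr.cue_on_ms - s.cue_latency_ms) / 1000.0, 0.0, None)
        rate = s.baseline_hz + s.rt_ramp_hz_s * dt_s
        rate = rate + sign * 0.5 * s.choice_ramp_hz_s_per_coh * (tr.coherence_C / 100.0) * dt_s
        if s.perimovement_burst_hz:
            rate = rate + s.perimovement_burst_hz * (t >= tr.move_on_ms + s.burst_onset_ms)
        if s.choice_gain_hz:
            rate = rate + sign * 0.5 * s.choice_gain_hz * (t >= tr.move_on_ms + s.choice_onset_ms)
        return np.clip(rate, 0.0, None)


def rate_profile(spec: ArchetypeSpec, trial: TrialRecord, preferred: int) -> RateProfile:
    """Intensity function for ``trial`` given the unit's preferred direction."""
    return RateProfile(spec, trial, preferred)


def simulate_spike_trains(
    profiles: Mapping[int, Sequence[RateProfile]],
    trials: Sequence[TrialRecord],
    seed: int | np.random.Generator = 0,
) -> list[SpikeRecord]:
    """Draw spikes for every (unit, trial) profile by Poisson thinning.

    ``profiles[unit_id][k]`` is the intensity on ``trials[k]``.  Spike
    times are rounded to integer ms on the session clock.  Reproducible
    given the seed; raises if an intensity is unbounded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spikes: list[SpikeRecord] = []
    for unit_id in sorted(profiles):
        times: list[np.ndarray] = []
        for prof in profiles[unit_id]:
            lam_max = prof.max_rate
            if not np.isfinite(lam_max):
                raise ValueError("unbounded rate profile")
            if lam_max <= 0:
                continue
            t0, t1 = prof.span
            n = rng.poisson(lam_max * (t1 - t0) / 1000.0)
            if n == 0:
                continue
            cand = rng.uniform(t0, t1, size=n)
            keep = rng.random(n) * lam_max < prof(cand)
            times.append(np.round(cand[keep]).astype(np.int64))
        if times:
            allt = np.sort(np.concatenate(times))
            spikes.extend(SpikeRecord(unit_id, int(t)) for t in allt)
    return spikes


def _apply_dead_time(times: np.ndarray, dead_ms: float) -> np.ndarray:
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= dead_ms:
            keep.append(t)
    return np.asarray(keep, dtype=np.int64)


# ------------------------------------------------------------------- session

def _kinematics(trial: TrialRecord, rng: np.random.Generator) -> None:
    """Attach a sigmoidal reach trace and a jittered fixation eye trace."""
    t = np.arange(trial.cue_on_ms - 200, trial.move_on_ms + 400, 10, dtype=np.int64)
    reach = 1.0 / (1.0 + np.exp(-(t - trial.move_on_ms - 150.0) / 40.0))
    trial.kin_t_ms = t
    trial.hand_x = trial.choice * 100.0 * reach + 0.5 * rng.standard_normal(t.size)
    trial.hand_y = 0.5 * rng.standard_normal(t.size)
    trial.eye_x = 0.3 * rng.standard_normal(t.size)
    trial.eye_y = 0.3 * rng.standard_normal(t.size)
    # peak tangential hand speed in mm/s (sigmoid peak slope 100/(4*40ms))
    trial.hand_speed = float(100.0 / (4 * 0.040) * (1.0 + 0.05 * rng.standard_normal()))


def generate_session(config: GeneratorConfig) -> SessionBundle:
    """Generate a full synthetic session with ground-truth archetype labels.

    Deterministic given ``config.seed``: behavior, unit placement via the
    depth rule, spiking, kinematics, and the ~2.5% change-of-mind flags are
    all drawn from one seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    ddm = DDMParams.default(config.coherence_levels)
    trials = simulate_behavior(ddm, config, rng)

    com = rng.random(len(trials)) < config.change_of_mind_rate
    for t, flag in zip(trials, com):
        t.change_of_mind = bool(flag)
        _kinematics(t, rng)

    rule = config.depth_rule or default_depth_rule
    # electrode sampling: P(electrode | archetype) from the depth rule by Bayes
    # with a uniform electrode prior
    probs = {a: np.array([rule(e)[a] for e in range(1, 17)]) for a in ARCHETYPES}

    units: list[UnitRecord] = []
    ground_truth: dict[int, str] = {}
    profiles: dict[int, list[RateProfile]] = {}
    unit_id = 0
    for archetype, n_units in zip(ARCHETYPES, config.units_per_archetype):
        p = probs[archetype] / probs[archetype].sum()
        for _ in range(n_units):
            electrode = int(rng.choice(np.arange(1, 17), p=p))
            if config.archetype_overrides and archetype in config.archetype_overrides:
                spec = config.archetype_overrides[archetype]
            else:
                spec = ArchetypeSpec.default(archetype)
            if electrode >= 9 and config.deep_extra_latency_ms:
                spec = replace(spec, cue_latency_ms=spec.cue_latency_ms + config.deep_extra_latency_ms)
            preferred = int(rng.choice([-1, 1]))
            profiles[unit_id] = [rate_profile(spec, t, preferred) for t in trials]
            depth = config.insertion_depth_mm + config.electrode_spacing_mm * (electrode - 1)
            units.append(UnitRecord(unit_id, f"synth{config.seed:04d}", electrode, depth, 0.0, "single"))
            ground_truth[unit_id] = archetype
            unit_id += 1

    raw = simulate_spike_trains(profiles, trials, rng)
    spikes: list[SpikeRecord] = []
    by_unit: dict[int, list[int]] = {}
    for s in raw:
        by_unit.setdefault(s.unit_id, []).append(s.spike_time_ms)
    for u in units:
        t = _apply_dead_time(np.asarray(by_unit.get(u.unit_id, []), dtype=np.int64), config.refractory_ms)
        if t.size >= 2:
            pct, label = classify_isolation(t)
            u.isi_violation_pct, u.isolation = pct, label
        spikes.extend(SpikeRecord(u.unit_id, int(x)) for x in t)

    return SessionBundle(
        session_id=f"synth{config.seed:04d}",
        monkey_id="S",
        trials=trials,
        units=units,
        spikes=spikes,
        ground_truth=ground_truth,
        notes="synthetic session",
    )
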