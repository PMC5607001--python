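"""Session data model, on-disk format, and unit isolation grading.

A recording session lives in a directory of plain-text files:

``trials.csv``
    One row per trial.  All event times are integer milliseconds on a
    single session clock; the reaction time ``rt_ms`` is always
    ``move_on_ms - cue_on_ms``.
``spikes.csv``
    ``unit_id, spike_time_ms`` -- one row per spike, times non-decreasing
    within a unit.
``units.csv``
    One row per unit with its electrode index (1 = most superficial contact
    of the 16-channel laminar probe), cortical depth in mm, the fraction of
    inter-spike intervals at or below the 2-ms refractory period, and the
    resulting ``single`` / ``multi`` isolation label.
``session.json``
    Session and subject identifiers plus, for synthetic sessions, the
    ground-truth archetype label of every unit.
``kinematics.csv``
    Optional sampled hand and eye traces (``trial_id, t_ms, hand_x, hand_y,
    eye_x, eye_y``).

Analysis windows throughout the package are half-open ``[t0, t1)`` and
times are kept as integers so that a write/read round trip is bit exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "UnitRecord",
    "SpikeRecord",
    "SessionBundle",
    "ValidationError",
    "read_session",
    "write_session",
    "classify_isolation",
    "bundles_equal",
]

#: refractory period used for isolation grading (ISI <= this counts as a violation)
ISI_REFRACTORY_MS = 2.0
#: units with a violation percentage strictly below this are "single"
SINGLE_UNIT_MAX_VIOLATION_PCT = 1.5

TRIAL_COLUMNS = [
    "trial_id",
    "coherence_C",
    "signed_coherence_SC",
    "choice",
    "chosen_color",
    "correct",
    "target_on_ms",
    "cue_on_ms",
    "move_on_ms",
    "rt_ms",
    "change_of_mind",
    "hand_speed",
]
SPIKE_COLUMNS = ["unit_id", "spike_time_ms"]
UNIT_COLUMNS = ["unit_id", "electrode_index", "depth_mm", "isi_violation_pct", "isolation"]
KINEMATIC_COLUMNS = ["trial_id", "t_ms", "hand_x", "hand_y", "eye_x", "eye_y"]


class ValidationError(ValueError):
    """A bundle violated the session-format invariants.

    ``errors`` lists one human-readable message per offending row.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid session bundle:\n" + "\n".join(self.errors))


@dataclass(eq=False)
class TrialRecord:
    """A single behavioral trial.

    ``coherence_C`` is the color coherence C = 100|R-G|/(R+G) of the
    checkerboard cue (percent); ``signed_coherence_SC`` carries the sign of
    the dominant color (positive = more red).  ``choice`` is the reach
    direction (-1 left, +1 right), ``chosen_color`` the color of the touched
    target (-1 green, +1 red).  Optional kinematic traces are sampled on the
    session clock at the times in ``kin_t_ms``.
    """

    trial_id: int
    coherence_C: float
    signed_coherence_SC: float
    choice: int
    chosen_color: int
    correct: bool
    target_on_ms: int
    cue_on_ms: int
    move_on_ms: int
    rt_ms: int
    change_of_mind: bool = False
    hand_speed: float = math.nan
    kin_t_ms: np.ndarray | None = None
    hand_x: np.ndarray | None = None
    hand_y: np.ndarray | None = None
    eye_x: np.ndarray | None = None
    eye_y: np.ndarray | None = None


@dataclass(eq=True)
class UnitRecord:
    unit_id: int
    session_id: str
    electrode_index: int  # 1..16, 1 most superficial
    depth_mm: float
    isi_violation_pct: float
    isolation: str  # "single" | "multi"


@dataclass(eq=True)
class SpikeRecord:
    unit_id: int
    spike_time_ms: int


@dataclass(eq=False)
class SessionBundle:
    """One recording session: trials, units, spikes, and metadata."""

    session_id: str
    monkey_id: str
    trials: list[TrialRecord] = field(default_factory=list)
    units: list[UnitRecord] = field(default_factory=list)
    spikes: list[SpikeRecord] = field(default_factory=list)
    ground_truth: dict[int, str] | None = None
    notes: str = ""

    # ------------------------------------------------------------------ views
    def trials_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(t, c) for c in TRIAL_COLUMNS}
            for t in self.trials
        ]
        df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
        if len(df):
            for c in ("correct", "change_of_mind"):
                df[c] = df[c].astype(int)
        return df

    def spikes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.unit_id, s.spike_time_ms) for s in self.spikes],
            columns=SPIKE_COLUMNS,
        )

    def units_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (u.unit_id, u.electrode_index, u.depth_mm, u.isi_violation_pct, u.isolation)
                for u in self.units
            ],
            columns=UNIT_COLUMNS,
        )

    def spike_times(self, unit_id: int) -> np.ndarray:
        """Sorted spike times (int ms) of one unit."""
        t = np.array(
            [s.spike_time_ms for s in self.spikes if s.unit_id == unit_id], dtype=np.int64
        )
        return np.sort(t)

    def analysis_trials(self) -> list[TrialRecord]:
        """Trials eligible for every downstream average.

        Change-of-mind trials are excluded throughout (their reach direction
        is ambiguous and they inflate perimovement variance).
        """
        return [t for t in self.trials if not t.change_of_mind]


# --------------------------------------------------------------------- checks

def _validate(bundle: SessionBundle) -> list[str]:
    errors: list[str] = []
    for t in bundle.trials:
        if t.rt_ms <= 0:
            errors.append(f"trial {t.trial_id}: rt_ms={t.rt_ms} must be > 0")
        if t.rt_ms != t.move_on_ms - t.cue_on_ms:
            errors.append(
                f"trial {t.trial_id}: rt_ms={t.rt_ms} != move_on-cue_on="
                f"{t.move_on_ms - t.cue_on_ms}"
            )
        if not math.isclose(abs(t.signed_coherence_SC), t.coherence_C, abs_tol=1e-9):
            errors.append(f"trial {t.trial_id}: |SC| != C")
        if not (0.0 <= t.coherence_C <= 100.0):
            errors.append(f"trial {t.trial_id}: C={t.coherence_C} outside [0, 100]")
        if t.choice not in (-1, 1) or t.chosen_color not in (-1, 1):
            errors.append(f"trial {t.trial_id}: choice/chosen_color must be -1 or +1")
    unit_ids = set()
    for u in bundle.units:
        if not 1 <= u.electrode_index <= 16:
            errors.append(f"unit {u.unit_id}: electrode_index={u.electrode_index} not in 1..16")
        is_single = u.isi_violation_pct < SINGLE_UNIT_MAX_VIOLATION_PCT
        if u.isolation != ("single" if is_single else "multi"):
            errors.append(
                f"unit {u.unit_id}: isolation '{u.isolation}' inconsistent with "
                f"isi_violation_pct={u.isi_violation_pct}"
            )
        unit_ids.add(u.unit_id)
    last: dict[int, int] = {}
    for s in bundle.spikes:
        if s.unit_id not in unit_ids:
            errors.append(f"spike at {s.spike_time_ms}: unknown unit {s.unit_id}")
            continue
        if s.unit_id in last and s.spike_time_ms < last[s.unit_id]:
            errors.append(f"unit {s.unit_id}: spike times decrease at {s.spike_time_ms}")
        last[s.unit_id] = s.spike_time_ms
    return errors


# ------------------------------------------------------------------------ I/O

def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a validated bundle to ``path`` such that :func:`read_session`
    inverts it exactly (all times as integer ms)."""
    errors = _validate(bundle)
    if errors:
        raise ValidationError(errors)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    bundle.trials_frame().to_csv(path / "trials.csv", index=False, float_format="%.17g")
    bundle.spikes_frame().to_csv(path / "spikes.csv", index=False)
    bundle.units_frame().to_csv(path / "units.csv", index=False, float_format="%.17g")

    kin_rows = []
    for t in bundle.trials:
        if t.kin_t_ms is None:
            continue
        for i, tm in enumerate(np.asarray(t.kin_t_ms)):
            kin_rows.append(
                (t.trial_id, int(tm), t.hand_x[i], t.hand_y[i], t.eye_x[i], t.eye_y[i])
            )
    if kin_rows:
        pd.DataFrame(kin_rows, columns=KINEMATIC_COLUMNS).to_csv(
            path / "kinematics.csv", index=False, float_format="%.17g"
        )

    meta = {
        "session_id": bundle.session_id,
        "monkey_id": bundle.monkey_id,
        "notes": bundle.notes,
        "sampling": "event times in integer ms on the session clock; windows half-open [t0, t1)",
    }
    if bundle.ground_truth is not None:
        meta["ground_truth"] = {str(k): v for k, v in bundle.ground_truth.items()}
    (path / "session.json").write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory.

    Raises ``FileNotFoundError`` for missing mandatory files and
    :class:`ValidationError` (listing offending rows) for invariant
    violations.
    """
    path = Path(path)
    for name in ("trials.csv", "spikes.csv", "units.csv", "session.json"):
        if not (path / name).exists():
            raise FileNotFoundError(f"session directory {path} is missing {name}")

    meta = json.loads((path / "session.json").read_text())
    trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    spikes_df = pd.read_csv(path / "spikes.csv")
    units_df = pd.read_csv(path / "units.csv", float_precision="round_trip")

    kin: dict[int, pd.DataFrame] = {}
    if (path / "kinematics.csv").exists():
        kdf = pd.read_csv(path / "kinematics.csv", float_precision="round_trip")
        kin = {int(tid): g for tid, g in kdf.groupby("trial_id")}

    trials = []
    for row in trials_df.itertuples(index=False):
        t = TrialRecord(
            trial_id=int(row.trial_id),
            coherence_C=float(row.coherence_C),
            signed_coherence_SC=float(row.signed_coherence_SC),
            choice=int(row.choice),
            chosen_color=int(row.chosen_color),
            correct=bool(row.correct),
            target_on_ms=int(row.target_on_ms),
            cue_on_ms=int(row.cue_on_ms),
            move_on_ms=int(row.move_on_ms),
            rt_ms=int(row.rt_ms),
            change_of_mind=bool(row.change_of_mind),
            hand_speed=float(row.hand_speed),
        )
        g = kin.get(t.trial_id)
        if g is not None:
            t.kin_t_ms = g["t_ms"].to_numpy(dtype=np.int64)
            for col in ("hand_x", "hand_y", "eye_x", "eye_y"):
                setattr(t, col, g[col].to_numpy(dtype=float))
        trials.append(t)

    units = [
        UnitRecord(
            unit_id=int(r.unit_id),
            session_id=str(meta["session_id"]),
            electrode_index=int(r.electrode_index),
            depth_mm=float(r.depth_mm),
            isi_violation_pct=float(r.isi_violation_pct),
            isolation=str(r.isolation),
        )
        for r in units_df.itertuples(index=False)
    ]
    spikes = [
        SpikeRecord(unit_id=int(r.unit_id), spike_time_ms=int(r.spike_time_ms))
        for r in spikes_df.itertuples(index=False)
    ]

    gt = meta.get("ground_truth")
    bundle = SessionBundle(
        session_id=str(meta["session_id"]),
        monkey_id=str(meta["monkey_id"]),
        trials=trials,
        units=units,
        spikes=spikes,
        ground_truth={int(k): v for k, v in gt.items()} if gt else None,
        notes=str(meta.get("notes", "")),
    )
    errors = _validate(bundle)
    if errors:
        raise ValidationError(errors)
    return bundle


# ------------------------------------------------------------------ isolation

def classify_isolation(spike_times: np.ndarray) -> tuple[float, str]:
    """Grade a unit's isolation from its inter-spike intervals.

    Returns ``(violation_pct, label)`` where ``violation_pct`` is
    100 x (#ISIs <= 2 ms)/(#ISIs) and the label is ``"single"`` iff the
    percentage is strictly below 1.5.  Requires at least two spikes.
    """
    spike_times = np.asarray(spike_times)
    if spike_times.size < 2:
        raise ValueError("isolation undefined for fewer than 2 spikes")
    isi = np.diff(np.sort(spike_times))
    pct = 100.0 * np.mean(isi <= ISI_REFRACTORY_MS)
    label = "single" if pct < SINGLE_UNIT_MAX_VIOLATION_PCT else "multi"
    return float(pct), label


# ------------------------------------------------------------------- equality

def _arr_eq(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return np.array_equal(np.asarray(a), np.asarray(b))


def trials_equal(a: TrialRecord, b: TrialRecord) -> bool:
    for c in TRIAL_COLUMNS:
        va, vb = getattr(a, c), getattr(b, c)
        if isinstance(va, float) and math.isnan(va):
            if not (isinstance(vb, float) and math.isnan(vb)):
                return False
        elif va != vb:
            return False
    return all(
        _arr_eq(getattr(a, c), getattr(b, c))
        for c in ("kin_t_ms", "hand_x", "hand_y", "eye_x", "eye_y")
    )


def bundles_equal(a: SessionBundle, b: SessionBundle) -> bool:
    """Field-by-field equality, with NaN == NaN for optional scalars."""
    if (a.session_id, a.monkey_id, a.ground_truth) != (b.session_id, b.monkey_id, b.ground_truth):
        return False
    if len(a.trials) != len(b.trials) or a.units != b.units or a.spikes != b.spikes:
        return False
    return all(trials_equal(x, y) for x, y in zip(a.trials, b.trials))
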