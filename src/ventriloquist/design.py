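"""Experimental design: conditions, sessions, and trial counts.

The design is a spatial ventriloquist paradigm. Auditory and visual signals
are sampled from four azimuthal locations (default −10°, −3.3°, 3.3°, 10°).
Unisensory auditory (4 conditions), unisensory visual (4 locations × 2 visual
reliabilities = 8 conditions) and audiovisual conditions are presented in
separate sessions. Audiovisual sessions cross all 4 × 4 location combinations
with visual reliability (32 conditions); the cue-combination (MLE) analyses
use only the congruent (ΔAV = 0°) and small-conflict (nominal ΔAV = ±6°,
i.e., adjacent grid locations) subset, crossed with the modality-specific
report factor — 52 conditions in total.

ΔAV is defined as auditory minus visual location.  The physical grid gives
adjacent disparities of 6.6°–6.7°; a nominal disparity (default 6°) is what
the weight equations use.  :func:`idealized_grid` returns an evenly spaced
grid on which the nominal and physical disparities coincide exactly, which
the round-trip identity tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidDesignError

DEFAULT_GRID: tuple[float, ...] = (-10.0, -3.3, 3.3, 10.0)
NOMINAL_DELTA: float = 6.0
RELIABILITIES: tuple[str, str] = ("high", "low")
REPORTS: tuple[str, str] = ("auditory", "visual")
DEFAULT_NULL_FRACTION: float = 0.059


def idealized_grid(delta: float = NOMINAL_DELTA) -> tuple[float, ...]:
    """Evenly spaced 4-point grid whose adjacent disparity is exactly *delta*.

    With the default nominal disparity of 6° this is (−9, −3, 3, 9): every
    small-conflict pair then sits at exactly ±delta around its congruent
    midpoint, so the PSE ↔ weight algebra holds without the 0.6°–0.7°
    slack of the physical grid.
    """
    return (-1.5 * delta, -0.5 * delta, 0.5 * delta, 1.5 * delta)


def validate_grid(grid: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(g) for g in grid)
    if len(grid) != 4:
        raise InvalidDesignError(f"location grid must have 4 entries, got {len(grid)}")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InvalidDesignError("location grid must be strictly increasing")
    return grid


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental cell.

    ``nominal_delta`` is the design-level disparity (−6, 0, +6 for the MLE
    subset; ``None`` for unisensory conditions and for large-disparity
    combinations outside the MLE subset).  ``delta_av`` is always the
    physical auditory-minus-visual difference.
    """

    modality: str  # "A", "V" or "AV"
    loc_a: float | None = None
    loc_v: float | None = None
    visual_reliability: str | None = None
    report: str | None = None
    nominal_delta: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("A", "V", "AV"):
            raise InvalidDesignError(f"unknown modality {self.modality!r}")
        if self.modality == "A":
            if self.loc_v is not None or self.visual_reliability is not None:
                raise InvalidDesignError("auditory condition cannot carry visual fields")
            if self.loc_a is None:
                raise InvalidDesignError("auditory condition needs loc_a")
        elif self.modality == "V":
            if self.loc_a is not None:
                raise InvalidDesignError("visual condition cannot carry loc_a")
            if self.loc_v is None or self.visual_reliability is None:
                raise InvalidDesignError("visual condition needs loc_v and reliability")
        else:
            if self.loc_a is None or self.loc_v is None or self.visual_reliability is None:
                raise InvalidDesignError("AV condition needs both locations and reliability")

    @property
    def delta_av(self) -> float | None:
        """Physical auditory-minus-visual disparity (AV conditions only)."""
        if self.modality != "AV":
            return None
        return self.loc_a - self.loc_v

    @property
    def abscissa(self) -> float:
        """Stimulus position on the psychometric-function axis.

        Unisensory: the single true location.  Audiovisual: the mean of the
        true auditory and visual locations.
        """
        if self.modality == "A":
            return self.loc_a
        if self.modality == "V":
            return self.loc_v
        return 0.5 * (self.loc_a + self.loc_v)


def pair_nominal_delta(grid: Sequence[float], loc_a: float, loc_v: float,
                       delta: float = NOMINAL_DELTA) -> float | None:
    """Nominal ΔAV for a location pair: 0, ±delta, or None outside the subset."""
    grid = validate_grid(grid)
    ia, iv = grid.index(loc_a), grid.index(loc_v)
    if ia == iv:
        return 0.0
    if abs(ia - iv) == 1:
        return delta if ia > iv else -delta
    return None


def enumerate_mle_conditions(grid: Sequence[float] = DEFAULT_GRID,
                             delta: float = NOMINAL_DELTA) -> list[ConditionSpec]:
    """All 52 conditions entering the cue-combination analysis.

    4 unisensory auditory + 8 unisensory visual + 40 audiovisual:
    (4 congruent + 6 small-conflict location pairs) × 2 visual reliabilities
    × 2 modality-specific reports.
    """
    grid = validate_grid(grid)
    conds: list[ConditionSpec] = [ConditionSpec("A", loc_a=loc) for loc in grid]
    for rel in RELIABILITIES:
        for loc in grid:
            conds.append(ConditionSpec("V", loc_v=loc, visual_reliability=rel))
    for rel in RELIABILITIES:
        for report in REPORTS:
            for loc_a in grid:
                for loc_v in grid:
                    nom = pair_nominal_delta(grid, loc_a, loc_v, delta)
                    if nom is None:
                        continue
                    conds.append(ConditionSpec(
                        "AV", loc_a=loc_a, loc_v=loc_v, visual_reliability=rel,
                        report=report, nominal_delta=nom))
    return conds


def enumerate_full_av_combinations(grid: Sequence[float] = DEFAULT_GRID,
                                   delta: float = NOMINAL_DELTA,
                                   report: str | None = None,
                                   ) -> list[tuple[ConditionSpec, bool]]:
    """All 4 × 4 audiovisual location combinations per reliability level.

    Returns ``(condition, in_mle_subset)`` pairs; 16 combinations per
    reliability, of which 4 are congruent and 6 are small-conflict.
    """
    grid = validate_grid(grid)
    out: list[tuple[ConditionSpec, bool]] = []
    for rel in RELIABILITIES:
        for loc_a in grid:
            for loc_v in grid:
                nom = pair_nominal_delta(grid, loc_a, loc_v, delta)
                cond = ConditionSpec("AV", loc_a=loc_a, loc_v=loc_v,
                                     visual_reliability=rel, report=report,
                                     nominal_delta=nom)
                out.append((cond, nom is not None))
    return out


def auditory_session_conditions(grid: Sequence[float] = DEFAULT_GRID) -> list[ConditionSpec]:
    return [ConditionSpec("A", loc_a=loc) for loc in validate_grid(grid)]


def visual_session_conditions(grid: Sequence[float] = DEFAULT_GRID) -> list[ConditionSpec]:
    grid = validate_grid(grid)
    return [ConditionSpec("V", loc_v=loc, visual_reliability=rel)
            for rel in RELIABILITIES for loc in grid]


def av_session_conditions(report: str, grid: Sequence[float] = DEFAULT_GRID,
                          delta: float = NOMINAL_DELTA) -> list[ConditionSpec]:
    """The 32 conditions of one audiovisual session (16 combos × 2 reliabilities)."""
    if report not in REPORTS:
        raise InvalidDesignError(f"unknown report modality {report!r}")
    return [c for c, _ in enumerate_full_av_combinations(grid, delta, report=report)]


@dataclass
class SessionPlan:
    """An ordered trial sequence for one session.

    ``trials`` holds the stimulus trials in presentation order; ``None``
    entries mark interspersed null events (fixation-only pseudo-events),
    which are additional to the stimulus-trial count.
    """

    session_id: int
    report: str | None
    trials: list[ConditionSpec | None]
    null_event_fraction: float = DEFAULT_NULL_FRACTION

    @property
    def stimulus_trials(self) -> list[ConditionSpec]:
        return [t for t in self.trials if t is not None]

    @property
    def n_stimulus_trials(self) -> int:
        return sum(t is not None for t in self.trials)

    @property
    def n_null_events(self) -> int:
        return sum(t is None for t in self.trials)


def build_session_plan(conditions: Sequence[ConditionSpec], trials_per_condition: int,
                       null_fraction: float = DEFAULT_NULL_FRACTION,
                       seed: int | None = None, session_id: int = 0,
                       report: str | None = None) -> SessionPlan:
    """Pseudorandomized session: each condition repeated, order shuffled from *seed*.

    Null events (``round(null_fraction × n_stimulus)`` of them) are inserted
    at random positions on top of the stimulus trials.
    """
    if trials_per_condition < 1:
        raise InvalidDesignError("trials_per_condition must be ≥ 1")
    if null_fraction < 0:
        raise InvalidDesignError("null_fraction must be ≥ 0")
    if seed is None:
        raise InvalidDesignError("a seed is required for a reproducible plan")
    rng = np.random.default_rng(seed)
    stim: list[ConditionSpec | None] = [c for c in conditions for _ in range(trials_per_condition)]
    order = rng.permutation(len(stim))
    events: list[ConditionSpec | None] = [stim[i] for i in order]
    n_null = int(round(null_fraction * len(stim)))
    for pos in sorted(rng.integers(0, len(events) + 1, size=n_null), reverse=True):
        events.insert(int(pos), None)
    return SessionPlan(session_id=session_id, report=report, trials=events,
                       null_event_fraction=null_fraction)


def default_session_plans(grid: Sequence[float] = DEFAULT_GRID,
                          delta: float = NOMINAL_DELTA,
                          n_av_sessions_per_report: int = 10,
                          n_auditory_sessions: int = 3,
                          n_visual_sessions: int = 3,
                          av_trials_per_condition: int = 11,
                          auditory_trials_per_condition: int = 88,
                          visual_trials_per_condition: int = 44,
                          null_fraction: float = DEFAULT_NULL_FRACTION,
                          seed: int = 0) -> list[SessionPlan]:
    """Session structure of the full experiment for one participant.

    Defaults follow the study: 10 audiovisual sessions per report modality
    (32 conditions × 11 trials = 352 stimuli each), 3 unisensory auditory
    sessions (4 × 88) and 3 unisensory visual sessions (8 × 44), each with
    5.9% null events interspersed.
    """
    rng = np.random.default_rng(seed)
    plans: list[SessionPlan] = []
    sid = 0
    for report in REPORTS:
        for _ in range(n_av_sessions_per_report):
            plans.append(build_session_plan(
                av_session_conditions(report, grid, delta), av_trials_per_condition,
                null_fraction, seed=int(rng.integers(2**31)), session_id=sid, report=report))
            sid += 1
    for _ in range(n_auditory_sessions):
        plans.append(build_session_plan(
            auditory_session_conditions(grid), auditory_trials_per_condition,
            null_fraction, seed=int(rng.integers(2**31)), session_id=sid, report="auditory"))
        sid += 1
    for _ in range(n_visual_sessions):
        plans.append(build_session_plan(
            visual_session_conditions(grid), visual_trials_per_condition,
            null_fraction, seed=int(rng.integers(2**31)), session_id=sid, report="visual"))
        sid += 1
    return plans


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = ["session_id", "trial_index", "modality", "loc_a", "loc_v",
            "visual_reliability", "report", "delta_av", "nominal_delta"]


def condition_record(cond: ConditionSpec) -> dict:
    return {
        "modality": cond.modality,
        "loc_a": cond.loc_a,
        "loc_v": cond.loc_v,
        "visual_reliability": cond.visual_reliability,
        "report": cond.report,
        "delta_av": cond.delta_av,
        "nominal_delta": cond.nominal_delta,
    }


def conditions_to_frame(conditions: Iterable[ConditionSpec]) -> pd.DataFrame:
    return pd.DataFrame([condition_record(c) for c in conditions])


def plans_to_frame(plans: Iterable[SessionPlan]) -> pd.DataFrame:
    """One row per event (stimulus trial or null) across sessions."""
    rows = []
    for plan in plans:
        for idx, trial in enumerate(plan.trials):
            if trial is None:
                rows.append({"session_id": plan.session_id, "trial_index": idx,
                             "modality": "null", "loc_a": None, "loc_v": None,
                             "visual_reliability": None, "report": plan.report,
                             "delta_av": None, "nominal_delta": None})
            else:
                rec = condition_record(trial)
                rec["report"] = trial.report if trial.report is not None else plan.report
                rows.append({"session_id": plan.session_id, "trial_index": idx, **rec})
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_plans(frame: pd.DataFrame,
                   null_fraction: float = DEFAULT_NULL_FRACTION) -> list[SessionPlan]:
    plans = []
    for sid, group in frame.groupby("session_id", sort=True):
        group = group.sort_values("trial_index")
        trials: list[ConditionSpec | None] = []
        report = None
        for _, row in group.iterrows():
            if row["modality"] == "null":
                trials.append(None)
                continue
            report = row["report"] if pd.notna(row["report"]) else None
            cond = ConditionSpec(
                modality=row["modality"],
                loc_a=float(row["loc_a"]) if pd.notna(row["loc_a"]) else None,
                loc_v=float(row["loc_v"]) if pd.notna(row["loc_v"]) else None,
                visual_reliability=row["visual_reliability"]
                if pd.notna(row["visual_reliability"]) else None,
                report=report if row["modality"] == "AV" else None,
                nominal_delta=float(row["nominal_delta"])
                if pd.notna(row["nominal_delta"]) else None)
            trials.append(cond)
        plans.append(SessionPlan(session_id=int(sid), report=report, trials=trials,
                                 null_event_fraction=null_fraction))
    return plans
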