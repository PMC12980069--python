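"""Domain records, delimited-text I/O, validation, and the exclusion rules.

Trial-level and participant-level data travel as pandas DataFrames with the
column contracts below; :class:`TrialRecord` / :class:`ParticipantRecord`
give a typed row-level view where convenient.

trials.csv columns
    participant_id, task, block, trial_index, target_emotion,
    distractor_emotion, color, is_target, responded, rt_ms, correct, timeout

participants.csv columns
    participant_id, age_years, gender, cesdc, staich, kars, admin_mode

Engagement dropout: a participant is excluded from a task when, somewhere in
the ordered main-phase trial sequence, at least ``threshold`` (default 4)
consecutive response-required trials go unanswered with no touch in between.
Any response (including a commission error on a no-go trial) resets the run;
a correctly withheld no-go trial neither extends nor breaks it.  For the
eFlanker, where every trial requires a response, this reduces to "4+
consecutive trials with no response".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    COLORS,
    EMOTIONS,
    GONOGO_EMOTIONS,
    TASK_DESIGNS,
    TASKS,
    TaskDesign,
    expected_condition_counts,
)

GENDERS = ("male", "female")
ADMIN_MODES = ("self", "experimenter")

TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "block",
    "trial_index",
    "target_emotion",
    "distractor_emotion",
    "color",
    "is_target",
    "responded",
    "rt_ms",
    "correct",
    "timeout",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_years",
    "gender",
    "cesdc",
    "staich",
    "kars",
    "admin_mode",
]

_BOOL_COLUMNS = ("is_target", "responded", "correct", "timeout")
_MAX_REPORTED = 10  # cap on individual row errors quoted in an exception


class SchemaError(ValueError):
    """A table violates the trial/participant contract."""


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    task: str
    block: int
    trial_index: int
    target_emotion: str
    distractor_emotion: str | None
    color: str | None
    is_target: bool
    responded: bool
    rt_ms: float | None
    correct: bool
    timeout: bool


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    age_years: float
    gender: str
    cesdc: int
    staich: int
    kars: int
    admin_mode: str


def records_from_trials(trials: pd.DataFrame):
    """Iterate a validated trial frame as :class:`TrialRecord` objects."""
    for row in trials.itertuples(index=False):
        yield TrialRecord(
            participant_id=row.participant_id,
            task=row.task,
            block=int(row.block),
            trial_index=int(row.trial_index),
            target_emotion=row.target_emotion,
            distractor_emotion=None if pd.isna(row.distractor_emotion) else row.distractor_emotion,
            color=None if pd.isna(row.color) else row.color,
            is_target=bool(row.is_target),
            responded=bool(row.responded),
            rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
            correct=bool(row.correct),
            timeout=bool(row.timeout),
        )


# ---------------------------------------------------------------------------
# parsing helpers


def _require_columns(frame: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing mandatory column(s): {', '.join(missing)}")


def _coerce_bool(frame: pd.DataFrame, col: str, errors: list[str]) -> None:
    mapping = {
        True: True, False: False,
        "True": True, "False": False, "true": True, "false": False,
        "TRUE": True, "FALSE": False, 1: True, 0: False, "1": True, "0": False,
    }
    series = frame[col].map(mapping)
    bad = series.isna() & frame[col].notna()
    if bad.any():
        rows = list(frame.index[bad][:_MAX_REPORTED])
        errors.append(f"column {col!r}: unparseable boolean at row(s) {rows}")
    if frame[col].isna().any():
        rows = list(frame.index[frame[col].isna()][:_MAX_REPORTED])
        errors.append(f"column {col!r}: missing value at row(s) {rows}")
    frame[col] = series.astype("boolean").fillna(False).astype(bool)


def _coerce_number(frame: pd.DataFrame, col: str, errors: list[str], *, allow_na: bool) -> None:
    series = pd.to_numeric(frame[col], errors="coerce")
    bad = series.isna() & frame[col].notna()
    if bad.any():
        rows = list(frame.index[bad][:_MAX_REPORTED])
        errors.append(f"column {col!r}: unparseable number at row(s) {rows}")
    if not allow_na:
        missing = series.isna() & frame[col].isna()
        if missing.any():
            rows = list(frame.index[missing][:_MAX_REPORTED])
            errors.append(f"column {col!r}: missing value at row(s) {rows}")
    frame[col] = series


def _report(errors: list[str], what: str) -> None:
    if errors:
        raise SchemaError(f"invalid {what}: " + "; ".join(errors))


def _check_membership(frame, col, allowed, errors, mask=None) -> None:
    values = frame[col]
    ok = values.isin(allowed)
    if mask is not None:
        ok = ok | ~mask
    if not ok.all():
        rows = list(frame.index[~ok][:_MAX_REPORTED])
        errors.append(f"column {col!r}: value outside {sorted(allowed)} at row(s) {rows}")


# ---------------------------------------------------------------------------
# trial tables


def validate_trials(trials: pd.DataFrame, task: str | None = None) -> pd.DataFrame:
    """Coerce dtypes and enforce every trial-level invariant.

    Returns the coerced frame; raises :class:`SchemaError` (with row numbers)
    on the first batch of violations found.
    """
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    frame = trials.copy()
    errors: list[str] = []

    frame["participant_id"] = frame["participant_id"].astype(str)
    for col in _BOOL_COLUMNS:
        _coerce_bool(frame, col, errors)
    _coerce_number(frame, "block", errors, allow_na=False)
    _coerce_number(frame, "trial_index", errors, allow_na=False)
    _coerce_number(frame, "rt_ms", errors, allow_na=True)
    _report(errors, "trial table")

    frame["block"] = frame["block"].astype(int)
    frame["trial_index"] = frame["trial_index"].astype(int)

    _check_membership(frame, "task", set(TASKS), errors)
    if task is not None:
        wrong = frame["task"] != task
        if wrong.any():
            rows = list(frame.index[wrong][:_MAX_REPORTED])
            errors.append(f"expected task {task!r}, found other tasks at row(s) {rows}")
    if (frame["block"] < 0).any():
        errors.append("column 'block': negative block numbers")
    if (frame["trial_index"] < 1).any():
        errors.append("column 'trial_index': indices must be >= 1")
    _check_membership(frame, "target_emotion", set(EMOTIONS), errors)

    is_flanker = frame["task"] == "eflanker"
    is_gonogo = frame["task"] == "egonogo"

    # task-specific condition columns
    if (is_flanker & frame["distractor_emotion"].isna()).any():
        errors.append("eFlanker rows must carry distractor_emotion")
    if (is_flanker & frame["color"].notna()).any():
        errors.append("eFlanker rows must not carry color")
    if (is_flanker & ~frame["is_target"]).any():
        errors.append("eFlanker rows must have is_target=True")
    _check_membership(frame, "distractor_emotion", set(EMOTIONS), errors,
                      mask=frame["distractor_emotion"].notna())
    if (~is_flanker & frame["color"].isna()).any():
        errors.append("eGoNoGo/eStroop rows must carry color")
    if (~is_flanker & frame["distractor_emotion"].notna()).any():
        errors.append("eGoNoGo/eStroop rows must not carry distractor_emotion")
    _check_membership(frame, "color", set(COLORS), errors, mask=frame["color"].notna())
    bad_gonogo = is_gonogo & ~frame["target_emotion"].isin(GONOGO_EMOTIONS)
    if bad_gonogo.any():
        rows = list(frame.index[bad_gonogo][:_MAX_REPORTED])
        errors.append(f"eGoNoGo has no neutral condition; bad row(s) {rows}")

    # response bookkeeping
    rt_mismatch = frame["rt_ms"].notna() != frame["responded"]
    if rt_mismatch.any():
        rows = list(frame.index[rt_mismatch][:_MAX_REPORTED])
        errors.append(f"rt_ms must be present iff responded; bad row(s) {rows}")
    if (frame["rt_ms"].dropna() < 0).any():
        errors.append("column 'rt_ms': negative reaction times")
    if (frame["timeout"] & frame["responded"]).any():
        rows = list(frame.index[frame["timeout"] & frame["responded"]][:_MAX_REPORTED])
        errors.append(f"timeout implies responded=False; bad row(s) {rows}")

    _report(errors, "trial table")
    return frame[TRIAL_COLUMNS]


def read_trials(path: str | Path, task: str | None = None) -> pd.DataFrame:
    """Read and validate a trials.csv file (practice blocks retained)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"participant_id": str})
    return validate_trials(raw, task=task)


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial frame in the canonical column order (UTF-8 CSV)."""
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# participant tables


def validate_participants(
    participants: pd.DataFrame,
    age_bounds: tuple[float, float] = (4.0, 10.0),
) -> pd.DataFrame:
    _require_columns(participants, PARTICIPANT_COLUMNS, "participant table")
    frame = participants.copy()
    errors: list[str] = []
    frame["participant_id"] = frame["participant_id"].astype(str)

    dupes = frame["participant_id"][frame["participant_id"].duplicated()]
    if len(dupes):
        errors.append(f"duplicate participant_id(s): {sorted(set(dupes))[:_MAX_REPORTED]}")

    _coerce_number(frame, "age_years", errors, allow_na=False)
    for col in ("cesdc", "staich", "kars"):
        _coerce_number(frame, col, errors, allow_na=False)
    _report(errors, "participant table")

    lo, hi = age_bounds
    out = (frame["age_years"] < lo) | (frame["age_years"] > hi)
    if out.any():
        rows = list(frame.index[out][:_MAX_REPORTED])
        errors.append(f"age_years outside [{lo}, {hi}] at row(s) {rows}")
    for col in ("cesdc", "staich", "kars"):
        if (frame[col] < 0).any():
            rows = list(frame.index[frame[col] < 0][:_MAX_REPORTED])
            errors.append(f"column {col!r}: negative scale value at row(s) {rows}")
        if (frame[col] % 1 != 0).any():
            errors.append(f"column {col!r}: scale values must be integers")
    _check_membership(frame, "gender", set(GENDERS), errors)
    _check_membership(frame, "admin_mode", set(ADMIN_MODES), errors)
    _report(errors, "participant table")

    for col in ("cesdc", "staich", "kars"):
        frame[col] = frame[col].astype(int)
    return frame[PARTICIPANT_COLUMNS]


def read_participants(
    path: str | Path, age_bounds: tuple[float, float] = (4.0, 10.0)
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"participant_id": str})
    return validate_participants(raw, age_bounds=age_bounds)


def write_participants(participants: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    participants[PARTICIPANT_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# exclusion rules


def longest_required_miss_run(trials: pd.DataFrame) -> int:
    """Longest run of consecutive unanswered response-required trials.

    Runs may span block boundaries.  A response to *any* trial resets the
    run; unanswered no-go trials leave it unchanged.
    """
    ordered = trials.sort_values(["block", "trial_index"], kind="stable")
    responded = ordered["responded"].to_numpy(bool)
    required = ordered["is_target"].to_numpy(bool)
    run = best = 0
    for resp, req in zip(responded, required):
        if resp:
            run = 0
        elif req:
            run += 1
            if run > best:
                best = run
    return best


def detect_dropout(trials: pd.DataFrame, threshold: int = 4) -> bool:
    """True iff one participant's one-task main-phase trials contain a run of
    >= ``threshold`` consecutive missed response-required trials."""
    if len(trials) == 0:
        raise ValueError("detect_dropout: empty trial list")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return longest_required_miss_run(trials) >= threshold


@dataclass
class ValidationReport:
    """Findings from cohort-level validation (report, never an exception)."""

    #: one row per participant x task: trial counts and dropout flag
    sessions: pd.DataFrame
    violations: list[str] = field(default_factory=list)
    orphan_trial_participants: list[str] = field(default_factory=list)
    orphan_participants: list[str] = field(default_factory=list)

    @property
    def dropout_counts(self) -> dict[str, int]:
        if len(self.sessions) == 0:
            return {}
        flagged = self.sessions[self.sessions["dropout"]]
        return flagged.groupby("task").size().to_dict()

    def dropout_flags(self) -> dict[tuple[str, str], bool]:
        return {
            (row.participant_id, row.task): bool(row.dropout)
            for row in self.sessions.itertuples(index=False)
        }

    @property
    def ok(self) -> bool:
        return not (self.violations or self.orphan_trial_participants
                    or self.orphan_participants)


def validate_cohort(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    designs: Mapping[str, TaskDesign] | None = None,
    dropout_threshold: int = 4,
) -> ValidationReport:
    """Cross-check a parsed cohort against the task designs.

    Reports (per participant and task) main-phase trial counts, condition
    count mismatches against the design, dropout flags, missing tasks, and
    ids present on only one side of the join.
    """
    designs = dict(designs or TASK_DESIGNS)
    violations: list[str] = []

    trial_ids = set(trials["participant_id"])
    part_ids = set(participants["participant_id"])
    orphan_trials = sorted(trial_ids - part_ids)
    orphan_parts = sorted(part_ids - trial_ids)
    for pid in orphan_trials:
        violations.append(f"participant {pid!r} has trials but no participant record")
    for pid in orphan_parts:
        violations.append(f"participant {pid!r} has a record but no trials")

    main = trials[trials["block"] > 0]
    rows = []
    for (pid, task), session in main.groupby(["participant_id", "task"], sort=True):
        design = designs.get(task)
        n_main = len(session)
        if design is not None and n_main != design.main_trials:
            violations.append(
                f"{pid}/{task}: {n_main} main trials, design expects {design.main_trials}"
            )
        expected = expected_condition_counts(task)
        if task == "eflanker":
            observed = session.groupby(["target_emotion", "distractor_emotion"]).size()
        else:
            observed = session.groupby(["target_emotion", "is_target"]).size()
        if not observed.reindex(expected.index, fill_value=0).equals(expected):
            violations.append(f"{pid}/{task}: condition counts deviate from design")
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                "n_main": n_main,
                "n_practice": int(((trials["participant_id"] == pid)
                                   & (trials["task"] == task)
                                   & (trials["block"] == 0)).sum()),
                "longest_miss_run": longest_required_miss_run(session),
                "dropout": detect_dropout(session, threshold=dropout_threshold),
            }
        )

    sessions = pd.DataFrame(
        rows,
        columns=["participant_id", "task", "n_main", "n_practice",
                 "longest_miss_run", "dropout"],
    )
    for pid in sorted(part_ids & trial_ids):
        present = set(sessions[sessions["participant_id"] == pid]["task"])
        for task in designs:
            if task not in present:
                violations.append(f"participant {pid!r} has no {task} trials")

    return ValidationReport(
        sessions=sessions,
        violations=violations,
        orphan_trial_participants=orphan_trials,
        orphan_participants=orphan_parts,
    )
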