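"""Read, validate, filter and write trial-level two-choice session data.

File dialect: comma-separated UTF-8 with a header row, one row per trial,
sides coded ``"L"``/``"R"``, rewards coded ``0``/``1``.  The reversal index is
stored in the file rather than recomputed on read so that downstream fitting
is insulated from criterion-detection bugs; :func:`check_reversal_consistency`
recomputes it for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SIDES = ("L", "R")
GROUPS = ("control", "MS")
SEXES = ("female", "male")
PHASES = ("pre_stress", "post_stress")

#: column order of the trial-log CSV dialect
TRIAL_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "phase",
    "session_index",
    "trial_index",
    "chosen_side",
    "correct_side",
    "rewarded",
    "reversal_index",
)

#: measure-table key columns followed by the measure columns, stable order
MEASURE_KEY_COLUMNS = ("subject_id", "group", "sex", "phase", "session_index")
MEASURE_VALUE_COLUMNS = (
    "alpha_rew",
    "alpha_nonrew",
    "beta",
    "kappa",
    "win_stay_correct",
    "win_stay_incorrect",
    "lose_shift_correct",
    "lose_shift_incorrect",
    "trials_to_criterion",
    "proportion_correct",
    "perseverative_responses",
)

#: sentinel written for missing values in measure tables
NA_SENTINEL = "NA"


class ValidationError(ValueError):
    """A trial log violated a structural invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One two-choice trial.

    Attributes
    ----------
    trial_index
        1-based ordinal within the session.
    chosen_side, correct_side
        ``"L"`` or ``"R"``; ``correct_side`` is the currently
        high-probability stimulus.
    rewarded
        0 or 1.
    reversal_index
        0-based count of contingency reversals completed before this trial.
    """

    trial_index: int
    chosen_side: str
    correct_side: str
    rewarded: int
    reversal_index: int

    def __post_init__(self) -> None:
        if self.chosen_side not in SIDES:
            raise ValidationError(f"chosen_side must be one of {SIDES}, got {self.chosen_side!r}")
        if self.correct_side not in SIDES:
            raise ValidationError(f"correct_side must be one of {SIDES}, got {self.correct_side!r}")
        if self.rewarded not in (0, 1):
            raise ValidationError(f"rewarded must be 0 or 1, got {self.rewarded!r}")
        if self.reversal_index < 0:
            raise ValidationError(f"reversal_index must be >= 0, got {self.reversal_index!r}")

    @property
    def is_correct(self) -> bool:
        return self.chosen_side == self.correct_side


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and design labels of one subject-session."""

    subject_id: str
    group: str
    sex: str
    phase: str
    session_index: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.session_index < 1:
            raise ValidationError(f"session_index must be >= 1, got {self.session_index!r}")


@dataclass
class Session:
    """Ordered trials for one subject/phase/session."""

    meta: SubjectMeta
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def key(self) -> tuple[str, str, int]:
        """(subject_id, phase, session_index) — unique session identifier."""
        return (self.meta.subject_id, self.meta.phase, self.meta.session_index)

    def choice_codes(self) -> np.ndarray:
        """Choices as int codes: 0 for L, 1 for R."""
        return np.fromiter((SIDES.index(t.chosen_side) for t in self.trials), dtype=np.int64, count=len(self.trials))

    def correct_codes(self) -> np.ndarray:
        return np.fromiter((SIDES.index(t.correct_side) for t in self.trials), dtype=np.int64, count=len(self.trials))

    def reward_array(self) -> np.ndarray:
        return np.fromiter((t.rewarded for t in self.trials), dtype=np.int64, count=len(self.trials))

    def reversal_array(self) -> np.ndarray:
        return np.fromiter((t.reversal_index for t in self.trials), dtype=np.int64, count=len(self.trials))

    def validate(self, max_trials: int | None = None) -> None:
        """Raise :class:`ValidationError` if any session invariant is broken."""
        for i, t in enumerate(self.trials):
            if t.trial_index != i + 1:
                raise ValidationError(
                    f"session {self.key}: trial_index must be consecutive from 1, "
                    f"got {t.trial_index} at position {i + 1}"
                )
        rev = self.reversal_array()
        if len(rev):
            d = np.diff(rev)
            if np.any(d < 0) or np.any(d > 1):
                pos = int(np.flatnonzero((d < 0) | (d > 1))[0]) + 2
                raise ValidationError(
                    f"session {self.key}: reversal_index must be non-decreasing in steps of "
                    f"at most 1 (violated at trial {pos})"
                )
        if max_trials is not None and len(self.trials) > max_trials:
            raise ValidationError(f"session {self.key}: {len(self.trials)} trials exceeds max {max_trials}")


def check_reversal_consistency(session: Session) -> None:
    """Cross-check the stored reversal_index against correct_side flips.

    The reversal index must increment exactly when (and only when) the
    correct side flips between consecutive trials.
    """
    correct = session.correct_codes()
    rev = session.reversal_array()
    for i in range(1, len(session)):
        flipped = correct[i] != correct[i - 1]
        stepped = rev[i] == rev[i - 1] + 1
        if flipped != stepped:
            raise ValidationError(
                f"session {session.key}: reversal_index and correct_side disagree at trial {i + 1}"
            )


def read_sessions(path: str | Path, max_trials: int | None = None) -> list[Session]:
    """Read a trial-log CSV into validated :class:`Session` objects.

    Sessions are grouped by (subject_id, phase, session_index); row order
    within a session is preserved.  Malformed rows raise
    :class:`ValidationError` naming the 1-based data-row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    sessions: dict[tuple[str, str, int], Session] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        try:
            meta = SubjectMeta(
                subject_id=row.subject_id,
                group=row.group,
                sex=row.sex,
                phase=row.phase,
                session_index=int(row.session_index),
            )
            trial = TrialRecord(
                trial_index=int(row.trial_index),
                chosen_side=row.chosen_side,
                correct_side=row.correct_side,
                rewarded=int(row.rewarded),
                reversal_index=int(row.reversal_index),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {pos}: {exc}") from exc
        key = (meta.subject_id, meta.phase, meta.session_index)
        sessions.setdefault(key, Session(meta)).trials.append(trial)

    out = list(sessions.values())
    for s in out:
        s.validate(max_trials=max_trials)
    return out


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    """Write sessions as a trial-log CSV (inverse of :func:`read_sessions`)."""
    rows = []
    for s in sessions:
        m = s.meta
        for t in s.trials:
            rows.append(
                (m.subject_id, m.group, m.sex, m.phase, m.session_index,
                 t.trial_index, t.chosen_side, t.correct_side, t.rewarded, t.reversal_index)
            )
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(path, index=False)


def filter_to_reversals(session: Session, max_reversals: int = 4) -> Session:
    """Keep the prefix of trials completed before the ``max_reversals``-th flip.

    Retains every trial whose reversal_index is below ``max_reversals`` —
    i.e. everything up to and including the trial that completes reversal
    number ``max_reversals``.  Sessions with fewer reversals pass unchanged.
    """
    if max_reversals < 1:
        raise ValueError("max_reversals must be >= 1")
    kept = [t for t in session.trials if t.reversal_index < max_reversals]
    if len(kept) == len(session.trials):
        return session
    return Session(session.meta, kept)


def select_sessions(sessions: Sequence[Session], per_phase: int = 3) -> list[Session]:
    """Keep, per (subject, phase), only sessions with session_index <= per_phase."""
    if per_phase < 1:
        raise ValueError("per_phase must be >= 1")
    return [s for s in sessions if s.meta.session_index <= per_phase]


def write_measure_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy one-row-per-session measure table.

    Missing values are written as the explicit sentinel ``"NA"``.  Duplicate
    (subject_id, phase, session_index) keys are rejected.
    """
    key_cols = [c for c in MEASURE_KEY_COLUMNS if c in table.columns]
    required = {"subject_id", "phase", "session_index"}
    if not required.issubset(table.columns):
        raise ValueError(f"measure table must contain key columns {sorted(required)}")
    if table.duplicated(subset=["subject_id", "phase", "session_index"]).any():
        raise ValueError("measure table has duplicate (subject_id, phase, session_index) keys")
    value_cols = [c for c in MEASURE_VALUE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in key_cols + value_cols]
    table = table[key_cols + value_cols + extra]
    table.to_csv(path, index=False, na_rep=NA_SENTINEL)


def read_measure_table(path: str | Path) -> pd.DataFrame:
    """Read a measure table written by :func:`write_measure_table`."""
    return pd.read_csv(path, na_values=[NA_SENTINEL], keep_default_na=False)
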