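"""Conventional reversal-learning measures computed per session.

Win-stay / lose-shift are percentages of eligible transitions, split by the
correctness of the PREVIOUS response (probabilistic feedback decouples
reward from correctness, which is what makes the split informative).  A
measure whose conditioning event never occurs is reported missing (NaN),
never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_fitting import FitResult
from .trial_io import (
    MEASURE_KEY_COLUMNS,
    MEASURE_VALUE_COLUMNS,
    Session,
)


@dataclass(frozen=True)
class ConventionalMeasures:
    win_stay_correct: float
    win_stay_incorrect: float
    lose_shift_correct: float
    lose_shift_incorrect: float
    trials_to_criterion: float
    proportion_correct: float
    perseverative_responses: float


def _stay_shift(session: Session, rewarded: int, prev_correct: str, count_stays: bool) -> float:
    if len(session) < 2:
        raise ValueError("need at least 2 trials")
    if prev_correct not in ("correct", "incorrect"):
        raise ValueError("prev_correct must be 'correct' or 'incorrect'")
    want_correct = prev_correct == "correct"
    num = den = 0
    for prev, cur in zip(session.trials, session.trials[1:]):
        if prev.rewarded != rewarded or prev.is_correct != want_correct:
            continue
        den += 1
        stayed = cur.chosen_side == prev.chosen_side
        if stayed == count_stays:
            num += 1
    if den == 0:
        return math.nan
    return 100.0 * num / den


def win_stay(session: Session, prev_correct: str = "correct") -> float:
    """Percent of choices repeating a REWARDED previous choice.

    Eligible transitions are those whose previous trial was rewarded and
    whose previous response was correct/incorrect per ``prev_correct``.
    NaN when no transition qualifies.
    """
    return _stay_shift(session, rewarded=1, prev_correct=prev_correct, count_stays=True)


def lose_shift(session: Session, prev_correct: str = "correct") -> float:
    """Percent of choices switching away from an UNREWARDED previous choice."""
    return _stay_shift(session, rewarded=0, prev_correct=prev_correct, count_stays=False)


def trials_to_criterion(session: Session, include_first_block: bool = True) -> float:
    """Mean number of trials per completed contingency block.

    A block runs from the session start (or a reversal) to the trial that
    completes the consecutive-correct criterion, inclusive.  Blocks are
    delimited by the stored reversal index; the trailing incomplete block is
    ignored.  NaN when no reversal was completed.
    """
    rev = session.reversal_array()
    if len(rev) == 0:
        return math.nan
    n_completed = int(rev[-1])
    if n_completed == 0:
        return math.nan
    counts = np.bincount(rev, minlength=n_completed + 1)[:n_completed]
    if not include_first_block:
        counts = counts[1:]
        if len(counts) == 0:
            return math.nan
    return float(np.mean(counts))


def proportion_correct(session: Session) -> float:
    """Fraction of trials choosing the currently designated correct side."""
    if len(session) == 0:
        raise ValueError("empty session")
    return float(np.mean(session.choice_codes() == session.correct_codes()))


def perseverative_responses(session: Session, per_reversal: bool = False) -> float:
    """Post-reversal choices of the previously correct side before the first
    choice of the new correct side; summed over reversals (or averaged with
    ``per_reversal``)."""
    rev = session.reversal_array()
    if len(rev) == 0 or rev[-1] == 0:
        return 0.0
    choices = session.choice_codes()
    correct = session.correct_codes()
    counts = []
    boundaries = np.flatnonzero(np.diff(rev)) + 1  # first trial of each new block
    for b in boundaries:
        block_rev = rev[b]
        count = 0
        for i in range(b, len(rev)):
            if rev[i] != block_rev:
                break
            if choices[i] == correct[i]:
                break
            count += 1
        counts.append(count)
    if per_reversal:
        return float(np.mean(counts))
    return float(np.sum(counts))


def compute_measures(session: Session) -> ConventionalMeasures:
    """All conventional measures for one session."""
    return ConventionalMeasures(
        win_stay_correct=win_stay(session, "correct"),
        win_stay_incorrect=win_stay(session, "incorrect"),
        lose_shift_correct=lose_shift(session, "correct"),
        lose_shift_incorrect=lose_shift(session, "incorrect"),
        trials_to_criterion=trials_to_criterion(session),
        proportion_correct=proportion_correct(session),
        perseverative_responses=perseverative_responses(session),
    )


def build_measure_table(
    sessions: list[Session],
    fits: list[FitResult] | None = None,
) -> pd.DataFrame:
    """One row per session: RL parameters (from ``fits``, if given) plus the
    conventional measures, in the stable measure-table column order."""
    fit_by_key = {}
    if fits:
        for f in fits:
            fit_by_key[f.session_key] = f
    rows = []
    for s in sessions:
        m = compute_measures(s)
        row = {
            "subject_id": s.meta.subject_id,
            "group": s.meta.group,
            "sex": s.meta.sex,
            "phase": s.meta.phase,
            "session_index": s.meta.session_index,
            "alpha_rew": math.nan,
            "alpha_nonrew": math.nan,
            "beta": math.nan,
            "kappa": math.nan,
            "win_stay_correct": m.win_stay_correct,
            "win_stay_incorrect": m.win_stay_incorrect,
            "lose_shift_correct": m.lose_shift_correct,
            "lose_shift_incorrect": m.lose_shift_incorrect,
            "trials_to_criterion": m.trials_to_criterion,
            "proportion_correct": m.proportion_correct,
            "perseverative_responses": m.perseverative_responses,
        }
        fit = fit_by_key.get(s.key)
        if fit is not None:
            p = fit.params
            row["alpha_rew"] = p.alpha_rew if p.alpha_rew is not None else p.alpha
            row["alpha_nonrew"] = p.alpha_nonrew if p.alpha_nonrew is not None else p.alpha
            row["beta"] = p.beta
            row["kappa"] = p.effective_kappa
        rows.append(row)
    cols = list(MEASURE_KEY_COLUMNS) + list(MEASURE_VALUE_COLUMNS)
    return pd.DataFrame(rows, columns=cols)
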