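"""Simulate the probabilistic reversal task and Q-learning agents.

The simulated task presents two options; choosing the currently "correct"
one is rewarded with probability 0.8 and the "incorrect" one with
probability 0.2 (defaults).  After 8 consecutive correct choices the
designations flip.  "Correct" means choosing the designated side,
irrespective of whether the probabilistic reward was actually delivered;
the consecutive-correct counter resets on any incorrect choice and after a
reversal (a stricter variant that also resets on unrewarded correct choices
is available via ``TaskConfig.criterion_requires_reward``).

Cohorts mirror a 2 (group) x 2 (sex) x 2 (phase) design: each cell maps to
its own agent parameters so group-level parameter shifts can be planted and
later recovered by the fitting stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

from .rl_models import ALPHA_BOUNDS, BETA_BOUNDS, KAPPA_BOUNDS, update_q
from .trial_io import GROUPS, PHASES, SEXES, Session, SubjectMeta, TrialRecord

_PARAM_BOUNDS = {
    "alpha_rew": ALPHA_BOUNDS,
    "alpha_nonrew": ALPHA_BOUNDS,
    "beta": BETA_BOUNDS,
    "kappa": KAPPA_BOUNDS,
}


@dataclass(frozen=True)
class TaskConfig:
    """Reversal-task environment parameters."""

    p_reward_correct: float = 0.8
    p_reward_incorrect: float = 0.2
    reversal_criterion: int = 8
    max_trials: int = 200
    criterion_requires_reward: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_reward_incorrect <= self.p_reward_correct <= 1.0):
            raise ValueError("need 0 <= p_reward_incorrect <= p_reward_correct <= 1")
        if self.reversal_criterion < 1:
            raise ValueError("reversal_criterion must be >= 1")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class AgentParams:
    """Generative agent parameters (split learning rates; q0 per side)."""

    alpha_rew: float
    alpha_nonrew: float
    beta: float
    kappa: float = 0.0
    q0: float = 0.5

    def __post_init__(self) -> None:
        for name, (lo, hi) in _PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def single_alpha(cls, alpha: float, beta: float, kappa: float = 0.0, q0: float = 0.5) -> "AgentParams":
        """Agent with one shared learning rate for both outcomes."""
        return cls(alpha_rew=alpha, alpha_nonrew=alpha, beta=beta, kappa=kappa, q0=q0)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: subjects per cell and per-cell agent parameters.

    ``cell_params`` maps every (group, sex, phase) combination in the design
    to the agent parameters used for subjects in that cell.  With
    ``jitter_sd`` unset, subjects inherit the exact cell values so recovery
    tests have known ground truth; otherwise each subject's parameters are
    drawn from a Gaussian around the cell values, truncated to bounds.
    """

    n_per_cell: int
    sessions_per_phase: int
    cell_params: Mapping[tuple[str, str, str], AgentParams]
    seed: int
    groups: tuple[str, ...] = GROUPS
    sexes: tuple[str, ...] = SEXES
    phases: tuple[str, ...] = PHASES
    jitter_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.sessions_per_phase < 1:
            raise ValueError("sessions_per_phase must be >= 1")
        for cell in itertools.product(self.groups, self.sexes, self.phases):
            if cell not in self.cell_params:
                raise ValueError(f"cell_params missing cell {cell}")


def simulate_session(
    agent: AgentParams,
    task: TaskConfig,
    rng: np.random.Generator,
    meta: SubjectMeta | None = None,
) -> Session:
    """Simulate one session of a Q-learning agent on the reversal task.

    Per trial: the agent picks a side from the softmax over its current
    Q-values (with the stickiness bonus toward its previous choice), reward
    is drawn Bernoulli according to whether the designated correct side was
    chosen, and the chosen side's Q-value is updated with the
    outcome-appropriate learning rate.
    """
    if meta is None:
        meta = SubjectMeta("sim", "control", "female", "pre_stress", 1)
    q_left = q_right = agent.q0
    prev: int | None = None
    correct = int(rng.integers(2))  # 0 = L, 1 = R
    streak = 0
    n_reversals = 0
    trials: list[TrialRecord] = []
    for t in range(1, task.max_trials + 1):
        s = 0.0 if prev is None else (1.0 if prev == 0 else -1.0)
        p_left = float(expit((q_left - q_right) / agent.beta + agent.kappa * s))
        choice = 0 if rng.random() < p_left else 1
        is_correct = choice == correct
        p_r = task.p_reward_correct if is_correct else task.p_reward_incorrect
        r = int(rng.random() < p_r)
        trials.append(
            TrialRecord(
                trial_index=t,
                chosen_side="L" if choice == 0 else "R",
                correct_side="L" if correct == 0 else "R",
                rewarded=r,
                reversal_index=n_reversals,
            )
        )
        a = agent.alpha_rew if r else agent.alpha_nonrew
        if choice == 0:
            q_left = update_q(q_left, a, r)
        else:
            q_right = update_q(q_right, a, r)
        prev = choice
        if is_correct and not (task.criterion_requires_reward and r == 0):
            streak += 1
        else:
            streak = 0
        if streak >= task.reversal_criterion:
            n_reversals += 1
            correct = 1 - correct
            streak = 0
    return Session(meta, trials)


def _jitter(base: AgentParams, sd: float, rng: np.random.Generator) -> AgentParams:
    vals = {}
    for name, (lo, hi) in _PARAM_BOUNDS.items():
        v = getattr(base, name) + rng.normal(0.0, sd)
        vals[name] = float(np.clip(v, lo, hi))
    return replace(base, **vals)


def simulate_cohort(
    design: CohortDesign,
    task: TaskConfig,
    return_truth: bool = False,
):
    """Simulate every subject-session in a cohort design.

    Each subject gets an independent RNG stream spawned from the design seed,
    so runs are reproducible and adding subjects never perturbs earlier ones.
    Returns the sessions, plus a per-(subject, phase) table of true agent
    parameters when ``return_truth`` is set.
    """
    subjects = [
        (group, sex, i)
        for group in design.groups
        for sex in design.sexes
        for i in range(1, design.n_per_cell + 1)
    ]
    streams = np.random.SeedSequence(design.seed).spawn(len(subjects))
    sessions: list[Session] = []
    truth_rows: list[dict] = []
    for (group, sex, i), stream in zip(subjects, streams):
        rng = np.random.default_rng(stream)
        subject_id = f"{group}_{sex}_{i:02d}"
        for phase in design.phases:
            params = design.cell_params[(group, sex, phase)]
            if design.jitter_sd:
                params = _jitter(params, design.jitter_sd, rng)
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "sex": sex,
                    "phase": phase,
                    "alpha_rew": params.alpha_rew,
                    "alpha_nonrew": params.alpha_nonrew,
                    "beta": params.beta,
                    "kappa": params.kappa,
                }
            )
            for si in range(1, design.sessions_per_phase + 1):
                meta = SubjectMeta(subject_id, group, sex, phase, si)
                sessions.append(simulate_session(params, task, rng, meta))
    if return_truth:
        import pandas as pd

        return sessions, pd.DataFrame(truth_rows)
    return sessions
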