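"""Trial-by-trial Q-learning model core for two-choice data.

Three nested model variants share the same machinery:

* ``M_ab``    — one learning rate and a temperature (stickiness fixed at 0).
* ``M_abk``   — adds a choice-autocorrelation ("stickiness") bonus kappa.
* ``M_a2bk``  — splits the learning rate into separate rates for rewarded
  and non-rewarded trials.

The chosen option's value moves toward the outcome by the delta rule
``Q <- Q + alpha * (r - Q)``; the unchosen option is untouched (no
forgetting term).  Choice follows a two-option softmax over ``Q/beta`` with
an additive ``kappa`` bonus on whichever side was chosen on the previous
trial; on the first trial of a session both previous-choice indicators are
zero (sessions are modelled independently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import expit, log_expit

from .trial_io import Session

ALPHA_BOUNDS = (0.001, 1.0)
BETA_BOUNDS = (0.005, 5.0)
KAPPA_BOUNDS = (-1.0, 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: its stable name and free-parameter set."""

    name: str
    free_parameters: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    @property
    def has_kappa(self) -> bool:
        return "kappa" in self.free_parameters

    @property
    def has_split_alpha(self) -> bool:
        return "alpha_rew" in self.free_parameters


M_AB = ModelSpec("M_ab", ("alpha", "beta"))
M_ABK = ModelSpec("M_abk", ("alpha", "beta", "kappa"))
M_A2BK = ModelSpec("M_a2bk", ("alpha_rew", "alpha_nonrew", "beta", "kappa"))

#: registry of the stable model identifiers
MODELS: dict[str, ModelSpec] = {m.name: m for m in (M_AB, M_ABK, M_A2BK)}


@dataclass(frozen=True)
class ModelParams:
    """A value for each free parameter of some :class:`ModelSpec`.

    Unused parameters stay ``None``; ``kappa=None`` acts as 0 so ``M_ab``
    parameter sets evaluate under the shared likelihood code.
    """

    alpha: float | None = None
    alpha_rew: float | None = None
    alpha_nonrew: float | None = None
    beta: float | None = None
    kappa: float | None = None

    def learning_rate(self, rewarded: int) -> float:
        """Learning rate applicable to a trial with the given outcome."""
        if self.alpha_rew is not None or self.alpha_nonrew is not None:
            a = self.alpha_rew if rewarded else self.alpha_nonrew
        else:
            a = self.alpha
        if a is None:
            raise ValueError(f"no learning rate defined on {self}")
        return a

    @property
    def effective_kappa(self) -> float:
        return 0.0 if self.kappa is None else self.kappa

    def validate_for(self, model: ModelSpec) -> None:
        for name in model.free_parameters:
            if getattr(self, name) is None:
                raise ValueError(f"{model.name} requires parameter {name!r}")

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass(frozen=True)
class QState:
    """Per-trial latent state: both Q-values plus the previous choice.

    ``prev_choice`` is ``"L"``, ``"R"`` or ``None`` (first trial); it houses
    the previous-choice indicators of the softmax.
    """

    q_left: float
    q_right: float
    prev_choice: str | None = None

    @property
    def stick_signal(self) -> int:
        """+1 if the previous choice was L, -1 if R, 0 if none."""
        if self.prev_choice is None:
            return 0
        return 1 if self.prev_choice == "L" else -1


def update_q(q: float, alpha: float, r: int) -> float:
    """Delta-rule update of the chosen option's value toward the outcome."""
    return q + alpha * (r - q)


def choice_prob_left(state: QState, beta: float, kappa: float = 0.0) -> float:
    """Softmax probability of choosing left.

    Computed as ``sigmoid((qL - qR)/beta + kappa * s)`` where ``s`` is +1/-1/0
    depending on the previous choice — algebraically the two-option softmax
    over ``Q/beta + kappa * prev-indicator`` and numerically stable for any
    exponent magnitude.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    logit = (state.q_left - state.q_right) / beta + kappa * state.stick_signal
    return float(expit(logit))


def session_loglik(
    params: ModelParams,
    model: ModelSpec,
    session: Session,
    q0: float = 0.5,
) -> float:
    """Log-likelihood of a session's choice sequence under one model.

    Iterates trials in order, accumulating ``log P(observed choice)`` from
    the softmax before applying the delta-rule update to the chosen side
    (rate chosen by outcome under ``M_a2bk``).  Stickiness is fixed at 0
    for ``M_ab``.  Returns the sum of per-trial log-probabilities (<= 0).
    """
    if len(session) == 0:
        raise ValueError("cannot compute the likelihood of an empty session")
    params.validate_for(model)
    beta = params.beta
    if beta is None or beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    kappa = params.effective_kappa if model.has_kappa else 0.0

    q_left = q_right = float(q0)
    prev: int | None = None
    total = 0.0
    for trial in session.trials:
        c = 0 if trial.chosen_side == "L" else 1
        s = 0.0 if prev is None else (1.0 if c == prev else -1.0)
        diff = (q_left - q_right) if c == 0 else (q_right - q_left)
        total += float(log_expit(diff / beta + kappa * s))
        a = params.learning_rate(trial.rewarded)
        if c == 0:
            q_left = update_q(q_left, a, trial.rewarded)
        else:
            q_right = update_q(q_right, a, trial.rewarded)
        prev = c
    return total
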