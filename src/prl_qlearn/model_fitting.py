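"""Exhaustive grid-search maximum-likelihood fitting, per session per model.

The likelihood over the whole grid is evaluated vectorised: the Q-value
trajectory depends only on the learning-rate axes, so for each learning-rate
combination the per-trial chosen-minus-unchosen value difference is computed
once and the temperature/stickiness axes are then broadcast over it.  The
grid optimum is exact — no interpolation or local refinement — so estimates
are grid-quantised.

Ties are broken by first occurrence in lexicographic grid order (axes
ordered alpha_rew, alpha_nonrew, alpha, beta, kappa; values ascending).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit

from .rl_models import MODELS, ModelParams, ModelSpec
from .trial_io import Session

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridAxis:
    """One parameter axis: closed range [lower, upper] stepped from lower."""

    lower: float
    upper: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")

    def values(self, endpoint_rule: str = "half_step") -> np.ndarray:
        """Axis values: lower, lower+step, ... up to the largest <= upper.

        The printed upper bound is appended when the last stepped value falls
        short of it by more than half a step (``"half_step"``, default), always
        (``"always"``), or never (``"never"``).
        """
        n = int(np.floor((self.upper - self.lower) / self.step + 1e-9))
        vals = np.round(self.lower + self.step * np.arange(n + 1), 10)
        if endpoint_rule == "always":
            append = vals[-1] < self.upper
        elif endpoint_rule == "never":
            append = False
        elif endpoint_rule == "half_step":
            append = (self.upper - vals[-1]) > self.step / 2
        else:
            raise ValueError(f"unknown endpoint_rule {endpoint_rule!r}")
        if append:
            vals = np.append(vals, self.upper)
        return vals


@dataclass(frozen=True)
class GridSpec:
    """Search-grid definition for all parameter types.

    Defaults: learning rates stepped by 0.05 on [0.001, 1], temperature by
    0.15 on [0.005, 5], stickiness by 0.1 on [-1, 1].
    """

    alpha: GridAxis = GridAxis(0.001, 1.0, 0.05)
    beta: GridAxis = GridAxis(0.005, 5.0, 0.15)
    kappa: GridAxis = GridAxis(-1.0, 1.0, 0.1)
    endpoint_rule: str = "half_step"

    def axis(self, param: str) -> np.ndarray:
        if param in ("alpha", "alpha_rew", "alpha_nonrew"):
            return self.alpha.values(self.endpoint_rule)
        if param == "beta":
            return self.beta.values(self.endpoint_rule)
        if param == "kappa":
            return self.kappa.values(self.endpoint_rule)
        raise KeyError(param)


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters and maximised log-likelihood for one session."""

    model: ModelSpec
    params: ModelParams
    loglik: float
    n_trials: int
    session_key: tuple[str, str, int]


#: lexicographic ordering of grid axes used for tie-breaking
_AXIS_ORDER = ("alpha_rew", "alpha_nonrew", "alpha", "beta", "kappa")


def build_grid(spec: GridSpec, model: ModelSpec) -> list[ModelParams]:
    """Cartesian product of the model's free-parameter axes, lexicographic."""
    names = [p for p in _AXIS_ORDER if p in model.free_parameters]
    axes = [spec.axis(p) for p in names]
    return [
        ModelParams(**dict(zip(names, map(float, combo))))
        for combo in itertools.product(*axes)
    ]


def _session_arrays(session: Session) -> tuple[np.ndarray, np.ndarray]:
    if len(session) == 0:
        raise ValueError("cannot fit an empty session")
    return session.choice_codes(), session.reward_array()


def _grid_loglik_tensor(
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha_pairs: np.ndarray,
    betas: np.ndarray,
    kappas: np.ndarray,
    q0: float,
) -> np.ndarray:
    """Log-likelihood over the full grid, shape (n_alpha_pairs, n_beta, n_kappa).

    ``alpha_pairs[:, 0]`` is the rewarded-trial rate, ``[:, 1]`` the
    non-rewarded one (equal for single-alpha models).
    """
    n = len(choices)
    n_a = len(alpha_pairs)
    q_left = np.full(n_a, q0, dtype=np.float64)
    q_right = np.full(n_a, q0, dtype=np.float64)
    diff_chosen = np.empty((n_a, n), dtype=np.float64)
    stick = np.empty(n, dtype=np.float64)
    a_rew = alpha_pairs[:, 0]
    a_non = alpha_pairs[:, 1]
    for t in range(n):
        c = choices[t]
        r = rewards[t]
        dq = q_left - q_right
        diff_chosen[:, t] = dq if c == 0 else -dq
        stick[t] = 0.0 if t == 0 else (1.0 if c == choices[t - 1] else -1.0)
        a = a_rew if r == 1 else a_non
        if c == 0:
            q_left = q_left + a * (r - q_left)
        else:
            q_right = q_right + a * (r - q_right)

    # Per-(beta, kappa) slices keep temporaries at (n_a, n) so they stay in
    # cache; in-place ufuncs avoid reallocating them 34*21 times.
    ll = np.empty((n_a, len(betas), len(kappas)), dtype=np.float64)
    scaled = np.empty_like(diff_chosen)
    logits = np.empty_like(diff_chosen)
    for bi, beta in enumerate(betas):
        np.divide(diff_chosen, beta, out=scaled)
        for ki, kappa in enumerate(kappas):
            np.add(scaled, kappa * stick[None, :], out=logits)
            log_expit(logits, out=logits)
            ll[:, bi, ki] = logits.sum(axis=1)
    return ll


def _model_axes(model: ModelSpec, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alpha_pairs, betas, kappas) for the model, in lexicographic order."""
    alphas = grid.axis("alpha")
    if model.has_split_alpha:
        alpha_pairs = np.array(list(itertools.product(alphas, alphas)))
    else:
        alpha_pairs = np.column_stack([alphas, alphas])
    betas = grid.axis("beta")
    kappas = grid.axis("kappa") if model.has_kappa else np.array([0.0])
    return alpha_pairs, betas, kappas


def fit_session(
    session: Session,
    model: ModelSpec,
    grid: GridSpec | None = None,
    q0: float = 0.5,
) -> FitResult:
    """Maximum-likelihood grid fit of one model to one session.

    Evaluates the session log-likelihood at every grid point and returns the
    first-occurring maximiser in lexicographic grid order.
    """
    grid = grid or GridSpec()
    choices, rewards = _session_arrays(session)
    alpha_pairs, betas, kappas = _model_axes(model, grid)
    ll = _grid_loglik_tensor(choices, rewards, alpha_pairs, betas, kappas, q0)
    flat_idx = int(np.argmax(ll))
    ia, ib, ik = np.unravel_index(flat_idx, ll.shape)
    if model.has_split_alpha:
        params = ModelParams(
            alpha_rew=float(alpha_pairs[ia, 0]),
            alpha_nonrew=float(alpha_pairs[ia, 1]),
            beta=float(betas[ib]),
            kappa=float(kappas[ik]),
        )
    else:
        params = ModelParams(
            alpha=float(alpha_pairs[ia, 0]),
            beta=float(betas[ib]),
            kappa=float(kappas[ik]) if model.has_kappa else None,
        )
    return FitResult(
        model=model,
        params=params,
        loglik=float(ll[ia, ib, ik]),
        n_trials=len(session),
        session_key=session.key,
    )


def fit_dataset(
    sessions: Sequence[Session],
    models: Iterable[ModelSpec],
    grid: GridSpec | None = None,
    q0: float = 0.5,
) -> list[FitResult]:
    """Fit every model to every session; one FitResult per pair.

    Deterministic and independent across sessions.  Per-session failures are
    re-raised with the session key attached.
    """
    models = list(models)
    results: list[FitResult] = []
    t0 = time.monotonic()
    total = len(sessions) * len(models)
    done = 0
    for session in sessions:
        for model in models:
            try:
                results.append(fit_session(session, model, grid=grid, q0=q0))
            except Exception as exc:
                raise RuntimeError(
                    f"fitting model {model.name} failed for session {session.key}: {exc}"
                ) from exc
            done += 1
            if done % 50 == 0 or done == total:
                logger.info(
                    "fitted %d/%d session-model pairs (%.1fs)", done, total, time.monotonic() - t0
                )
    return results


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy per-fit table: session key, model, parameters, loglik, n_trials."""
    rows = []
    for f in fits:
        subject_id, phase, session_index = f.session_key
        row = {
            "subject_id": subject_id,
            "phase": phase,
            "session_index": session_index,
            "model": f.model.name,
            "alpha": f.params.alpha,
            "alpha_rew": f.params.alpha_rew,
            "alpha_nonrew": f.params.alpha_nonrew,
            "beta": f.params.beta,
            "kappa": f.params.kappa,
            "loglik": f.loglik,
            "n_trials": f.n_trials,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> list[FitResult]:
    """Inverse of :func:`fits_to_frame` (used by the CLI stages)."""
    fits = []
    for row in df.itertuples(index=False):
        model = MODELS[row.model]
        kwargs = {}
        for name in ("alpha", "alpha_rew", "alpha_nonrew", "beta", "kappa"):
            v = getattr(row, name)
            if v is not None and not pd.isna(v):
                kwargs[name] = float(v)
        fits.append(
            FitResult(
                model=model,
                params=ModelParams(**kwargs),
                loglik=float(row.loglik),
                n_trials=int(row.n_trials),
                session_key=(row.subject_id, row.phase, int(row.session_index)),
            )
        )
    return fits
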