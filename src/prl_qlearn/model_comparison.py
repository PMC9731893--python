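"""Model-comparison measures and winner selection across sessions.

Three measures are computed per session:

* log-likelihood ratio ``d = 2 * (LL2 - LL1)`` between two fitted models;
* pseudo-r2, the likelihood improvement over the chance (P = 0.5 per trial)
  model, scaled so 0 is chance and 1 is perfect prediction;
* BIC in its log-model-evidence form ``LL - (k/2) * log(m)`` with ``k`` free
  parameters and ``m`` trials — LARGER is better under this convention.
  :func:`classical_bic` converts to the usual minimise-``-2LL + k*log(m)``
  form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model_fitting import FitResult

_LOG_HALF = math.log(0.5)


def loglik_ratio(fit1: FitResult, fit2: FitResult) -> float:
    """d = 2 * (loglik2 - loglik1); antisymmetric under argument swap."""
    if fit1.session_key != fit2.session_key:
        raise ValueError(
            f"cannot compare fits of different sessions: {fit1.session_key} vs {fit2.session_key}"
        )
    return 2.0 * (fit2.loglik - fit1.loglik)


def pseudo_r2(fit: FitResult) -> float:
    """Scaled likelihood gain over chance: 0 at chance, 1 at perfect fit."""
    if fit.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return 1.0 - fit.loglik / (fit.n_trials * _LOG_HALF)


def bic_score(fit: FitResult) -> float:
    """Penalised log-likelihood ``LL - (k/2) log(m)``; larger is better."""
    if fit.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = fit.model.n_free
    return fit.loglik - 0.5 * k * math.log(fit.n_trials)


def classical_bic(fit: FitResult) -> float:
    """Conventional BIC ``-2 LL + k log(m)``; smaller is better."""
    return -2.0 * bic_score(fit)


@dataclass(frozen=True)
class ModelSelection:
    """Comparison table plus the overall winner by mean BIC."""

    table: pd.DataFrame
    overall_winner: str
    mean_bic: dict[str, float]


def select_model(fits: list[FitResult]) -> ModelSelection:
    """Per-session and overall model comparison.

    Every session must be fitted under every model present.  The per-session
    winner maximises the BIC score; the overall winner maximises mean BIC
    across sessions.  The table also carries pseudo-r2 per model and the
    pairwise d statistics.
    """
    by_session: dict[tuple, dict[str, FitResult]] = {}
    model_names: list[str] = []
    for f in fits:
        if f.model.name not in model_names:
            model_names.append(f.model.name)
        entry = by_session.setdefault(f.session_key, {})
        entry[f.model.name] = f
    for key, entry in by_session.items():
        missing = [m for m in model_names if m not in entry]
        if missing:
            raise ValueError(f"session {key} missing fits for models {missing}")

    rows = []
    for key in by_session:
        entry = by_session[key]
        subject_id, phase, session_index = key
        row: dict = {
            "subject_id": subject_id,
            "phase": phase,
            "session_index": session_index,
            "n_trials": entry[model_names[0]].n_trials,
        }
        for m in model_names:
            row[f"loglik_{m}"] = entry[m].loglik
            row[f"pseudo_r2_{m}"] = pseudo_r2(entry[m])
            row[f"bic_{m}"] = bic_score(entry[m])
        for i, m1 in enumerate(model_names):
            for m2 in model_names[i + 1 :]:
                row[f"d_{m2}_vs_{m1}"] = loglik_ratio(entry[m1], entry[m2])
        row["winner"] = max(model_names, key=lambda m: row[f"bic_{m}"])
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_bic = {m: float(table[f"bic_{m}"].mean()) for m in model_names}
    overall = max(model_names, key=lambda m: mean_bic[m])
    return ModelSelection(table=table, overall_winner=overall, mean_bic=mean_bic)
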