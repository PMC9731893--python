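"""End-to-end run orchestration: simulate (or load) -> filter -> fit ->
compare -> measures -> correlate -> recovery report, under one master seed.

All stochastic stages derive their RNG streams from the master seed, so a
run directory is reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral_measures import build_measure_table
from .model_comparison import select_model
from .model_fitting import FitResult, GridAxis, GridSpec, fit_dataset, fits_to_frame
from .rl_models import MODELS, ModelSpec
from .stats_correlation import normality_screen, pearson_matrix, subject_means
from .synthetic_data import AgentParams, CohortDesign, TaskConfig, simulate_cohort
from .trial_io import (
    filter_to_reversals,
    read_sessions,
    select_sessions,
    write_measure_table,
    write_sessions,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    design: CohortDesign | None = None
    input_path: str | None = None
    max_reversals: int | None = 4
    sessions_per_phase: int | None = 3
    models: tuple[str, ...] = ("M_ab", "M_abk", "M_a2bk")
    grid: GridSpec = field(default_factory=GridSpec)
    q0: float = 0.5
    fdr: float = 0.05
    measure_model: str = "M_a2bk"

    def __post_init__(self) -> None:
        if self.design is None and self.input_path is None:
            raise ValueError("config needs either a cohort design or an input file")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        if self.measure_model not in self.models:
            raise ValueError("measure_model must be one of the fitted models")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        task = TaskConfig(**raw.get("task", {}))
        design = None
        if "cohort" in raw and raw["cohort"]:
            design = _design_from_dict(raw["cohort"], seed)
        grid_raw = raw.get("grid", {})
        grid_kwargs = {}
        for name in ("alpha", "beta", "kappa"):
            if name in grid_raw:
                lo, hi, step = grid_raw[name]
                grid_kwargs[name] = GridAxis(lo, hi, step)
        if "endpoint_rule" in grid_raw:
            grid_kwargs["endpoint_rule"] = grid_raw["endpoint_rule"]
        filters = raw.get("filters", {})
        models = tuple(raw.get("models", ("M_ab", "M_abk", "M_a2bk")))
        return cls(
            seed=seed,
            task=task,
            design=design,
            input_path=raw.get("input"),
            max_reversals=filters.get("max_reversals", 4),
            sessions_per_phase=filters.get("sessions_per_phase", 3),
            models=models,
            grid=GridSpec(**grid_kwargs),
            q0=float(raw.get("q0", 0.5)),
            fdr=float(raw.get("fdr", 0.05)),
            measure_model=raw.get("measure_model", models[-1]),
        )


def _design_from_dict(raw: dict, seed: int) -> CohortDesign:
    groups = tuple(raw.get("groups", ("control", "MS")))
    sexes = tuple(raw.get("sexes", ("female", "male")))
    phases = tuple(raw.get("phases", ("pre_stress", "post_stress")))
    default = dict(raw.get("default_params", {}))
    cell_params = {}
    for cell in [(g, s, p) for g in groups for s in sexes for p in phases]:
        cell_params[cell] = dict(default)
    for ov in raw.get("overrides", []):
        ov = dict(ov)
        sel_g = ov.pop("group", None)
        sel_s = ov.pop("sex", None)
        sel_p = ov.pop("phase", None)
        for (g, s, p) in cell_params:
            if (sel_g in (None, g)) and (sel_s in (None, s)) and (sel_p in (None, p)):
                cell_params[(g, s, p)].update(ov)
    return CohortDesign(
        n_per_cell=int(raw.get("n_per_cell", 4)),
        sessions_per_phase=int(raw.get("sessions_per_phase", 3)),
        cell_params={k: AgentParams(**v) for k, v in cell_params.items()},
        seed=int(raw.get("seed", seed)),
        groups=groups,
        sexes=sexes,
        phases=phases,
        jitter_sd=raw.get("jitter_sd"),
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def recovery_report(truth: pd.DataFrame, fits: list[FitResult], grid: GridSpec | None = None) -> pd.DataFrame:
    """Per-parameter recovery summary: bias, median absolute error (raw and
    in grid steps) and fitted-vs-true Pearson r (NaN when truth is constant).

    ``truth`` has one row per (subject_id, phase) with true parameter columns;
    fitted values are averaged over each subject-phase's sessions.
    """
    if truth is None or len(truth) == 0:
        raise ValueError("no ground truth available for recovery report")
    fit_rows = []
    for f in fits:
        subject_id, phase, _ = f.session_key
        p = f.params
        fit_rows.append(
            {
                "subject_id": subject_id,
                "phase": phase,
                "alpha_rew": p.alpha_rew if p.alpha_rew is not None else p.alpha,
                "alpha_nonrew": p.alpha_nonrew if p.alpha_nonrew is not None else p.alpha,
                "beta": p.beta,
                "kappa": p.effective_kappa,
            }
        )
    fitted = pd.DataFrame(fit_rows).groupby(["subject_id", "phase"], as_index=False).mean()
    merged = truth.merge(fitted, on=["subject_id", "phase"], suffixes=("_true", "_fit"))
    if len(merged) == 0:
        raise ValueError("ground truth and fits share no (subject_id, phase) keys")
    grid = grid or GridSpec()
    steps = {"alpha_rew": grid.alpha.step, "alpha_nonrew": grid.alpha.step,
             "beta": grid.beta.step, "kappa": grid.kappa.step}
    rows = []
    for param, step in steps.items():
        t = merged[f"{param}_true"].to_numpy(dtype=float)
        f_ = merged[f"{param}_fit"].to_numpy(dtype=float)
        err = f_ - t
        if np.std(t) == 0 or np.std(f_) == 0:
            r = math.nan
        else:
            r = float(np.corrcoef(t, f_)[0, 1])
        rows.append(
            {
                "parameter": param,
                "n": len(err),
                "bias": float(np.mean(err)),
                "median_abs_error": float(np.median(np.abs(err))),
                "median_abs_error_steps": float(np.median(np.abs(err)) / step),
                "pearson_r": r,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.input_path is not None:
        sessions = _stage("load")(read_sessions)(config.input_path)
        source = "external input"
    else:
        sessions, truth = _stage("simulate")(simulate_cohort)(config.design, config.task, return_truth=True)
        source = "simulated"
    write_sessions(sessions, outdir / "sessions.csv")

    @_stage("filter")
    def _filter(sessions):
        if config.sessions_per_phase is not None:
            sessions = select_sessions(sessions, per_phase=config.sessions_per_phase)
        if config.max_reversals is not None:
            sessions = [filter_to_reversals(s, config.max_reversals) for s in sessions]
        return sessions

    filtered = _filter(sessions)
    write_sessions(filtered, outdir / "sessions_filtered.csv")

    models = [MODELS[m] for m in config.models]
    fits = _stage("fit")(fit_dataset)(filtered, models, grid=config.grid, q0=config.q0)
    fits_to_frame(fits).to_csv(outdir / "fits.csv", index=False)

    selection = _stage("compare")(select_model)(fits)
    selection.table.to_csv(outdir / "comparison.csv", index=False)
    logger.info("overall winner by mean BIC: %s", selection.overall_winner)

    measure_fits = [f for f in fits if f.model.name == config.measure_model]
    table = _stage("measures")(build_measure_table)(filtered, measure_fits)
    write_measure_table(table, outdir / "measures.csv")

    @_stage("correlate")
    def _correlate(table):
        agg = subject_means(table)
        normality_screen(agg).to_csv(outdir / "normality.csv", index=False)
        corr = pearson_matrix(agg, q=config.fdr)
        corr.to_long().to_csv(outdir / "corr.csv", index=False)
        return corr

    _correlate(table)

    if truth is not None:
        report = _stage("recovery")(recovery_report)(truth, measure_fits, config.grid)
        report.to_csv(outdir / "recovery_report.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)

    manifest = {
        "seed": config.seed,
        "source": source,
        "models": list(config.models),
        "measure_model": config.measure_model,
        "max_reversals": config.max_reversals,
        "sessions_per_phase": config.sessions_per_phase,
        "q0": config.q0,
        "fdr": config.fdr,
        "overall_winner": selection.overall_winner,
        "n_sessions": len(filtered),
        "versions": {
            "prl_qlearn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
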