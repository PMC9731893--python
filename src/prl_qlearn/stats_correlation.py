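"""Pearson correlations between RL parameters and conventional measures,
with Shapiro-Wilk normality screening and Benjamini-Hochberg FDR control.

By default the analysis operates on per-subject means (sessions averaged
within subject); a per-session variant is available through
:func:`pearson_matrix` directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: default column set correlated against each other
DEFAULT_COLUMNS = (
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


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r/p matrices with per-pair n and FDR flags."""

    columns: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    q: float

    def to_long(self) -> pd.DataFrame:
        """Long-format table of the unique off-diagonal pairs."""
        rows = []
        for i, a in enumerate(self.columns):
            for b in self.columns[i + 1 :]:
                rows.append(
                    {
                        "measure_1": a,
                        "measure_2": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "p_adjusted": self.p_adjusted.loc[a, b],
                        "significant": bool(self.significant.loc[a, b]),
                        "n": int(self.n.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def fdr_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values).

    NaN p-values are excluded from the procedure and stay NaN/not-significant.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        rej, adj, _, _ = multipletests(p[mask], alpha=q, method="fdr_bh")
        reject[mask] = rej
        adjusted[mask] = adj
    return reject, adjusted


def subject_means(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Average the measure columns within subject (across phases/sessions)."""
    columns = [c for c in (columns or DEFAULT_COLUMNS) if c in table.columns]
    return table.groupby("subject_id", as_index=False)[columns].mean()


def pearson_matrix(table: pd.DataFrame, columns=None, q: float = 0.05) -> CorrelationMatrix:
    """Pairwise Pearson correlations with pairwise deletion of missing rows.

    Pairs with fewer than 3 complete observations or a constant column get
    NaN r/p (flagged missing, not an error).  FDR adjustment is applied
    across the unique off-diagonal pairs.
    """
    columns = [c for c in (columns or DEFAULT_COLUMNS) if c in table.columns]
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = table[columns[i]].notna().sum()
    for i in range(k):
        for j in range(i + 1, k):
            x = table[columns[i]].to_numpy(dtype=float)
            y = table[columns[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue

    iu = np.triu_indices(k, 1)
    reject_flat, adjusted_flat = fdr_adjust(p[iu], q=q)
    p_adj = np.full((k, k), np.nan)
    sig = np.zeros((k, k), dtype=bool)
    p_adj[iu] = adjusted_flat
    sig[iu] = reject_flat
    p_adj = np.where(np.isnan(p_adj), p_adj.T, p_adj)
    sig = sig | sig.T

    def frame(a):
        return pd.DataFrame(a, index=columns, columns=columns)

    return CorrelationMatrix(
        columns=list(columns),
        r=frame(r),
        p=frame(p),
        n=frame(n),
        p_adjusted=frame(p_adj),
        significant=frame(sig),
        q=q,
    )


def normality_screen(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Shapiro-Wilk statistic and p per measure column.

    Columns with fewer than 3 non-missing values are skipped with a warning
    (NaN row); columns failing at 0.05 are logged before any correlation is
    reported.
    """
    columns = [c for c in (columns or DEFAULT_COLUMNS) if c in table.columns]
    rows = []
    for c in columns:
        x = table[c].dropna().to_numpy(dtype=float)
        if len(x) < 3:
            logger.warning("normality screen skipped for %r: only %d values", c, len(x))
            rows.append({"measure": c, "W": np.nan, "p": np.nan, "n": len(x)})
            continue
        res = stats.shapiro(x)
        if res.pvalue < 0.05:
            logger.warning(
                "measure %r fails Shapiro-Wilk normality (W=%.4f, p=%.4g)", c, res.statistic, res.pvalue
            )
        rows.append({"measure": c, "W": float(res.statistic), "p": float(res.pvalue), "n": len(x)})
    return pd.DataFrame(rows)
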