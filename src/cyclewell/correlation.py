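"""Spearman rank-correlation screen across the monitored variables.

Computes a pairwise-complete Spearman correlation matrix over the daily
variables (self-reported performance, wellness scores, sleep duration and
bedtime, daily symptom burden, pain intensity, coach evaluation) with
per-pair significance at alpha = 0.05. The variables have very different
missingness (coach scores are sparse), hence pairwise-complete deletion with
per-cell n. Cells with large n use the t approximation for the p-value;
small cells (n < 30) fall back to a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DailyRecord, records_to_frame

__all__ = [
    "DEFAULT_VARIABLES",
    "CorrelationMatrix",
    "daily_symptom_burden",
    "spearman_rho",
    "spearman_matrix",
]

DEFAULT_VARIABLES = (
    "self_performance",
    "rpe",
    "sleep_quality",
    "fitness",
    "mood",
    "sleep_duration",
    "bedtime",
    "n_symptoms",
    "pain_intensity",
    "coach_performance",
)


def daily_symptom_burden(record: DailyRecord) -> int:
    """Number of distinct symptoms declared that day (set semantics)."""
    return len(record.symptoms)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho / p-value matrices with per-cell n.

    Cells with fewer than ``min_n`` complete pairs (or a constant variable)
    are indeterminate: rho and p are NaN and the cell is not significant.
    """

    variables: tuple[str, ...]
    rho: np.ndarray
    p_values: np.ndarray
    n_pairs: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.p_values < self.alpha) & ~np.isnan(self.p_values)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: var_a, var_b, rho, p, n, significant."""
        rows = []
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables):
                if j <= i:
                    continue
                rows.append(
                    dict(
                        var_a=a,
                        var_b=b,
                        rho=self.rho[i, j],
                        p=self.p_values[i, j],
                        n=int(self.n_pairs[i, j]),
                        significant=bool(self.significant[i, j]),
                    )
                )
        return pd.DataFrame(rows)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average-tie-corrected ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _t_approx_p(rho: float, n: int) -> float:
    """Two-sided p from the large-sample t approximation."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value on rank correlations."""
    rx = stats.rankdata(x) - stats.rankdata(x).mean()
    ry = stats.rankdata(y) - stats.rankdata(y).mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return np.nan
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if abs((rx @ perm) / denom) >= abs(rho_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def spearman_matrix(
    records: Sequence[DailyRecord] | pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    alpha: float = 0.05,
    min_n: int = 4,
    perm_threshold: int = 30,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix with significance.

    Daily symptom burden enters as ``n_symptoms`` (count of distinct
    declared symptoms). Cells whose complete-pair count is below
    ``perm_threshold`` get an exact-style permutation p-value
    (``n_permutations`` draws, seeded); larger cells use the t
    approximation. Cells with fewer than ``min_n`` pairs or zero rank
    variance are indeterminate (NaN).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in data: {missing}")
    data = df[list(variables)].to_numpy(dtype=float)
    k = len(variables)
    rho = np.eye(k)
    pvals = np.zeros((k, k))
    npairs = np.zeros((k, k), dtype=int)
    rng = np.random.default_rng(seed)
    for i in range(k):
        npairs[i, i] = int((~np.isnan(data[:, i])).sum())
        for j in range(i + 1, k):
            mask = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
            n = int(mask.sum())
            npairs[i, j] = npairs[j, i] = n
            if n < min_n:
                r, p = np.nan, np.nan
            else:
                x, y = data[mask, i], data[mask, j]
                r = spearman_rho(x, y)
                if np.isnan(r):
                    p = np.nan
                elif n < perm_threshold:
                    p = _permutation_p(x, y, r, n_permutations, rng)
                else:
                    p = _t_approx_p(r, n)
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return CorrelationMatrix(
        variables=tuple(variables),
        rho=rho,
        p_values=pvals,
        n_pairs=npairs,
        alpha=alpha,
    )
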