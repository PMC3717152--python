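"""Rank statistics for quality-metric vs RMSD correlation analysis.

A model's built-in quality scores (geometry factors, Z-scores, energies,
DOPE) would be useful for model selection only if they track the model's
actual deviation from the crystal structure. This module quantifies that
with Spearman rank correlation of each metric column against the RMSD
column, raw two-sided p-values, and a Holm step-down family-wise
adjustment across the metric family.

Rho is computed on raw values versus RMSD values (not direction-folded), so
the sign of rho carries the metric's orientation; the per-metric "better"
direction is carried alongside for interpretation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .structure_io import MetricTable

__all__ = [
    "CorrelationReport",
    "spearman",
    "spearman_pvalue",
    "holm_adjust",
    "qc_rmsd_correlation",
]


@dataclass
class MetricCorrelation:
    metric: str
    rho: float
    p_raw: float
    p_adjusted: float
    n: int
    direction: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"{self.metric}: rho out of [-1, 1]")
        if self.p_adjusted + 1e-15 < self.p_raw:
            raise ValueError(f"{self.metric}: adjusted p below raw p")


@dataclass
class CorrelationReport:
    entries: list[MetricCorrelation]
    rmsd_column: str = "RMSD"

    def rho_of(self, metric: str) -> float:
        for e in self.entries:
            if e.metric == metric:
                return e.rho
        raise KeyError(metric)

    def rounded(self, ndigits: int = 2) -> dict[str, dict[str, float]]:
        return {
            e.metric: {
                "rho": round(e.rho, ndigits),
                "p_raw": round(e.p_raw, 3),
                "p_adjusted": round(e.p_adjusted, 3),
            }
            for e in self.entries
        }


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of average-ranked values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    rx = rx - rx.mean()
    ry = ry - ry.mean(axis=-1, keepdims=True)
    num = ry @ rx
    den = math.sqrt(float(rx @ rx)) * np.sqrt(np.sum(ry * ry, axis=-1))
    return num / den


def spearman_pvalue(
    rho: float,
    n: int,
    method: Literal["t_approx", "exact_permutation"] = "t_approx",
    n_montecarlo: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    ``t_approx`` uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom. ``exact_permutation`` enumerates all n! rank permutations for
    n <= 10 and falls back to seeded Monte-Carlo sampling beyond that.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    if method == "t_approx":
        if abs(rho) >= 1.0:
            return float(np.finfo(float).tiny)  # |rho| = 1: underflow clamp
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * sps.t.sf(abs(t), df=n - 2))
    if method == "exact_permutation":
        ranks = np.arange(1, n + 1, dtype=float)
        target = abs(rho) - 1e-12
        if n <= 10:
            count = total = 0
            perm_iter = itertools.permutations(range(n))
            while True:
                chunk = np.array(list(itertools.islice(perm_iter, 50_000)))
                if chunk.size == 0:
                    break
                rhos = _rho_from_ranks(ranks, ranks[chunk])
                count += int(np.sum(np.abs(rhos) >= target))
                total += len(chunk)
            return count / total
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_montecarlo)])
        rhos = _rho_from_ranks(ranks, ranks[perms])
        # add-one correction keeps the estimate in (0, 1]
        return (1 + int(np.sum(np.abs(rhos) >= target))) / (n_montecarlo + 1)
    raise ValueError(f"unknown method {method!r}")


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sorted ascending, the i-th smallest p is multiplied by (m - i + 1), a
    running maximum is enforced, values are capped at 1 and returned in the
    original order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return np.asarray(multipletests(p, method="holm")[1], float)


def qc_rmsd_correlation(
    table: MetricTable,
    pvalue_method: Literal["t_approx", "exact_permutation"] = "t_approx",
) -> CorrelationReport:
    """Correlate every metric column against the RMSD column.

    Raw p-values are Holm-adjusted across the metric family; the RMSD
    self-correlation is not part of the family.
    """
    if table.rmsd_column not in table.data.columns:
        raise ValueError(f"table has no RMSD column {table.rmsd_column!r}")
    rmsd = table.data[table.rmsd_column].to_numpy(float)
    n = len(rmsd)
    metrics = table.metric_columns
    rhos = [spearman(table.data[m].to_numpy(float), rmsd) for m in metrics]
    p_raw = [spearman_pvalue(r, n, method=pvalue_method) for r in rhos]
    p_adj = holm_adjust(p_raw)
    entries = [
        MetricCorrelation(
            metric=m,
            rho=r,
            p_raw=p,
            p_adjusted=float(pa),
            n=n,
            direction=table.directions.get(m),
        )
        for m, r, p, pa in zip(metrics, rhos, p_raw, p_adj)
    ]
    return CorrelationReport(entries=entries, rmsd_column=table.rmsd_column)
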