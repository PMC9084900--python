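"""Host-symbiont co-occurrence screening across community samples.

The coverage of each taxon marker in each sample is derived from assembler
kmer coverage, normalized to sequencing depth, and screened for association
with the symbiont marker column using Spearman's rank correlation with
midranks for ties, with Benjamini-Hochberg correction across all column
pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def kmer_to_total_coverage(c_k: float, k: int, r: int) -> float:
    """Total read coverage from kmer coverage: C = C_K * R / (R - K + 1)."""
    if c_k < 0:
        raise ValueError("kmer coverage must be nonnegative")
    if not (1 <= k <= r):
        raise ValueError(f"require 1 <= k <= r, got k={k}, r={r}")
    return c_k * r / (r - k + 1)


@dataclass
class AbundanceMatrix:
    """Sample-by-taxon abundance table with optional per-sample read totals."""

    values: pd.DataFrame
    read_totals: Optional[pd.Series] = None

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate column ids")
        if (self.values.fillna(0) < 0).any().any():
            raise ValueError("negative abundance values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)


def normalize_matrix(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample's row to coverage per million sequenced reads."""
    if matrix.read_totals is None:
        raise ValueError("read totals required for normalization")
    totals = matrix.read_totals.reindex(matrix.values.index)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"missing read totals for samples: {missing}")
    if (totals <= 0).any():
        raise ValueError("read totals must be positive")
    return AbundanceMatrix(
        values=matrix.values.div(totals, axis=0) * 1e6, read_totals=matrix.read_totals
    )


def spearman_midrank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Spearman's rho with midranks for ties, over pairwise-complete pairs.

    Returns (rho, two-sided p from the t approximation on n-2 df, n used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateInputError("constant vector after ranking; rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p, n


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclass
class AssociationResult:
    pair: tuple[str, str]
    rho: float
    p_raw: float
    p_adj: float
    n_used: int


def correlation_matrix(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Symmetric Spearman rho matrix with a unit diagonal; degenerate columns
    hold NaN off-diagonal."""
    cols = matrix.taxa
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        try:
            r, _, _ = spearman_midrank(matrix.values[a], matrix.values[b])
        except DegenerateInputError:
            r = np.nan
        rho.loc[a, b] = rho.loc[b, a] = r
    return rho


def association_screen(
    matrix: AbundanceMatrix, symbiont_column: str
) -> list[AssociationResult]:
    """All pairwise Spearman tests with BH correction across every pair.

    Degenerate (constant-rank) pairs are excluded with a logged reason.
    Results are ordered with symbiont-involving pairs first, by rho
    descending, then the remaining pairs by rho descending.
    """
    cols = matrix.taxa
    if symbiont_column not in cols:
        raise ValueError(f"symbiont column {symbiont_column!r} not in matrix")
    if len(cols) < 3:
        raise ValueError("need the symbiont column plus at least 2 other columns")
    results: list[AssociationResult] = []
    for a, b in combinations(cols, 2):
        try:
            rho, p, n = spearman_midrank(matrix.values[a], matrix.values[b])
        except (DegenerateInputError, ValueError) as exc:
            logger.info("pair (%s, %s) excluded: %s", a, b, exc)
            continue
        results.append(AssociationResult(pair=(a, b), rho=rho, p_raw=p, p_adj=np.nan, n_used=n))
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, padj in zip(results, adjusted):
        r.p_adj = float(padj)
    results.sort(
        key=lambda r: (symbiont_column not in r.pair, -r.rho)
    )
    return results
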