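"""Nonparametric group tests and Bliss drug-synergy scoring.

Group comparisons between locus sets (rpk or fold-change distributions) use
rank-based tests: Mann-Whitney U for two groups and Kruskal-Wallis for more.
Small tieless Mann-Whitney samples (n1 + n2 <= 12) use exact enumeration of
the permutation null; larger or tied samples use the normal approximation
with tie and continuity corrections.  These wrap the scipy implementations
behind a contract that fixes method selection and degenerate-input handling.

Drug combinations are scored against Bliss independence: the expected
combined inhibition of two independently acting drugs is
``E_a + E_b - E_a * E_b``; the synergy score is the observed excess in
percentage points (x100, the SynergyFinder convention), so additive
combinations score ~0 and a +0.10 excess scores 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "DoseGrid",
    "BlissResult",
    "EXACT_MAX_N",
    "mann_whitney_u",
    "kruskal_wallis",
    "pearson_r2",
    "bliss_synergy",
    "bh_fdr",
]

EXACT_MAX_N = 12  # exact enumeration limit for Mann-Whitney


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], two_sided: bool = True
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    Exact permutation p-value when n1 + n2 <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    The reported U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    exact = len(x) + len(y) <= EXACT_MAX_N and not _has_ties(np.r_[x, y])
    method = "exact" if exact else "asymptotic"
    res = _sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided" if two_sided else "greater",
        method=method,
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        method=f"mann-whitney-u/{method}",
        n=(len(x), len(y)),
        two_sided=two_sided,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-squared p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # scipy refuses the all-identical case
        return TestResult(
            statistic=0.0,
            p_value=1.0,
            method="kruskal-wallis",
            n=tuple(len(a) for a in arrays),
        )
    res = _sps.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kruskal-wallis",
        n=tuple(len(a) for a in arrays),
    )


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = _sps.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class DoseGrid:
    """Observed inhibition in [0, 1] on a dose_a x dose_b grid.

    Rows are doses of drug A, columns doses of drug B; the dose-0 row and
    column are the single-agent margins the Bliss expectation is built from.
    """

    values: pd.DataFrame  # index: doses of A, columns: doses of B

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(float)
        self.values.columns = self.values.columns.astype(float)
        self.values = self.values.sort_index().sort_index(axis=1)
        if 0.0 not in self.values.index or 0.0 not in self.values.columns:
            raise ValueError("dose grid must include the dose-0 margins")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DoseGrid":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "dose_a"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class BlissResult:
    """Per-combination Bliss excess scores (percentage points) and their mean."""

    scores: pd.DataFrame
    mean_score: float


def bliss_synergy(grid: DoseGrid, clip: bool = False) -> BlissResult:
    """Score each dose combination against Bliss independence.

    expected = E_a + E_b - E_a*E_b from the single-agent margins;
    score = (observed - expected) * 100.  The mean is taken over all
    combinations with both doses nonzero.
    """
    values = grid.values.to_numpy(dtype=float)
    if clip:
        values = np.clip(values, 0.0, 1.0)
    elif np.any(values < 0) or np.any(values > 1):
        raise ValueError("inhibition values outside [0, 1]; pass clip=True to clip")
    a0 = int(np.flatnonzero(grid.values.index == 0.0)[0])
    b0 = int(np.flatnonzero(grid.values.columns == 0.0)[0])
    e_a = values[:, b0]  # drug A alone, per A dose
    e_b = values[a0, :]  # drug B alone, per B dose
    expected = e_a[:, None] + e_b[None, :] - e_a[:, None] * e_b[None, :]
    scores = (values - expected) * 100.0
    combo = np.ones_like(scores, dtype=bool)
    combo[a0, :] = False
    combo[:, b0] = False
    mean_score = float(scores[combo].mean()) if combo.any() else float("nan")
    frame = pd.DataFrame(scores, index=grid.values.index, columns=grid.values.columns)
    return BlissResult(scores=frame, mean_score=mean_score)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
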