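"""Group-level comparison of per-foot risk-region areas across conditions.

Each foot contributes one total R-ROI area (cm²) per insole condition,
giving a repeated-measures design with feet as subjects.  Because area
distributions are heavily non-normal (many exact zeros from optimally
offloaded feet), the comparison is nonparametric:

1. Friedman test across the k conditions (midranks, tie correction);
2. all pairwise Wilcoxon signed-rank tests at a Bonferroni-corrected level
   α_family / n_pairs (0.05/3 ≈ 0.016667 for three conditions);
3. descriptives (mean, SD, median, max) and the count of "optimal" feet —
   those whose risk region was removed entirely (area exactly 0).

Mean differences are reported alongside the rank-based p-values, as is
conventional in this literature; note that means, not rank statistics, are
being differenced.

`AreaComparison` is the model-style entry point:
``AreaComparison.from_csv("areas.csv", ["FI", "TCCI", "CADCAM"]).fit()``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AreaTable, read_area_table

__all__ = [
    "PairwiseResult",
    "GroupComparison",
    "ConditionDescriptives",
    "friedman_test",
    "wilcoxon_signed_rank",
    "compare_conditions",
    "count_optimal",
    "descriptives",
    "AreaComparison",
    "AreaComparisonResults",
]


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p: float
    mean_difference_cm2: float  # mean(condition1) - mean(condition2)
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    k: int
    n: int
    friedman_chi2: float
    friedman_df: int
    friedman_p: float
    pairwise: tuple[PairwiseResult, ...]
    alpha_family: float
    alpha_pairwise: float


@dataclass(frozen=True)
class ConditionDescriptives:
    """Per-condition mean/sd/median/max of areas, cm²."""

    table: pd.DataFrame  # index: condition; columns: mean, sd, median, max


def _friedman_chi2(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for an (n, k) value matrix.

    Midranks within rows; the classic statistic divided by the tie
    correction 1 − Σ(t³ − t) / (n·k·(k² − 1)).
    """
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c == 0:  # every row entirely tied
        return 0.0
    return float(chi2 / c)


def _friedman_exact_p(matrix: np.ndarray) -> float:
    """Exact permutation p: enumerate all within-row rank permutations."""
    import itertools as _it

    n, k = matrix.shape
    if math.factorial(k) ** n > 2_000_000:
        raise ValueError("table too large for exact enumeration")
    obs = _friedman_chi2(matrix)
    # chi2 depends on the rows only through their (midrank) vectors and the
    # per-row tie correction, both invariant under within-row permutation,
    # so enumerate permuted rank vectors and score column sums directly.
    row_ranks = [stats.rankdata(row) for row in matrix]
    ties = sum(
        float(np.sum(c**3 - c))
        for row in matrix
        for c in [np.unique(row, return_counts=True)[1]]
    )
    corr = 1.0 - ties / (n * k * (k * k - 1))
    if corr == 0:
        return 1.0
    sums = np.zeros((1, k))
    for r in row_ranks:
        # keep duplicate rank vectors: the null is uniform over the k!
        # value permutations, not over distinct rank vectors
        perms = np.array(list(_it.permutations(r)), dtype=float)
        sums = (sums[:, None, :] + perms[None, :, :]).reshape(-1, k)
    chi2_all = (12.0 / (n * k * (k + 1)) * np.sum(sums**2, axis=1)
                - 3.0 * n * (k + 1)) / corr
    return float(np.mean(chi2_all >= obs - 1e-9))


def friedman_test(
    table: AreaTable, conditions: Sequence[str], method: str = "approx"
) -> tuple[float, int, float]:
    """Friedman test across conditions (rows = feet).

    ``method="approx"`` (default) uses midranks within rows and the
    tie-corrected chi-square approximation — accurate in the significant
    tail where this framework operates, but anti-conservative for mid-range
    p at small n; ``method="exact"`` enumerates the within-row permutation
    null (feasible for small tables).  Returns ``(chi2, df, p)``.  Rows
    with any missing value for the requested conditions are an error, not
    silently dropped.
    """
    data = table.require_complete(conditions)
    if len(data) < 2 or len(conditions) < 2:
        raise ValueError("need at least 2 complete rows and 2 conditions")
    matrix = data[list(conditions)].to_numpy(float)
    df = len(conditions) - 1
    chi2 = _friedman_chi2(matrix)
    if method == "exact":
        return chi2, df, _friedman_exact_p(matrix)
    if method != "approx":
        raise ValueError("method must be 'approx' or 'exact'")
    if np.all(np.ptp(matrix, axis=1) == 0):
        # every row constant: no evidence of any difference
        return 0.0, df, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    zero_policy: str = "drop",
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    ``zero_policy="drop"`` removes zero differences (the classic Wilcoxon
    policy); ``"pratt"`` keeps them in the ranking.  ``mode="auto"`` uses
    exact enumeration for n ≤ 25 without tied |differences|, otherwise the
    normal approximation with continuity correction; ``"exact"`` and
    ``"approx"`` force a method.  Returns ``(W, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all differences are zero; p = 1", UserWarning, stacklevel=2)
        return 0.0, 1.0
    if mode == "auto":
        has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
        method = "exact" if nonzero.size <= 25 and not has_ties else "approx"
    else:
        method = mode
    zero_method = "wilcox" if zero_policy == "drop" else "pratt"
    res = stats.wilcoxon(
        x, y, zero_method=zero_method, correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def count_optimal(table: AreaTable, condition: str) -> int:
    """Number of feet with complete risk-region removal (area exactly 0)."""
    if condition not in table.data.columns:
        raise ValueError(f"condition {condition!r} not in table")
    return int((table.data[condition] == 0).sum())


def descriptives(
    table: AreaTable, conditions: Sequence[str] | None = None
) -> ConditionDescriptives:
    """Mean, sample SD, median and max of areas per condition."""
    df = table.data if conditions is None else table.data[list(conditions)]
    if df.empty:
        raise ValueError("empty area table")
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1),  # NaN for a single row: not applicable
            "median": df.median(),
            "max": df.max(),
        }
    )
    out.index.name = "condition"
    return ConditionDescriptives(out)


def compare_conditions(
    table: AreaTable,
    conditions: Sequence[str],
    alpha_family: float = 0.05,
) -> GroupComparison:
    """Friedman test followed by Bonferroni-corrected pairwise signed-rank tests.

    The pairwise level is ``alpha_family / n_pairs`` (0.05/3 for three
    conditions).  Mean differences are mean(condition1) − mean(condition2)
    in cm², i.e. positive values mean condition2 achieved smaller risk
    regions.
    """
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    data = table.require_complete(conditions)
    chi2, df, p = friedman_test(table, conditions)
    pairs = list(itertools.combinations(conditions, 2))
    alpha_pairwise = alpha_family / len(pairs)
    pairwise = []
    for c1, c2 in pairs:
        x = data[c1].to_numpy(float)
        y = data[c2].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            w, pv = wilcoxon_signed_rank(x, y)
        pairwise.append(
            PairwiseResult(
                pair=(c1, c2),
                statistic=w,
                p=pv,
                mean_difference_cm2=float(x.mean() - y.mean()),
                significant=pv < alpha_pairwise,
            )
        )
    return GroupComparison(
        k=len(conditions),
        n=len(data),
        friedman_chi2=chi2,
        friedman_df=df,
        friedman_p=p,
        pairwise=tuple(pairwise),
        alpha_family=alpha_family,
        alpha_pairwise=alpha_pairwise,
    )


class AreaComparison:
    """Model-style wrapper for the group-level area comparison.

    Parameters
    ----------
    table : AreaTable
        Per-foot total R-ROI areas.
    conditions : sequence of str
        Condition columns to compare, e.g. ``["FI", "TCCI", "CADCAM"]``.
    alpha_family : float
        Family-wise type-I level for the pairwise tests.
    """

    def __init__(
        self,
        table: AreaTable,
        conditions: Sequence[str] | None = None,
        alpha_family: float = 0.05,
    ):
        self.table = table
        self.conditions = list(conditions) if conditions else table.conditions
        self.alpha_family = alpha_family

    @classmethod
    def from_csv(
        cls, path: str | Path, conditions: Sequence[str] | None = None, **kw
    ) -> "AreaComparison":
        return cls(read_area_table(path), conditions, **kw)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conditions: Sequence[str] | None = None, **kw
    ) -> "AreaComparison":
        """Build from a DataFrame with subject/side columns or index."""
        if not isinstance(df.index, pd.MultiIndex):
            df = df.set_index(["subject", "side"])
        return cls(AreaTable(df), conditions, **kw)

    def fit(self) -> "AreaComparisonResults":
        comparison = compare_conditions(self.table, self.conditions, self.alpha_family)
        desc = descriptives(self.table, self.conditions)
        optimal = {c: count_optimal(self.table, c) for c in self.conditions}
        return AreaComparisonResults(self, comparison, desc, optimal)


@dataclass(frozen=True)
class AreaComparisonResults:
    model: AreaComparison
    comparison: GroupComparison
    descriptives: ConditionDescriptives
    optimal_counts: dict[str, int]

    def pairwise_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition_1": r.pair[0],
                "condition_2": r.pair[1],
                "W": r.statistic,
                "p": r.p,
                "mean_difference_cm2": r.mean_difference_cm2,
                "significant": r.significant,
            }
            for r in self.comparison.pairwise
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Risk-Region Area Comparison",
            "=" * 60,
            f"feet (n):          {c.n}    conditions (k): {c.k}",
            f"Friedman:          chi2 = {c.friedman_chi2:.3f}, df = {c.friedman_df}, "
            f"p = {c.friedman_p:.3g}",
            f"pairwise alpha:    {c.alpha_pairwise:.6g} "
            f"(Bonferroni, family {c.alpha_family:g})",
            "",
            "Descriptives (cm^2):",
            self.descriptives.table.round(2).to_string(),
            "",
            "Pairwise signed-rank tests:",
            self.pairwise_frame().to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
            "",
            "Optimal offloading (area = 0): "
            + ", ".join(f"{k}: {v}/{c.n}" for k, v in self.optimal_counts.items()),
        ]
        return "\n".join(lines)
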