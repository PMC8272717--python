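"""Rank-based comparison of the 12 analysis conditions.

Six reactivity parameters crossed with the use or non-use of covariates
give 12 conditions. At every voxel the conditions are ranked by their
reliability value (rank 12 = most reliable); a Kolmogorov-Smirnov check
motivates nonparametric testing, a Kruskal-Wallis omnibus test asks
whether the rankings differ, and Bonferroni-adjusted confidence
intervals around each condition's mean rank (from a one-way ANOVA on
the ranks) provide simple effects: conditions with disjoint intervals
differ significantly.

Voxels are treated as independent observations here, as is conventional
for this procedure; spatial correlation makes the tests anti-
conservative, which is a documented property, not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ConditionGrid",
    "RankingResult",
    "rank_conditions_per_voxel",
    "ks_normality_check",
    "kruskal_wallis",
    "simple_effects_ci",
    "rank_analysis",
]


@dataclass
class ConditionGrid:
    """Per-voxel reliability value for each condition.

    ``values`` is (n_conditions, n_voxels); conditions are typically the
    six parameters x {with, without} covariates (ICC without covariates,
    |sr| with covariates, so both are on a higher-is-more-reliable
    footing).
    """

    values: np.ndarray
    condition_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.condition_names):
            raise ValueError("one row per condition required")

    def drop_conditions(self, names: list[str]) -> "ConditionGrid":
        keep = [i for i, n in enumerate(self.condition_names) if n not in names]
        return ConditionGrid(self.values[keep], [self.condition_names[i] for i in keep])


@dataclass
class RankingResult:
    condition_names: list[str]
    mean_ranks: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    alpha: float
    kw_h: float
    kw_p: float
    ks_stat: float
    ks_p: float
    nonoverlap: np.ndarray = field(default=None)  # (m, m) bool, CIs disjoint

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition_names,
                "mean_rank": self.mean_ranks,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def top_condition_is_distinct(self) -> bool:
        """Is the best-ranked condition's CI disjoint from all others?"""
        top = int(np.argmax(self.mean_ranks))
        others = [i for i in range(len(self.mean_ranks)) if i != top]
        return bool(all(self.nonoverlap[top, i] for i in others))


def rank_conditions_per_voxel(grid: ConditionGrid) -> np.ndarray:
    """Within-voxel ranks of the conditions; rank m = most reliable.

    Ties get average ranks. Voxels with any NaN are dropped (logged).
    Returns (n_conditions, n_used_voxels).
    """
    vals = grid.values
    ok = np.isfinite(vals).all(axis=0)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("dropping %d voxels with incomplete condition values", n_drop)
    vals = vals[:, ok]
    if vals.shape[1] == 0:
        raise ValueError("no voxel has a complete set of condition values")
    return stats.rankdata(vals, axis=0)


def ks_normality_check(values: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic of the values against a Normal with the
    sample mean and SD.

    Estimating the reference parameters from the same sample makes the
    nominal p anti-conservative (the Lilliefors caveat); here a small p
    is only used to justify proceeding nonparametrically. Constant input
    returns p = 0 by convention.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("need at least 8 values for the normality check")
    sd = x.std(ddof=1)
    if sd == 0:
        log.info("constant input to normality check; returning p = 0 by convention")
        return float("inf"), 0.0
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("total sample too small")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def simple_effects_ci(
    ranks: np.ndarray, alpha: float = 0.05, correction: str = "bonferroni"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bonferroni-adjusted CIs around each condition's mean rank.

    One-way ANOVA on the ranks with condition as the factor: each CI is
    ``mean_rank ± t(1 - alpha/(2m), N - m) * sqrt(MSE / n_voxels)`` with
    the pooled within-condition mean square error. Returns
    (mean_ranks, lower, upper, nonoverlap matrix).
    """
    ranks = np.asarray(ranks, dtype=float)
    m, n = ranks.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    means = ranks.mean(axis=1)
    sse = float(((ranks - means[:, None]) ** 2).sum())
    df_err = m * n - m
    mse = sse / df_err
    if correction == "bonferroni":
        level = 1.0 - alpha / (2.0 * m)
    elif correction is None or correction == "none":
        level = 1.0 - alpha / 2.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    half = stats.t.ppf(level, df_err) * np.sqrt(mse / n)
    lower, upper = means - half, means + half
    nonoverlap = (lower[:, None] > upper[None, :]) | (upper[:, None] < lower[None, :])
    np.fill_diagonal(nonoverlap, False)
    return means, lower, upper, nonoverlap


def rank_analysis(grid: ConditionGrid, alpha: float = 0.05) -> RankingResult:
    """Full pipeline: rank per voxel, KS check, Kruskal-Wallis omnibus,
    simple-effects CIs."""
    ranks = rank_conditions_per_voxel(grid)
    ks_stat, ks_p = ks_normality_check(grid.values[np.isfinite(grid.values)])
    kw_h, kw_p = kruskal_wallis(list(ranks))
    means, lower, upper, nonoverlap = simple_effects_ci(ranks, alpha=alpha)
    return RankingResult(
        condition_names=list(grid.condition_names),
        mean_ranks=means,
        ci_lower=lower,
        ci_upper=upper,
        alpha=alpha,
        kw_h=kw_h,
        kw_p=kw_p,
        ks_stat=ks_stat,
        ks_p=ks_p,
        nonoverlap=nonoverlap,
    )
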