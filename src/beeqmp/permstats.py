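"""Univariate permutation inference: permutation ANOVA / t-tests and friends.

Because bacterial loads are heteroscedastic across bee types, omnibus tests
are run by randomization: the response is shuffled B times (default 10,000),
the F (one-way ANOVA) or |t| (Welch) statistic is recomputed on each shuffle,
and the p-value is the fraction of randomized statistics at least as large as
the observed one, floored at 1/B (``p = max(exceed, 1)/B``) so the smallest
reportable p with B = 10,000 is 1e-4. Permutations are sampled with
replacement from the permutation group (plain Monte Carlo).

Pairwise follow-ups are classical Tukey HSD (Tukey-Kramer for unbalanced
designs) or permutation Welch tests with Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, UndefinedStatisticError

__all__ = [
    "PermTestResult",
    "PairwiseComparison",
    "welch_t",
    "anova_f",
    "perm_test",
    "tukey_hsd",
    "pairwise_perm_t",
    "bonferroni",
    "spearman",
]


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of a randomization test.

    ``exceed_count`` is the number of the ``n_permutations`` randomized
    statistics that were >= the observed one; ``p`` follows the declared
    floor convention ``max(exceed_count, 1) / n_permutations``.
    """

    statistic_name: str
    observed: float
    n_permutations: int
    exceed_count: int
    p: float
    seed: int | None = None


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    estimate: float  # mean(level_a) - mean(level_b)
    p_adjusted: float
    method: str  # "tukey" | "bonferroni_perm"


def welch_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Welch's t statistic ``(mean x - mean y)/sqrt(sx^2/nx + sy^2/ny)``.

    If both group variances are exactly zero the standard error vanishes;
    the statistic is then defined as 0 for equal means and signed infinity
    otherwise (the limit as the variances shrink).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DesignError("Welch's t needs n >= 2 per group")
    diff = x.mean() - y.mean()
    se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
    return float(diff / np.sqrt(se2))


def _group_indices(groups: Sequence) -> tuple[np.ndarray, list, list[np.ndarray]]:
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    idx = [np.flatnonzero(groups == lv) for lv in levels]
    if len(levels) < 2:
        raise DesignError("need at least two groups")
    if min(len(i) for i in idx) < 2:
        raise DesignError("every group needs at least two observations")
    return groups, levels, idx


def anova_f(values: Sequence[float], groups: Sequence) -> float:
    """Classical one-way ANOVA F statistic."""
    values = np.asarray(values, dtype=float)
    _, _, idx = _group_indices(groups)
    return float(_anova_f_rows(values[None, :], idx)[0])


def _anova_f_rows(v: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    """One-way F for each row of ``v`` with fixed group index sets."""
    n = v.shape[1]
    a = len(idx)
    grand = v.mean(axis=1)
    ss_between = np.zeros(v.shape[0])
    ss_within = np.zeros(v.shape[0])
    for ix in idx:
        sub = v[:, ix]
        gm = sub.mean(axis=1)
        ss_between += len(ix) * (gm - grand) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def _welch_abs_t_rows(v: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    if len(idx) != 2:
        raise DesignError("welch_t_abs requires exactly two groups")
    x, y = v[:, idx[0]], v[:, idx[1]]
    diff = x.mean(axis=1) - y.mean(axis=1)
    se2 = x.var(ddof=1, axis=1) / x.shape[1] + y.var(ddof=1, axis=1) / y.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(se2 == 0.0, np.where(diff == 0.0, 0.0, np.inf), t)
    return np.abs(t)


_STATISTICS = {"anova_F": _anova_f_rows, "welch_t_abs": _welch_abs_t_rows}


def perm_test(
    values: Sequence[float],
    groups: Sequence,
    statistic: str = "anova_F",
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """Randomization test of a one-way group effect on a response.

    The response vector is permuted ``n_permutations`` times against the
    fixed group labels; ``p = max(#{stat_perm >= stat_obs}, 1)/B``. A constant
    response leaves the statistic undefined (0/0): by convention no
    permutation exceeds it and p = 1, with a warning.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; use one of {sorted(_STATISTICS)}")
    values = np.asarray(values, dtype=float)
    _, _, idx = _group_indices(groups)
    rng = np.random.default_rng(seed)
    stat_rows = _STATISTICS[statistic]

    if np.ptp(values) == 0.0:
        warnings.warn("constant response: permutation statistic undefined, p = 1", stacklevel=2)
        return PermTestResult(statistic, float("nan"), n_permutations, n_permutations, 1.0)

    observed = float(stat_rows(values[None, :], idx)[0])
    perm = rng.permuted(np.tile(values, (n_permutations, 1)), axis=1)
    stats = stat_rows(perm, idx)
    exceed = int(np.count_nonzero(stats >= observed))
    p = max(exceed, 1) / n_permutations
    return PermTestResult(statistic, observed, n_permutations, exceed, p,
                          seed if isinstance(seed, int) else None)


def tukey_hsd(values: Sequence[float], groups: Sequence) -> list[PairwiseComparison]:
    """Tukey's HSD pairwise comparisons after a one-way fit.

    Uses the studentized-range distribution with pooled within-group variance;
    unbalanced designs follow the Tukey-Kramer form. With two groups the
    procedure reduces to a pooled-variance t test.
    """
    values = np.asarray(values, dtype=float)
    _, levels, idx = _group_indices(groups)
    res = sps.tukey_hsd(*(values[ix] for ix in idx))
    out = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            out.append(
                PairwiseComparison(
                    level_a=str(levels[i]),
                    level_b=str(levels[j]),
                    estimate=float(values[idx[i]].mean() - values[idx[j]].mean()),
                    p_adjusted=float(min(1.0, res.pvalue[i, j])),
                    method="tukey",
                )
            )
    return out


def pairwise_perm_t(
    values: Sequence[float],
    groups: Sequence,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> list[PairwiseComparison]:
    """Permutation Welch tests for every pair of levels, Bonferroni-adjusted."""
    values = np.asarray(values, dtype=float)
    _, levels, idx = _group_indices(groups)
    rng = np.random.default_rng(seed)
    pairs, raw = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            sub = np.concatenate([values[idx[i]], values[idx[j]]])
            lab = np.r_[np.zeros(len(idx[i])), np.ones(len(idx[j]))]
            res = perm_test(sub, lab, "welch_t_abs", n_permutations, rng)
            pairs.append((str(levels[i]), str(levels[j]),
                          float(values[idx[i]].mean() - values[idx[j]].mean())))
            raw.append(res.p)
    adj = bonferroni(raw)
    return [
        PairwiseComparison(a, b, est, p, "bonferroni_perm")
        for (a, b, est), p in zip(pairs, adj)
    ]


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment ``p_adj = min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return list(np.minimum(1.0, p * p.size))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks, ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DesignError("spearman needs paired vectors with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)
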