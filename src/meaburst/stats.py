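"""Nonparametric statistical battery for spike-train feature comparisons.

The four tests used to compare MEA cohorts: Mann-Whitney U for two-group
feature comparisons, Pearson chi-square on response-class contingency
tables, Kruskal-Wallis one-way ANOVA across dose groups, and Dunn's rank
post hoc with Bonferroni multiplicity adjustment (the scheme GraphPad
Prism reports).  All tests are two-sided with alpha 0.05 by default.

Mann-Whitney, Kruskal-Wallis and the chi-square statistic are delegated
to scipy.stats; Dunn's test is implemented here from the pooled-midrank
z formula since scipy and statsmodels offer no Dunn implementation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: largest min(n) at which the exact Mann-Whitney null is enumerated
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    n_per_group: tuple[int, ...] = ()
    alpha: float = ALPHA
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "alpha": self.alpha,
            **self.details,
        }


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z_statistic: float
    p_unadjusted: float
    p_adjusted: float


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when min(n) <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.  Identical constant samples yield p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values identical across both samples; p = 1")
        return TestResult("mann_whitney_u", statistic=x.size * y.size / 2.0,
                          p_value=1.0, n_per_group=(x.size, y.size),
                          details={"method": "degenerate"})
    exact = min(x.size, y.size) <= EXACT_MWU_MAX_N and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult("mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_per_group=(x.size, y.size),
                      details={"method": method})


def pearson_chi_square(table) -> TestResult:
    """Uncorrected Pearson chi-square test of homogeneity on a contingency
    table (rows = groups, columns = categories).

    Expected counts come from the row/column margins; df =
    (rows-1)(cols-1).  A zero margin is an error instructing the caller to
    drop the degenerate category first.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError(
            "contingency table has an empty row or column; drop the "
            "degenerate category (df decreases accordingly) and retry"
        )
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult("pearson_chi_square", statistic=float(chi2),
                      p_value=float(p), df=float(df),
                      n_per_group=tuple(int(n) for n in obs.sum(axis=1)),
                      details={"n_total": int(obs.sum())})


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis one-way ANOVA on ranks with tie correction.

    H is referred to chi-square with df = k-1.  All-identical
    observations yield H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult("kruskal_wallis", statistic=0.0, p_value=1.0,
                          df=float(len(groups) - 1),
                          n_per_group=tuple(g.size for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", statistic=float(h), p_value=float(p),
                      df=float(len(groups) - 1),
                      n_per_group=tuple(g.size for g in groups))


def dunns_posthoc(groups: dict[str, "np.ndarray | list"],
                  alpha: float = ALPHA,
                  adjustment: str = "bonferroni") -> list[PairwiseResult]:
    """Dunn's rank-based pairwise post hoc following Kruskal-Wallis.

    For groups a, b with pooled midranks,

        z_ab = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12
                - sum(t^3 - t)/(12(N-1))) (1/n_a + 1/n_b)]

    with the tie term summed over tie groups of size t.  Two-sided p per
    pair; ``bonferroni`` multiplies by the number of pairs (capped at 1),
    ``none`` leaves p unadjusted.  With two groups the factor is 1 either
    way.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError("adjustment must be 'bonferroni' or 'none'")
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # per-group mean ranks
    mean_ranks = {}
    start = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = ranks[start:start + arr.size].mean()
        start += arr.size
    # tie correction over pooled tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(range(len(names)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        na, nb = arrays[i].size, arrays[j].size
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjustment == "bonferroni" else p
        results.append(PairwiseResult(group_a=names[i], group_b=names[j],
                                      z_statistic=float(z),
                                      p_unadjusted=float(p),
                                      p_adjusted=float(p_adj)))
    return results


def pairwise_to_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "group_a": [r.group_a for r in results],
        "group_b": [r.group_b for r in results],
        "z": [r.z_statistic for r in results],
        "p_unadjusted": [r.p_unadjusted for r in results],
        "p_adjusted": [r.p_adjusted for r in results],
    })
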