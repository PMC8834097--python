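"""Rank-based univariate screens.

Two nonparametric tests cover the study designs: Dunn's post-hoc test with
Bonferroni correction for three-group comparisons (control / typical case /
mild case) and the Wilcoxon rank-sum (Mann–Whitney) test for two-group
comparisons.  Both are two-sided.  No Kruskal–Wallis gate is applied before
Dunn's test.

Dunn's z for groups a, b, with joint midranks over all N observations:

    z = (R̄_a − R̄_b) / sqrt[ (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_a + 1/n_b) ]

where t runs over tie-group sizes.  The Bonferroni family is the set of
pairwise comparisons within one analyte (m = 3 for three groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import CytokinePanel

__all__ = ["TestResult", "dunn_test", "wilcoxon_rank_sum", "univariate_screen"]


@dataclass
class TestResult:
    """A single two-group comparison."""

    comparison: tuple[str, str]
    statistic: float          # Dunn z, or Wilcoxon rank sum W of group a
    p_raw: float
    p_adjusted: float
    method: str


def _tie_term(values: np.ndarray) -> float:
    """Σ(t³ − t) over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def dunn_test(values: Sequence[float], groups: Sequence[str]) -> list[TestResult]:
    """Dunn's post-hoc test on joint ranks, Bonferroni-adjusted.

    Returns one :class:`TestResult` per group pair (groups in sorted order,
    pairs in lexicographic order).  The adjustment multiplies each raw
    two-sided normal p by the number of pairs, capped at 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    if values.shape != labels.shape:
        raise ValueError("values and groups must have equal length")
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValueError("Dunn's test needs at least 2 groups")
    for g in names:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} has no observations")
    N = values.size
    ranks = sps.rankdata(values)
    mean_rank = {g: float(ranks[labels == g].mean()) for g in names}
    n_by = {g: int((labels == g).sum()) for g in names}
    tie_corr = _tie_term(values) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_corr
    pairs = list(combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / n_by[a] + 1.0 / n_by[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(TestResult((a, b), float(z), p_raw, min(1.0, m * p_raw),
                              method="dunn-bonferroni"))
    return out


#: largest pooled sample size for which "auto" picks the exact test
#: (matches the conventional cutoff of R's wilcox.test)
EXACT_LIMIT = 50


def _rank_sum_counts(n_a: int, N: int) -> np.ndarray:
    """Counts of n_a-subsets of ranks {1..N} by rank sum (exact null)."""
    w_max = sum(range(N - n_a + 1, N + 1))
    counts = np.zeros((n_a + 1, w_max + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n_a, r), 0, -1):
            counts[k, r:] += counts[k - 1, : w_max + 1 - r]
    return counts[n_a]


def _exact_rank_sum_p(w_obs: float, n_a: int, n_b: int) -> float:
    """Two-sided exact p for the rank sum of sample a (no ties).

    Equivalent to enumerating all C(n_a + n_b, n_a) equally likely rank
    assignments: returns 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
    """
    N = n_a + n_b
    counts = _rank_sum_counts(n_a, N)
    total = comb(N, n_a)
    sums = np.arange(counts.size)
    p_le = counts[sums <= w_obs].sum() / total
    p_ge = counts[sums >= w_obs].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    ``mode="exact"`` computes the exact permutation p over all rank
    assignments (valid for untied data); ``"normal"`` uses the normal
    approximation with midranks, tie correction and continuity correction;
    ``"auto"`` picks exact for untied data up to a pooled size of
    ``EXACT_LIMIT`` (50, the conventional exact/asymptotic switch point),
    falling back to the approximation otherwise.  The statistic reported is
    W, the rank sum of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    n_a, n_b = a.size, b.size
    N = n_a + n_b
    has_ties = np.unique(pooled).size < N
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n_a].sum())
    if mode == "auto":
        mode = "exact" if (N <= EXACT_LIMIT and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires untied data")
        p = _exact_rank_sum_p(W, n_a, n_b)
        method = "wilcoxon-exact"
    elif mode == "normal":
        mu = n_a * (N + 1) / 2.0
        tie = _tie_term(pooled) / (N * (N - 1))
        var = n_a * n_b / 12.0 * ((N + 1) - tie)
        if var <= 0 or W == mu:
            p = 1.0
        else:
            z = (W - mu - 0.5 * np.sign(W - mu)) / np.sqrt(var)
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon-normal"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(("a", "b"), W, p, p, method=method)


def univariate_screen(panel: CytokinePanel, grouping: str = "group_label",
                      mode: str = "auto") -> pd.DataFrame:
    """Run the appropriate rank test for every analyte.

    Two groups → one Wilcoxon rank-sum row per analyte; three or more →
    Dunn's test rows (one per group pair, Bonferroni within the analyte).
    Per-analyte failures are flagged in the ``error`` column rather than
    aborting the screen.
    """
    labels_all = panel.groups(grouping).astype(str)
    names = sorted(set(labels_all))
    rows = []
    for analyte in panel.analyte_names:
        col = panel.concentrations[analyte].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        vals, labels = col[ok], labels_all[ok]
        try:
            if len(names) == 2:
                ga, gb = names
                res = wilcoxon_rank_sum(vals[labels == ga], vals[labels == gb], mode=mode)
                rows.append({"analyte": analyte, "group_a": ga, "group_b": gb,
                             "statistic": res.statistic, "p_raw": res.p_raw,
                             "p_adjusted": res.p_adjusted, "method": res.method,
                             "error": ""})
            else:
                for res in dunn_test(vals, labels):
                    rows.append({"analyte": analyte, "group_a": res.comparison[0],
                                 "group_b": res.comparison[1],
                                 "statistic": res.statistic, "p_raw": res.p_raw,
                                 "p_adjusted": res.p_adjusted, "method": res.method,
                                 "error": ""})
        except ValueError as exc:
            rows.append({"analyte": analyte, "group_a": "", "group_b": "",
                         "statistic": np.nan, "p_raw": np.nan, "p_adjusted": np.nan,
                         "method": "", "error": str(exc)})
    columns = ["analyte", "group_a", "group_b", "statistic", "p_raw",
               "p_adjusted", "method", "error"]
    return pd.DataFrame(rows, columns=columns)
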