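"""Univariate group comparisons with multiplicity control.

Two-group screens use an unpaired Welch t-test per variable with
Benjamini-Hochberg false-discovery-rate adjustment.  Multi-group comparisons
route each variable to one-way ANOVA or Kruskal-Wallis depending on a
Shapiro-Wilk normality check of the within-group residuals, adjust across
variables with Bonferroni, and summarize pairwise post-hoc comparisons as
compact homogeneity letters (groups sharing a letter do not differ).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclasses.dataclass
class TestResult:
    variable: str
    test: str                # t | anova | kruskal_wallis | chi_square
    statistic: float
    p_raw: float
    p_adj: float
    adjust: str              # bh | bonferroni | none
    significant: bool
    letters: dict | None = None   # group -> homogeneity letters


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    stat = float(res.statistic)
    if not np.isfinite(p):
        p = 1.0
    return stat, p


def two_group_bh(table: pd.DataFrame, groups: pd.Series | np.ndarray,
                 q: float = 0.05, equal_var: bool = False
                 ) -> list[TestResult]:
    """Per-variable unpaired t-tests with Benjamini-Hochberg adjustment.

    ``table`` is samples x variables; ``groups`` a binary label per sample.
    Welch's unequal-variance statistic by default (``equal_var=True`` for the
    pooled Student variant).  Significant iff BH-adjusted p < q.
    """
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise StatsError("two_group_bh needs exactly 2 groups")
    a = table.loc[g == levels[0]]
    b = table.loc[g == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need >= 2 samples per group")
    stats_p = []
    for v in table.columns:
        x, y = a[v].to_numpy(float), b[v].to_numpy(float)
        if equal_var:
            res = stats.ttest_ind(x, y, equal_var=True)
            s, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(p):
                s, p = 0.0, 1.0
        else:
            s, p = _welch_t(x, y)
        stats_p.append((v, s, p))
    raw = np.array([p for _, _, p in stats_p])
    rej, p_adj = benjamini_hochberg(raw, q)
    return [TestResult(v, "t", s, float(p), float(pa), "bh", bool(r))
            for (v, s, p), pa, r in zip(stats_p, p_adj, rej)]


def benjamini_hochberg(p_values: np.ndarray, q: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up: returns (reject flags at level q, adjusted p-values)."""
    rej, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return rej, p_adj


def _compact_letters(groups: list, differs: set[tuple]) -> dict:
    """Compact letter display: groups sharing a letter are homogeneous.

    Greedy insert-absorb: each letter is a maximal set of mutually
    homogeneous groups; every group receives at least one letter.
    """
    letters: list[set] = []
    for g in groups:
        placed = False
        for s in letters:
            if all(tuple(sorted((g, h), key=str)) not in differs for h in s):
                s.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb subsets
    letters = [s for i, s in enumerate(letters)
               if not any(s < t for j, t in enumerate(letters) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for ch, s in zip(alphabet, letters):
        for g in sorted(s, key=str):
            out[g] += ch
    return out


def multi_group(table: pd.DataFrame, labels: pd.Series | np.ndarray,
                alpha: float = 0.05) -> list[TestResult]:
    """ANOVA / Kruskal-Wallis per variable across >= 3 groups.

    A Shapiro-Wilk test on the pooled within-group residuals (alpha 0.05)
    gates each variable to one-way ANOVA (normal) or Kruskal-Wallis
    (non-normal).  P-values are Bonferroni-adjusted across variables.
    Pairwise post-hoc comparisons (same parametric routing, Bonferroni over
    the pairs) give the homogeneity-letter display.
    """
    lab = pd.Series(np.asarray(labels), index=table.index)
    levels = sorted(lab.unique(), key=str)
    if len(levels) < 2:
        raise StatsError("need >= 2 groups")
    results: list[TestResult] = []
    raw_rows = []
    for v in table.columns:
        x = table[v].astype(float)
        by_group = [x[lab == g].to_numpy() for g in levels]
        if min(len(g) for g in by_group) < 2:
            raw_rows.append((v, "skipped", np.nan, np.nan, None,
                             "a group of size 1"))
            continue
        resid = np.concatenate([g - g.mean() for g in by_group])
        if np.ptp(resid) == 0:
            normal = True  # constant residuals: trivially parametric, p = 1
        else:
            try:
                normal = stats.shapiro(resid).pvalue >= 0.05
            except Exception:
                normal = False
        if normal:
            if all(np.var(g, ddof=1) == 0 for g in by_group) and \
                    len({float(g.mean()) for g in by_group}) == 1:
                stat, p = 0.0, 1.0
            else:
                res = stats.f_oneway(*by_group)
                stat, p = float(res.statistic), float(res.pvalue)
                if not np.isfinite(p):
                    stat, p = 0.0, 1.0
            test = "anova"
        else:
            if all(len(set(g)) == 1 for g in by_group) and \
                    len({tuple(sorted(set(g))) for g in by_group}) == 1:
                stat, p = 0.0, 1.0
            else:
                res = stats.kruskal(*by_group)
                stat, p = float(res.statistic), float(res.pvalue)
                if not np.isfinite(p):
                    stat, p = 0.0, 1.0
            test = "kruskal_wallis"
        letters = _posthoc_letters(by_group, levels, normal, alpha)
        raw_rows.append((v, test, stat, p, letters, ""))

    tested = [(i, r) for i, r in enumerate(raw_rows) if r[1] != "skipped"]
    m = len(tested)
    for i, (v, test, stat, p, letters, note) in enumerate(raw_rows):
        if test == "skipped":
            results.append(TestResult(v, "skipped", np.nan, np.nan, np.nan,
                                      "none", False, None))
            continue
        p_adj = min(p * m, 1.0)
        results.append(TestResult(v, test, stat, p, p_adj, "bonferroni",
                                  p_adj < alpha, letters))
    return results


def _posthoc_letters(by_group: list[np.ndarray], levels: list,
                     normal: bool, alpha: float) -> dict:
    pairs = list(combinations(range(len(levels)), 2))
    differs: set[tuple] = set()
    for i, j in pairs:
        x, y = by_group[i], by_group[j]
        if normal:
            _, p = _welch_t(x, y)
        else:
            if set(x) == set(y) and len(set(x)) == 1:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y,
                                             alternative="two-sided").pvalue)
        if min(p * len(pairs), 1.0) < alpha:
            differs.add(tuple(sorted((levels[i], levels[j]), key=str)))
    return _compact_letters(levels, differs)


def chi_square_homogeneity(counts: np.ndarray) -> TestResult:
    """Pearson chi-square homogeneity test, no continuity correction."""
    C = np.asarray(counts)
    if C.ndim != 2 or C.shape[0] < 2 or C.shape[1] < 2:
        raise StatsError("need a contingency table with >= 2 rows and columns")
    if (C < 0).any() or not np.issubdtype(C.dtype, np.number):
        raise StatsError("counts must be non-negative")
    if (C.sum(axis=0) == 0).any() or (C.sum(axis=1) == 0).any():
        raise StatsError("zero marginal in contingency table")
    res = stats.chi2_contingency(C, correction=False)
    return TestResult("contingency", "chi_square", float(res.statistic),
                      float(res.pvalue), float(res.pvalue), "none",
                      res.pvalue < 0.05)
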