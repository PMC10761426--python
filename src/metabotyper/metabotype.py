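"""Metabotype discovery: Ward clustering of factor scores + DA validation.

Samples are clustered in latent factor-score space by agglomerative
hierarchical clustering with squared Euclidean distance and Ward's method
(merge heights are within-cluster sum-of-squares increments).  The number of
metabotypes is chosen among candidate cuts by leave-one-out cross-validated
linear discriminant analysis: the cut whose clusters a linear rule predicts
best is the most defensible partition.  Cluster labels are ordered by
descending size so "metabotype 1" is always the largest group.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .integrate import FactorScores

log = logging.getLogger(__name__)


class MetabotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ward agglomeration (Lance-Williams on squared Euclidean distances)
# ---------------------------------------------------------------------------

def ward_cluster(scores: FactorScores) -> np.ndarray:
    """Agglomerate samples; return an (n-1) x 4 merge history.

    Row t is ``(a, b, height, size)``: clusters ``a`` and ``b`` (original
    samples are 0..n-1, the cluster formed at step t gets id n+t) merge at
    ``height`` = the increase in total within-cluster sum of squares.  Ties
    break to the smallest (a, b) pair, so the result is deterministic.
    """
    X = scores.scores.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise MetabotypeError("need >= 2 samples")
    if not np.isfinite(X).any() or np.isnan(X).any() or np.isinf(X).any():
        raise MetabotypeError("non-finite scores")

    # Ward inter-cluster distance D such that Delta-SS = D / 2;
    # initialized with squared Euclidean distances between points.
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(sq[i, j])

    merges = np.zeros((n - 1, 4))
    next_id = n
    for t in range(n - 1):
        best = None
        for i_idx in range(len(ids)):
            for j_idx in range(i_idx + 1, len(ids)):
                a, b = ids[i_idx], ids[j_idx]
                key = (a, b) if a < b else (b, a)
                d = D[key]
                if best is None or d < best[0] - 1e-12 or (
                        abs(d - best[0]) <= 1e-12 and key < best[1]):
                    best = (d, key)
        d_min, (a, b) = best
        na, nb = sizes[a], sizes[b]
        merges[t] = (a, b, d_min / 2.0, na + nb)
        new = next_id
        next_id += 1
        ids.remove(a)
        ids.remove(b)
        for c in ids:
            nc = sizes[c]
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            dac, dbc = D.pop(ka), D.pop(kb)
            D[(c, new)] = ((na + nc) * dac + (nb + nc) * dbc - nc * d_min) \
                / (na + nb + nc)
        D.pop((a, b), None)
        ids.append(new)
        sizes[new] = na + nb
    return merges


def cut_k(merge_history: np.ndarray, k: int) -> np.ndarray:
    """Labels from cutting the dendrogram into k groups.

    Label indices are ordered by descending cluster size (ties: the cluster
    containing the smallest sample index first), so metabotype 1 is the
    largest group.
    """
    n = merge_history.shape[0] + 1
    if not 1 <= k <= n:
        raise MetabotypeError(f"k={k} out of range 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(merge_history[t, 0]), int(merge_history[t, 1])
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    clusters: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        clusters.setdefault(r, []).append(i)
    ordered = sorted(clusters.values(), key=lambda mem: (-len(mem), mem[0]))
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(ordered, start=1):
        labels[members] = lab
    return labels


# ---------------------------------------------------------------------------
# model selection by discriminant analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetabotypeResult:
    merge_history: np.ndarray
    candidate_k: list[int]
    loo_accuracy: dict[int, float]
    chosen_k: int
    labels: pd.Series                  # per-sample metabotype (1-based)
    factor_means: pd.DataFrame         # clusters x factors
    cluster_sizes: list[int]

    def validate(self) -> None:
        h = self.merge_history[:, 2]
        if np.any(np.diff(h) < -1e-8):
            raise MetabotypeError("merge heights not monotone")
        if self.labels.nunique() != self.chosen_k:
            raise MetabotypeError("labels do not take chosen_k values")
        if sum(self.cluster_sizes) != len(self.labels):
            raise MetabotypeError("cluster sizes do not sum to n")


def loo_lda_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy of linear DA (pooled within-class covariance)."""
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(X[mask], y[mask])
        correct += int(lda.predict(X[i:i + 1])[0] == y[i])
    return correct / n


def choose_k_by_da(scores: FactorScores, merge_history: np.ndarray,
                   candidates: tuple[int, ...] = (2, 3, 4)
                   ) -> MetabotypeResult:
    """Pick the metabotype count with the best LOO-validated linear DA.

    Candidates leaving any cluster with fewer than 2 members are skipped with
    a warning.  Ties go to the largest k: among equally well validated
    partitions, the most granular metabotyping is the most informative one
    (three perfectly separated clusters must yield k = 3 even though their
    2-cut is also perfectly separable).
    """
    X = scores.scores.to_numpy(dtype=float)
    accuracies: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in candidates:
        labels = cut_k(merge_history, k)
        counts = np.bincount(labels)[1:]
        if counts.min() < 2:
            log.warning("k=%d leaves a cluster of size %d; skipped", k,
                        counts.min())
            continue
        labelings[k] = labels
        accuracies[k] = loo_lda_accuracy(X, labels)
    if not accuracies:
        raise MetabotypeError("all candidate k were skipped")
    best_acc = max(accuracies.values())
    chosen_k = max(k for k, a in accuracies.items() if a >= best_acc)
    labels = pd.Series(labelings[chosen_k], index=scores.scores.index,
                       name="metabotype")
    means = scores.scores.groupby(labels).mean()
    means.index.name = "metabotype"
    sizes = labels.value_counts().sort_index().tolist()
    result = MetabotypeResult(
        merge_history=merge_history, candidate_k=sorted(accuracies),
        loo_accuracy=accuracies, chosen_k=chosen_k, labels=labels,
        factor_means=means, cluster_sizes=sizes)
    result.validate()
    return result


def characterize(result: MetabotypeResult, scores: FactorScores
                 ) -> pd.DataFrame:
    """Per-metabotype mean of each factor score (Table of cluster profiles)."""
    means = scores.scores.groupby(result.labels).mean()
    means.index.name = "metabotype"
    return means


# ---------------------------------------------------------------------------
# clinical characterization
# ---------------------------------------------------------------------------

def compare_clinical(labels: pd.Series, metadata: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Compare clinical covariates across metabotypes.

    Numeric covariates are routed to the multi-group comparison (ANOVA or
    Kruskal-Wallis gated by residual normality, Bonferroni-adjusted, with
    pairwise homogeneity letters); categorical covariates to a chi-square
    homogeneity test.  Constant covariates are skipped with a note.
    """
    from .univariate_stats import (chi_square_homogeneity, multi_group)

    if labels.nunique() < 2:
        raise MetabotypeError("need >= 2 clusters")
    meta = metadata.loc[labels.index]
    numeric_cols = [c for c in meta.columns
                    if pd.api.types.is_numeric_dtype(meta[c])]
    cat_cols = [c for c in meta.columns if c not in numeric_cols]

    rows = []
    constant_numeric = [c for c in numeric_cols if meta[c].nunique() <= 1]
    numeric_cols = [c for c in numeric_cols if meta[c].nunique() > 1]
    if numeric_cols:
        table = meta[numeric_cols].astype(float)
        results = multi_group(table, labels, alpha=alpha)
        for r in results:
            rows.append({"covariate": r.variable, "test": r.test,
                         "statistic": r.statistic, "p_raw": r.p_raw,
                         "p_adj": r.p_adj, "significant": r.significant,
                         "letters": r.letters, "note": ""})
    for c in cat_cols:
        if meta[c].nunique() < 2:
            rows.append({"covariate": c, "test": "skipped", "statistic": np.nan,
                         "p_raw": np.nan, "p_adj": np.nan, "significant": False,
                         "letters": None, "note": "constant covariate"})
            continue
        counts = pd.crosstab(meta[c], labels)
        r = chi_square_homogeneity(counts.to_numpy())
        rows.append({"covariate": c, "test": "chi_square",
                     "statistic": r.statistic, "p_raw": r.p_raw,
                     "p_adj": r.p_raw, "significant": r.p_raw < alpha,
                     "letters": None, "note": ""})
    for c in constant_numeric:
        rows.append({"covariate": c, "test": "skipped", "statistic": np.nan,
                     "p_raw": np.nan, "p_adj": np.nan, "significant": False,
                     "letters": None, "note": "constant covariate"})
    return pd.DataFrame(rows).set_index("covariate")
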