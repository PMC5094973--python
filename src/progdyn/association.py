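"""Downstream association analyses.

Cohort discrimination by two-way hierarchical clustering on a gene set,
PCA projection, exact Fisher tests on cluster × class tables, Pearson
correlation screens of enrichment scores against feature panels (pathway
scores, drug log-IC50 vectors), and two-or-more-group location tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaln
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSet, ValidationError
from .enrichment import DEFAULT_ALPHA, ssgsea_matrix

# --------------------------------------------------------------------------
# clustering and PCA


def cluster_two_way(expr: ExpressionMatrix,
                    gene_sets: Union[GeneSet, Sequence[GeneSet]],
                    alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """Two-cluster hierarchical clustering of samples on a gene set.

    Samples are clustered on the set-restricted expression matrix with
    distance = 1 − Pearson correlation between sample profiles and Ward
    linkage, cutting the tree at 2 clusters. Cluster 1 is, by convention,
    the cluster with the higher mean combined enrichment score for the set
    family (so for a tumor gene set, cluster 1 is the tumor-like cluster).
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    members = frozenset().union(*(gs.members for gs in gene_sets))
    sub = expr.values.loc[expr.values.index.intersection(pd.Index(sorted(members)))]
    if sub.shape[0] < 2:
        raise ValidationError("fewer than 2 in-set genes measured")
    if sub.shape[1] < 3:
        raise ValidationError("need at least 3 samples to cluster")
    dist = pdist(sub.to_numpy().T, metric="correlation")
    link = hierarchy.linkage(dist, method="ward")
    raw = hierarchy.fcluster(link, t=2, criterion="maxclust")
    labels = pd.Series(raw, index=expr.sample_ids, name="cluster")

    scores = ssgsea_matrix(expr, gene_sets, alpha=alpha, combine=True)
    sample_score = scores.mean(axis=0)
    if sample_score[labels == 1].mean() >= sample_score[labels == 2].mean():
        return labels
    return labels.map({1: 2, 2: 1}).rename("cluster")


def pca_project(expr: ExpressionMatrix, gene_set: GeneSet = None,
                n_components: int = 2) -> pd.DataFrame:
    """Project samples on the top principal components of a (set-restricted)
    mean-centered expression matrix.

    Sign convention: each component is flipped so that its largest-magnitude
    gene loading is positive, making coordinates deterministic.
    """
    values = expr.values
    if gene_set is not None:
        keep = values.index.intersection(pd.Index(sorted(gene_set.members)))
        values = values.loc[keep]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 genes and 2 samples")
    X = values.to_numpy().T  # samples × genes
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValidationError("matrix is constant; PCA undefined")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(coords, index=expr.sample_ids,
                        columns=[f"PC{k + 1}" for k in range(n_components)])


# --------------------------------------------------------------------------
# Fisher's exact test on r × c tables


@dataclass(frozen=True)
class FisherResult:
    p: float
    method: str  # 'exact_2x2' | 'exact_enumeration' | 'monte_carlo'
    n_sim: int = 0

    def __float__(self) -> float:
        return self.p


_REL_EPS = 1e-7  # tolerance when comparing table probabilities (as in R)


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a fixed-margin table."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return (gammaln(row + 1).sum() + gammaln(col + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    r = len(row_margins)

    def fill(row_idx, remaining_cols, rows):
        if row_idx == r - 1:
            last = np.array(remaining_cols)
            if (last >= 0).all():
                yield np.array(rows + [last])
            return
        target = row_margins[row_idx]

        def compositions(j, left, current):
            if j == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield current + [left]
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                yield from compositions(j + 1, left - v, current + [v])

        for comp in compositions(0, target, []):
            comp_arr = np.array(comp)
            yield from fill(row_idx + 1,
                            [c - v for c, v in zip(remaining_cols, comp_arr)],
                            rows + [comp_arr])

    yield from fill(0, list(col_margins), [])


def fisher_exact(table, seed: int = 0, n_sim: int = 100_000,
                 exact_max_dim: int = 4, exact_max_total: int = 500) -> FisherResult:
    """Two-sided Fisher's exact test on an r × c contingency table.

    2×2 tables use the hypergeometric test; larger tables with r, c ≤
    ``exact_max_dim`` and total ≤ ``exact_max_total`` are handled by exact
    enumeration over all tables with the observed margins (two-sided rule:
    sum the probabilities of tables no more probable than the observed one,
    the convention of mainstream statistical software); anything larger
    falls back to a seeded Monte-Carlo estimate over ``n_sim`` random
    fixed-margin tables.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2 x 2")
    if (table < 0).any():
        raise ValidationError("contingency table counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("contingency table has a zero margin")

    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return FisherResult(p=float(min(p, 1.0)), method="exact_2x2")

    log_obs = _log_table_prob(table)
    cutoff = log_obs + np.log1p(_REL_EPS)
    r, c = table.shape
    if r <= exact_max_dim and c <= exact_max_dim and table.sum() <= exact_max_total:
        total = 0.0
        for t in _enumerate_tables(row, col):
            lp = _log_table_prob(t)
            if lp <= cutoff:
                total += np.exp(lp)
        return FisherResult(p=float(min(total, 1.0)), method="exact_enumeration")

    # Monte-Carlo over random fixed-margin tables (random pairing of labels)
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(r), row)
    col_labels = np.repeat(np.arange(c), col)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(col_labels)
        sim = np.zeros((r, c), dtype=np.int64)
        np.add.at(sim, (row_labels, perm), 1)
        if _log_table_prob(sim) <= cutoff:
            hits += 1
    p = (hits + 1) / (n_sim + 1)
    return FisherResult(p=float(p), method="monte_carlo", n_sim=n_sim)


def cluster_class_table(clusters: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Cluster × class contingency table (rows = clusters, cols = classes)."""
    return pd.crosstab(clusters, classes)


# --------------------------------------------------------------------------
# correlation screen


def correlate_scores(scores: pd.Series, features: pd.DataFrame,
                     screen_p: float = 0.01) -> pd.DataFrame:
    """Pearson-correlation screen of a per-sample score against a feature panel.

    ``features`` is samples × features (e.g. pathway ES or drug log-IC50
    columns); pairs with missing feature values are dropped per feature.
    Returns one row per feature with ``r``, two-sided ``p`` (t transform,
    n − 2 df), ``n``, a ``hit`` flag (p < ``screen_p``), a ``sensitivity``
    flag for negative-r hits (the IC50 reading: higher score, lower IC50),
    and a Benjamini–Hochberg ``q`` column for transparency (the screen
    itself is on unadjusted p).
    """
    features = features.loc[features.index.intersection(scores.index)]
    rows = []
    for name in features.columns:
        pair = pd.concat([scores, features[name]], axis=1, join="inner").dropna()
        n = len(pair)
        if n < 3:
            raise ValidationError(f"feature {name!r} has fewer than 3 paired values")
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"feature": name, "r": np.nan, "p": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"feature": name, "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows).set_index("feature")
    out["hit"] = out["p"] < screen_p
    out["sensitivity"] = out["hit"] & (out["r"] < 0)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# group comparisons

GROUP_TESTS = ("t", "mann_whitney", "anova", "kruskal_wallis")


def compare_groups(scores: Sequence[float], labels: Sequence, test: str) -> tuple[float, float]:
    """Compare a continuous score between groups with the named test.

    ``t`` and ``mann_whitney`` require exactly 2 groups; ``anova`` and
    ``kruskal_wallis`` accept 2 or more. Mann-Whitney uses the exact null
    distribution when the combined n is ≤ 20 and there are no ties, and the
    tie-corrected normal approximation otherwise. Returns (statistic, p),
    two-sided.
    """
    if test not in GROUP_TESTS:
        raise ValidationError(f"test must be one of {GROUP_TESTS}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = [scores[labels == lab] for lab in pd.unique(labels)]
    k = len(groups)
    min_n = 1 if test == "mann_whitney" else 2
    for g in groups:
        if len(g) < min_n:
            raise ValidationError(f"every group needs >= {min_n} observations")
    if test in ("t", "mann_whitney") and k != 2:
        raise ValidationError(f"{test} requires exactly 2 groups, got {k}")
    if test in ("anova", "kruskal_wallis") and k < 2:
        raise ValidationError(f"{test} requires >= 2 groups, got {k}")

    if test == "t":
        res = stats.ttest_ind(groups[0], groups[1])
    elif test == "mann_whitney":
        pooled = np.concatenate(groups)
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(groups[0], groups[1],
                                 alternative="two-sided", method=method)
    elif test == "anova":
        res = stats.f_oneway(*groups)
    else:
        res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
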