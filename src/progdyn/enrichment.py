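"""Single-sample and preranked gene-set enrichment scoring.

Two related statistics are implemented from first principles:

* **ssGSEA** — a per-sample enrichment score. The sample's expression values
  are rank-normalized (replaced by ranks N..1, highest expression first) and
  the score is the sum over all rank positions of the difference between two
  empirical cumulative distribution functions: the weighted ECDF of the
  in-set genes (weight = rank^alpha) and the unweighted ECDF of the
  remaining genes,

      ES = sum_i [ P_in(i) - P_out(i) ],
      P_in(i)  = sum_{j<=i, j in set} rank_j^alpha / sum_{j in set} rank_j^alpha,
      P_out(i) = #{j<=i, j not in set} / (N - |set|).

  A positive ES means the set's genes concentrate at the top of the sample's
  expression profile. When a set family has UP and DN versions, the combined
  score is ES(UP) − ES(DN).

* **Preranked GSEA** — the classic weighted Kolmogorov–Smirnov statistic on
  an externally ranked gene list (e.g. genes ranked by tumor-vs-normal
  log2 FC). The running sum increments by |score|^p (normalized over the
  in-set genes) on hits and decrements uniformly on misses; the ES is the
  running-sum value of maximal absolute magnitude, keeping its sign. The
  nominal p-value comes from a null of random same-size gene sets drawn
  from the ranked universe.

Ties in expression are broken deterministically by gene identifier after the
value sort, so scoring is bitwise reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, ValidationError

#: Default ssGSEA rank-weighting exponent (the convention of the widely used
#: GenePattern ssGSEA projection tool).
DEFAULT_ALPHA = 0.25


def _ranked_genes(values: pd.Series) -> pd.Index:
    """Genes sorted by expression descending, ties broken by gene id."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return pd.Index(order)


def ssgsea_score(values: pd.Series, gene_set: Iterable[str],
                 alpha: float = DEFAULT_ALPHA) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    Parameters
    ----------
    values
        Per-gene log2 expression of a single sample (index = gene ids).
    gene_set
        Gene identifiers of the set (a GeneSet's members or any iterable).
        Members absent from ``values`` are ignored.
    alpha
        Rank-weighting exponent; 0 weights all in-set genes equally.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    members = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    measured = set(values.index)
    in_set = members & measured
    if not in_set:
        raise ValidationError("gene set shares no genes with the measured genes")
    n_out = len(measured) - len(in_set)
    if n_out == 0:
        raise ValidationError("gene set covers every measured gene; "
                              "the out-of-set ECDF is undefined")

    order = _ranked_genes(values)
    n = len(order)
    ranks = np.arange(n, 0, -1, dtype=float)  # rank-normalized values N..1
    hit = np.fromiter((g in in_set for g in order), dtype=bool, count=n)
    weights = np.where(hit, ranks ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~hit) / n_out
    return float(np.sum(p_in - p_out))


def combine_up_dn(es_up: float, es_dn: float) -> float:
    """Combined score of an UP/DN set family: ES(UP) − ES(DN)."""
    return es_up - es_dn


def ssgsea_matrix(expr: ExpressionMatrix, gene_sets: Sequence[GeneSet],
                  alpha: float = DEFAULT_ALPHA, combine: bool = True) -> pd.DataFrame:
    """Score every gene set in every sample (sets × samples DataFrame).

    With ``combine=True``, any _UP/_DN pair sharing a base name is replaced
    by one combined row (ES_UP − ES_DN) under the base name; unpaired and
    undirected sets keep their own row.
    """
    names = [gs.name for gs in gene_sets]
    if len(set(names)) != len(names):
        raise ValidationError("gene set names must be unique")
    raw = pd.DataFrame(index=names, columns=expr.sample_ids, dtype=float)
    for sample in expr.sample_ids:
        values = expr.values[sample]
        for gs in gene_sets:
            raw.loc[gs.name, sample] = ssgsea_score(values, gs, alpha=alpha)
    if not combine:
        return raw
    return combine_matrix(raw, gene_sets)


def combine_matrix(raw: pd.DataFrame, gene_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Collapse _UP/_DN row pairs of a raw ES matrix into combined rows."""
    by_base: dict = {}
    for gs in gene_sets:
        by_base.setdefault(gs.base_name, {})[gs.direction] = gs.name
    rows, index = [], []
    for base, dirs in by_base.items():
        if "up" in dirs and "dn" in dirs:
            rows.append(raw.loc[dirs["up"]] - raw.loc[dirs["dn"]])
            index.append(base)
        else:
            for name in dirs.values():
                rows.append(raw.loc[name])
                index.append(name)
    return pd.DataFrame(rows, index=index)


def preranked_gsea(ranked: pd.Series, gene_set: Iterable[str],
                   weight_p: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 15, max_size: int = 500,
                   enforce_size: bool = True) -> tuple[float, float]:
    """Preranked GSEA: weighted KS enrichment score and nominal p-value.

    Parameters
    ----------
    ranked
        Per-gene ranking scores (e.g. log2 FC), index = gene ids. The list
        is ordered by score descending (ties broken by gene id) internally,
        so the caller need not pre-sort.
    gene_set
        The set to test; only members present in ``ranked`` count.
    weight_p
        Exponent on |score| for hit increments (1 = classic weighted GSEA,
        0 = unweighted Kolmogorov–Smirnov).
    n_perm, seed
        Size and seed of the random-gene-set null used for the nominal
        p-value: the fraction of the ``n_perm`` null scores that share the
        observed sign and reach at least its magnitude.
    min_size, max_size, enforce_size
        Effective-size bounds (GSEA's defaults are 15–500); set
        ``enforce_size=False`` to override.

    Returns
    -------
    (es, p)
    """
    if ranked.index.duplicated().any():
        raise ValidationError("ranked list contains duplicate genes")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    members = set(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    order = _ranked_genes(ranked)
    scores = ranked.loc[order].to_numpy(dtype=float)
    hit = np.fromiter((g in members for g in order), dtype=bool, count=len(order))
    size = int(hit.sum())
    if size == 0:
        raise ValidationError("gene set shares no genes with the ranked list")
    if enforce_size and not (min_size <= size <= max_size):
        raise ValidationError(
            f"effective gene-set size {size} outside [{min_size}, {max_size}]"
        )
    if size == len(order):
        raise ValidationError("gene set covers the whole ranked list")

    es = _ks_running_es(scores, hit, weight_p)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_hit = np.zeros(len(order), dtype=bool)
        perm_hit[rng.choice(len(order), size=size, replace=False)] = True
        null[i] = _ks_running_es(scores, perm_hit, weight_p)
    same_sign = null >= 0 if es >= 0 else null <= 0
    p = float(np.mean(same_sign & (np.abs(null) >= abs(es))))
    return float(es), p


def _ks_running_es(scores: np.ndarray, hit: np.ndarray, weight_p: float) -> float:
    """Signed maximal deviation of the weighted KS running sum."""
    inc = np.where(hit, np.abs(scores) ** weight_p, 0.0)
    total_hit = inc.sum()
    if total_hit == 0:
        # all in-set ranking scores are exactly zero; fall back to equal weights
        inc = hit.astype(float)
        total_hit = inc.sum()
    n_miss = len(scores) - int(hit.sum())
    running = np.cumsum(inc / total_hit - (~hit).astype(float) / n_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])
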