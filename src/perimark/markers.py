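"""Wilcoxon differential expression and percent-expressed marker selection.

The marker test compares log-normalized expression in stringent pericytes
against all other cells of the same tissue with a two-sided Wilcoxon
rank-sum test, adjusts p-values by Benjamini-Hochberg, and filters
candidates on three expression fractions computed from raw counts:

* ``pct1`` — fraction of stringent pericytes with count > 0 (must exceed 0.80),
* ``pct2`` — fraction of all other cells with count > 0 (must be below 0.05),
* ``pct3`` — the maximum expressing fraction across clusters other than the
  pericyte-enriched one(s); candidates with pct3 below 0.10 are flagged as
  high-specificity markers.

All threshold comparisons are strict. Two Wilcoxon modes are provided: an
exact mode that evaluates the full permutation distribution of the rank sum
(ties handled via midranks, counted by a subset-sum polynomial over doubled
ranks), and a normal approximation with tie-corrected variance and a 0.5
continuity correction.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterLabels
from .io import CountMatrix
from .preprocess import NormMatrix

__all__ = [
    "wilcoxon_test",
    "bh_adjust",
    "de_table",
    "pct3_per_gene",
    "select_markers",
    "cross_tissue_venn",
    "map_orthologs",
]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _exact_ranksum_p(ranks2: np.ndarray, n: int, w2_obs: int) -> float:
    """Two-sided exact p for the rank-sum with doubled midranks ``ranks2``.

    Counts size-n subsets by a subset-sum DP; ties are handled exactly
    because midranks are half-integers, so doubling makes them integers.
    """
    N = len(ranks2)
    total2 = int(ranks2.sum())
    max_s = total2
    # dp[j][s] = number of subsets of size j with doubled rank sum s
    dp = np.zeros((n + 1, max_s + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(n, 0, -1):     # descending: each item used once
            dp[j, r:] += dp[j - 1, : max_s + 1 - r]
    counts = dp[n]
    mean2 = n * (N + 1)     # doubled mean n(N+1)/2
    dev = abs(w2_obs - mean2)
    sums = np.arange(max_s + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    return float(counts[extreme].sum() / comb(N, n))


def _normal_ranksum_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """Normal approximation with tie correction and 0.5 continuity correction."""
    N = len(ranks)
    m = N - n
    mu = n * (N + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    dev = w_obs - mu
    z = (abs(dev) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def wilcoxon_test(
    x: np.ndarray, y: np.ndarray, mode: str = "normal"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns ``(rank_sum, p)`` where ``rank_sum`` is the sum of midranks of
    ``x`` in the pooled sample. ``mode='exact'`` evaluates all C(n+m, n)
    group assignments; ``mode='normal'`` uses the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if mode == "exact":
        ranks2 = np.round(2 * ranks).astype(np.int64)
        w2 = int(round(2 * w))
        p = _exact_ranksum_p(ranks2, x.size, w2)
    else:
        p = _normal_ranksum_p(ranks, x.size, w)
    return w, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def _expressing_fraction(counts: CountMatrix, cols: np.ndarray) -> np.ndarray:
    """Per-gene fraction of the given cells with raw count > 0."""
    sub = counts.values[:, cols]
    nnz = sub.getnnz(axis=1)  # counts are validated nonnegative; nnz == #positive
    return nnz / max(len(cols), 1)


def pct3_per_gene(
    counts: CountMatrix, labels: ClusterLabels, enriched: set[int]
) -> np.ndarray:
    """Max over non-enriched clusters of the cluster's expressing fraction."""
    non_enriched = [c for c in range(labels.n_clusters) if c not in enriched]
    if not non_enriched:
        raise ValueError("all clusters are enriched; pct3 undefined")
    out = np.zeros(counts.n_genes)
    for c in non_enriched:
        members = labels.members(c)
        np.maximum(out, _expressing_fraction(counts, members), out=out)
    return out


def de_table(
    norm: NormMatrix,
    counts: CountMatrix,
    stringent_mask: np.ndarray,
    labels: ClusterLabels,
    enriched: set[int],
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene DE statistics of stringent pericytes vs all other cells.

    Genes expressed (count > 0) in fewer than ``min_cells`` cells are not
    tested. The fold change is computed on de-logged normalized means with a
    pseudocount of 1 on both sides:
    ``log2((mean(expm1 x | stringent) + 1) / (mean(expm1 x | others) + 1))``.
    """
    mask = np.asarray(stringent_mask, dtype=bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < min_cells or n0 < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per group, got {n1} stringent / {n0} other"
        )
    expressed_cells = counts.values.getnnz(axis=1)
    tested = np.where(expressed_cells >= min_cells)[0]

    X = np.asarray(norm.values[tested, :].todense(), dtype=float)
    ranks = stats.rankdata(X, axis=1)
    w = ranks[:, mask].sum(axis=1)
    N = X.shape[1]
    mu = n1 * (N + 1) / 2.0
    var = np.empty(len(tested))
    for i in range(len(tested)):
        _, t = np.unique(X[i], return_counts=True)
        var[i] = n1 * n0 / 12.0 * ((N + 1) - (t**3 - t).sum() / (N * (N - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(w - mu) - 0.5) / np.sqrt(var)
    z = np.clip(z, 0.0, None)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * stats.norm.sf(z)), 1.0)

    mean_str = np.expm1(X[:, mask]).mean(axis=1)
    mean_oth = np.expm1(X[:, ~mask]).mean(axis=1)
    log2fc = np.log2((mean_str + 1.0) / (mean_oth + 1.0))

    pct1 = _expressing_fraction(counts, np.where(mask)[0])[tested]
    pct2 = _expressing_fraction(counts, np.where(~mask)[0])[tested]
    pct3 = pct3_per_gene(counts, labels, enriched)[tested]

    table = pd.DataFrame({
        "gene": [counts.gene_ids[g] for g in tested],
        "avg_log2fc": log2fc,
        "p": p,
        "p_adj": bh_adjust(p),
        "pct1": pct1,
        "pct2": pct2,
        "pct3": pct3,
        "selected": False,
        "high_specificity": False,
    })
    return table


def select_markers(
    table: pd.DataFrame,
    alpha: float = 0.05,
    pct1_min: float = 0.80,
    pct2_max: float = 0.05,
    pct3_max: float = 0.10,
) -> pd.DataFrame:
    """Set selection flags with strict inequalities at every threshold:
    selected iff p_adj < alpha and pct1 > pct1_min and pct2 < pct2_max;
    high_specificity additionally requires pct3 < pct3_max."""
    table = table.copy()
    sel = (table["p_adj"] < alpha) & (table["pct1"] > pct1_min) & (table["pct2"] < pct2_max)
    table["selected"] = sel
    table["high_specificity"] = sel & (table["pct3"] < pct3_max)
    return table


def cross_tissue_venn(marker_sets: dict[str, set[str]]) -> dict[frozenset, list[str]]:
    """Partition the union of per-tissue marker sets by membership pattern.

    Each gene lands in exactly one pattern: the set of tissues whose marker
    set contains it.
    """
    if len(marker_sets) < 2:
        raise ValueError("need marker sets from at least 2 tissues")
    union = set().union(*marker_sets.values())
    out: dict[frozenset, list[str]] = {}
    for gene in sorted(union):
        pattern = frozenset(t for t, s in marker_sets.items() if gene in s)
        out.setdefault(pattern, []).append(gene)
    return out


def venn_to_frame(partition: dict[frozenset, list[str]]) -> pd.DataFrame:
    rows = [
        {"pattern": "+".join(sorted(pat)), "size": len(genes),
         "genes": ",".join(genes)}
        for pat, genes in partition.items()
    ]
    return pd.DataFrame(rows).sort_values("pattern", kind="mergesort").reset_index(drop=True)


def map_orthologs(genes) -> dict[str, str]:
    """Mouse symbol -> human ortholog symbol by the uppercase convention."""
    return {g: g.upper() for g in genes}
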