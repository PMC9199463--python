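"""Pre-ranked gene set enrichment analysis.

Genes are ranked by average log2 fold change (descending, ties by gene ID).
For a gene set, the enrichment score (ES) is the signed maximum deviation
from zero of a running sum that increments by |r|^p / N_R at each set member
("hit") and decrements by 1/(N - N_H) at each non-member, with weight
exponent p = 1 by default. Significance comes from gene-set permutation:
null sets of identical size are drawn uniformly without replacement from
the ranked genes. The permutation p uses an add-one estimator restricted to
same-sign nulls; NES divides ES by the mean |null ES| of the same sign; the
FDR q compares the pooled null NES distribution against the observed NES
distribution sign-by-sign, clipped to [0, 1] and made monotone over the
observed ordering.

Gene-set (rather than phenotype) permutation is the only coherent scheme
for pre-ranked input, where per-sample labels are no longer available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection

logger = logging.getLogger("perimark")

__all__ = ["RankedList", "rank_by_log2fc", "enrichment_score", "preranked_gsea"]


@dataclass
class RankedList:
    """Genes sorted by ranking metric descending, ties by gene ID ascending."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        for i in range(len(self.genes) - 1):
            a, b = self.metric[i], self.metric[i + 1]
            if a < b or (a == b and self.genes[i] > self.genes[i + 1]):
                raise ValueError("list not sorted by (metric desc, gene asc)")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_log2fc(table: pd.DataFrame) -> RankedList:
    """Ranked list from a marker table: avg_log2fc descending, ties by gene."""
    if table.empty:
        raise ValueError("marker table is empty")
    df = table.sort_values(["avg_log2fc", "gene"], ascending=[False, True],
                           kind="mergesort")
    return RankedList(list(df["gene"]), df["avg_log2fc"].to_numpy())


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running-sum curve for one gene set.

    The curve has one value per list position. When the maximum positive and
    negative deviations tie in magnitude the positive one is reported.
    """
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.genes])
    n_hit = int(hits.sum())
    N = len(ranked)
    if n_hit == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    if n_hit == N:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.metric) ** weight_p
    w_hit = np.where(hits, w, 0.0)
    n_r = w_hit.sum()
    if n_r == 0:
        w_hit = hits.astype(float)   # all hit weights zero: fall back to equal
        n_r = float(n_hit)
    steps = np.where(hits, w_hit / n_r, -1.0 / (N - n_hit))
    curve = np.cumsum(steps)
    i_max, i_min = int(np.argmax(curve)), int(np.argmin(curve))
    top, bottom = curve[i_max], curve[i_min]
    es = top if top >= -bottom else bottom
    return float(es), curve


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n_miss_denom: int
) -> np.ndarray:
    """Vectorized ES for many same-size sets given their hit positions.

    ``positions`` is (n_sets, s), 0-based, sorted ascending per row;
    ``weights`` is |r|^p over the full ranked list. Agrees with the explicit
    walk of :func:`enrichment_score`.
    """
    pos = np.sort(positions, axis=1)
    w = weights[pos]
    n_r = w.sum(axis=1, keepdims=True)
    s = pos.shape[1]
    uniform = (n_r == 0).ravel()
    cum = np.where(n_r > 0, np.cumsum(w, axis=1) / np.where(n_r > 0, n_r, 1), 0.0)
    if uniform.any():
        cum[uniform] = (np.arange(1, s + 1) / s)[None, :]
    k = np.arange(1, s + 1)[None, :]
    top = cum - (pos + 1 - k) / n_miss_denom          # just after each hit
    prev = np.concatenate([np.zeros((pos.shape[0], 1)), cum[:, :-1]], axis=1)
    bottom = prev - (pos - (k - 1)) / n_miss_denom    # just before each hit
    t = top.max(axis=1)
    b = bottom.min(axis=1)
    return np.where(t >= -b, t, b)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Permutation GSEA over a collection; returns one record per set.

    Columns: set, size, es, nes, p_perm, fdr_q, significant. Deterministic
    given ``seed`` (sets are processed in sorted name order). Sets sharing
    no genes with the ranked list are dropped with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    N = len(ranked)
    weights = np.abs(ranked.metric) ** weight_p
    rng = np.random.default_rng(seed)

    names, sizes, es_obs = [], [], []
    null_es: list[np.ndarray] = []
    for name in collection:
        members = collection[name] & set(ranked.genes)
        if not members:
            logger.warning("gene set %s shares no genes with the ranking; dropped", name)
            continue
        if len(members) == N:
            raise ValueError(f"gene set {name} covers the entire ranked list")
        es, _ = enrichment_score(ranked, members, weight_p)
        s = len(members)
        r = rng.random((n_perm, N))
        pos = np.argpartition(r, s - 1, axis=1)[:, :s]
        null = _es_from_positions(weights, pos, N - s)
        names.append(name)
        sizes.append(s)
        es_obs.append(es)
        null_es.append(null)

    es_obs = np.array(es_obs)
    p_perm = np.empty(len(names))
    nes = np.empty(len(names))
    null_nes_pool: list[np.ndarray] = []
    for i, null in enumerate(null_es):
        positive = es_obs[i] >= 0
        same = (null >= 0) if positive else (null < 0)
        n_same = int(same.sum())
        if n_same == 0:
            p_perm[i] = 1.0
            nes[i] = 0.0
        else:
            extreme = same & (np.abs(null) >= abs(es_obs[i]))
            p_perm[i] = (1 + int(extreme.sum())) / (1 + n_same)
            nes[i] = es_obs[i] / np.abs(null[same]).mean()
        # normalize this set's null the same way, for the pooled FDR null
        pos_mask, neg_mask = null >= 0, null < 0
        nn = np.zeros_like(null)
        if pos_mask.any():
            nn[pos_mask] = null[pos_mask] / np.abs(null[pos_mask]).mean()
        if neg_mask.any():
            nn[neg_mask] = null[neg_mask] / np.abs(null[neg_mask]).mean()
        null_nes_pool.append(nn)

    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    fdr_q = np.ones(len(names))
    for sign in (1.0, -1.0):
        obs_idx = np.where((nes >= 0) if sign > 0 else (nes < 0))[0]
        if obs_idx.size == 0:
            continue
        null_side = pooled[(pooled >= 0) if sign > 0 else (pooled < 0)]
        for i in obs_idx:
            thr = abs(nes[i])
            frac_null = (
                float((np.abs(null_side) >= thr).sum()) / len(null_side)
                if len(null_side) else 0.0
            )
            obs_side = np.abs(nes[obs_idx])
            frac_obs = float((obs_side >= thr).sum()) / len(obs_idx)
            fdr_q[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
        # enforce monotonicity: a more extreme set never has a larger q
        order = obs_idx[np.argsort(-np.abs(nes[obs_idx]), kind="mergesort")]
        running = np.inf
        for i in order[::-1]:
            running = min(running, fdr_q[i])
            fdr_q[i] = running

    df = pd.DataFrame({
        "set": names,
        "size": sizes,
        "es": es_obs,
        "nes": nes,
        "p_perm": p_perm,
        "fdr_q": fdr_q,
        "significant": fdr_q < q_threshold,
    })
    return df.sort_values(["fdr_q", "set"], kind="mergesort").reset_index(drop=True)
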