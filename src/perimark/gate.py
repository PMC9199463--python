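"""Pericyte-enriched cluster identification and stringent-pericyte gating.

A cluster is pericyte-enriched when a disproportionate fraction of its cells
co-express both canonical mural markers (raw count > 0 for each): the
dual-positive fraction must clear an absolute floor AND a fold over the
global dual-positive fraction. "Stringent pericytes" are the cells inside
enriched clusters that themselves co-express both markers. Multiple enriched
clusters per tissue are pooled for gating.

"Expressing" always means raw count > 0; no magnitude threshold is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterLabels
from .io import CountMatrix

logger = logging.getLogger("perimark")

__all__ = ["GateParams", "GateResult", "find_enriched_clusters",
           "gate_stringent", "gate_summary", "run_gate"]


@dataclass
class GateParams:
    """Dual-marker gate thresholds.

    ``min_dual_fraction`` is the absolute floor on a cluster's dual-positive
    fraction; ``fold_over_global`` the required fold over the tissue-wide
    dual-positive fraction.
    """

    marker_a: str = "Cspg4"
    marker_b: str = "Pdgfrb"
    min_dual_fraction: float = 0.05
    fold_over_global: float = 5.0

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise ValueError("gate markers must be distinct")
        if self.min_dual_fraction <= 0 or self.fold_over_global <= 0:
            raise ValueError("gate thresholds must be positive")


@dataclass
class GateResult:
    """Enriched clusters, stringent mask, and per-tissue bookkeeping."""

    enriched_cluster_ids: set[int]
    stringent_mask: np.ndarray
    summary: pd.DataFrame

    def __post_init__(self) -> None:
        self.stringent_mask = np.asarray(self.stringent_mask, dtype=bool)


def _dual_positive(counts: CountMatrix, params: GateParams) -> np.ndarray:
    ia = counts.gene_index(params.marker_a)
    ib = counts.gene_index(params.marker_b)
    a = np.asarray(counts.values[ia].todense()).ravel() > 0
    b = np.asarray(counts.values[ib].todense()).ravel() > 0
    return a & b


def find_enriched_clusters(
    counts: CountMatrix, labels: ClusterLabels, params: GateParams
) -> set[int]:
    """Clusters whose dual-positive fraction f_c satisfies
    f_c >= min_dual_fraction and f_c >= fold_over_global * global fraction.

    May return several clusters; an empty set is returned with a warning
    when none qualifies.
    """
    if len(labels.labels) != counts.n_cells:
        raise ValueError("labels do not cover all cells")
    dual = _dual_positive(counts, params)
    n = counts.n_cells
    n_dual = int(dual.sum())
    enriched: set[int] = set()
    for c in range(labels.n_clusters):
        members = labels.members(c)
        f_c = dual[members].mean()
        # background = dual-positive fraction among cells outside the
        # candidate cluster (self-excluded, so a lone hot cluster in an
        # otherwise cold tissue always clears the fold)
        n_out = n - len(members)
        f_out = (n_dual - dual[members].sum()) / n_out if n_out else 0.0
        if f_c >= params.min_dual_fraction and f_c >= params.fold_over_global * f_out:
            enriched.add(c)
    if not enriched:
        logger.warning(
            "tissue %s: no cluster passes the dual-marker enrichment rule "
            "(global dual-positive fraction %.4f)", counts.tissue, dual.mean(),
        )
    return enriched


def gate_stringent(
    counts: CountMatrix,
    labels: ClusterLabels,
    enriched: set[int],
    params: GateParams,
) -> np.ndarray:
    """Per-cell stringent-pericyte mask: cluster in ``enriched`` AND both
    marker counts > 0."""
    if not enriched:
        raise ValueError("enriched cluster set is empty")
    dual = _dual_positive(counts, params)
    in_enriched = np.isin(labels.labels, sorted(enriched))
    return in_enriched & dual


def gate_summary(
    mask: np.ndarray,
    labels: ClusterLabels,
    enriched: set[int],
    tissue: str,
) -> pd.DataFrame:
    """Per-tissue stringent counts and proportion within enriched clusters."""
    mask = np.asarray(mask, dtype=bool)
    in_enriched = np.isin(labels.labels, sorted(enriched))
    n_stringent = int(mask.sum())
    n_enriched = int(in_enriched.sum())
    proportion = n_stringent / n_enriched if n_enriched else 0.0
    return pd.DataFrame(
        [{
            "tissue": tissue,
            "n_stringent": n_stringent,
            "n_enriched_cells": n_enriched,
            "proportion": proportion,
        }]
    )


def combine_summaries(per_tissue: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-tissue summaries and append the cross-tissue total row."""
    df = pd.concat(per_tissue, ignore_index=True)
    total = pd.DataFrame([{
        "tissue": "TOTAL",
        "n_stringent": int(df["n_stringent"].sum()),
        "n_enriched_cells": int(df["n_enriched_cells"].sum()),
        "proportion": (
            df["n_stringent"].sum() / df["n_enriched_cells"].sum()
            if df["n_enriched_cells"].sum() else 0.0
        ),
    }])
    return pd.concat([df, total], ignore_index=True)


def run_gate(
    counts: CountMatrix, labels: ClusterLabels, params: GateParams
) -> GateResult:
    """Full gate for one tissue. With no enriched cluster the mask is all
    False and downstream marker discovery should be skipped."""
    enriched = find_enriched_clusters(counts, labels, params)
    if enriched:
        mask = gate_stringent(counts, labels, enriched, params)
    else:
        mask = np.zeros(counts.n_cells, dtype=bool)
    summary = gate_summary(mask, labels, enriched, counts.tissue)
    return GateResult(enriched, mask, summary)
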