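"""Spatial-spot clustering and marker co-localization.

Spots are transcript aggregates on an integer array grid (rectangular,
4-connected), not single cells. They are clustered with the same
log-normalize / HVG / PCA / SNN-Louvain stack as cells; pericyte spots are
designated at the cluster level by the dual-marker enrichment rule, so all
spots of a qualifying cluster are included (clusters may be pooled).
Co-localization of two marker spot sets with the pericyte spots is reported
as the full 7-region Venn partition plus overlap percentages with explicit
denominators: pct_overlap(X) = 100 * |X & P| / |P| and
pct_both_in_p = 100 * |A & B & P| / |P|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import gate as _gate
from . import preprocess as _pre
from .cluster import ClusterLabels
from .gate import GateParams
from .io import CountMatrix

logger = logging.getLogger("perimark")

__all__ = ["SpotTable", "VennResult", "cluster_spots",
           "designate_pericyte_spots", "spot_sets", "venn_colocalize"]


@dataclass
class SpotTable:
    """Barcoded spots with integer array coordinates and per-spot counts.

    ``counts`` is a gene x spot :class:`CountMatrix`; ``coords`` is (n, 2)
    integer (row, col), unique per spot.
    """

    barcodes: list[str]
    coords: np.ndarray
    counts: CountMatrix

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.shape != (len(self.barcodes), 2):
            raise ValueError("coords must be (n_spots, 2)")
        if len({tuple(c) for c in self.coords}) != len(self.barcodes):
            raise ValueError("spot coordinates must be unique")
        if self.counts.n_cells != len(self.barcodes):
            raise ValueError("counts do not match the spot list")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def write(self, csv_path, bundle_dir) -> None:
        """Spot CSV (barcode,row,col) plus a matching MTX count bundle."""
        from .io import write_mtx_bundle
        pd.DataFrame({
            "barcode": self.barcodes,
            "row": self.coords[:, 0],
            "col": self.coords[:, 1],
        }).to_csv(csv_path, index=False)
        write_mtx_bundle(self.counts, bundle_dir)

    @classmethod
    def read(cls, csv_path, bundle_dir) -> "SpotTable":
        from .io import read_mtx_bundle
        df = pd.read_csv(csv_path)
        counts = read_mtx_bundle(bundle_dir, tissue="spatial")
        if list(df["barcode"]) != counts.barcodes:
            raise ValueError("spot CSV barcodes do not match count bundle")
        return cls(list(df["barcode"]), df[["row", "col"]].to_numpy(), counts)


@dataclass
class VennResult:
    """Sizes of the 7 regions of the (A, B, P) partition plus overlap
    percentages against |P| (the pericyte-spot denominator)."""

    regions: dict[str, int]
    pct_overlap_a: float
    pct_overlap_b: float
    pct_both_in_p: float

    REGION_KEYS = (
        "A_only", "B_only", "P_only", "AB_only", "AP_only", "BP_only", "ABP",
    )

    def __post_init__(self) -> None:
        missing = set(self.REGION_KEYS) - set(self.regions)
        if missing:
            raise ValueError(f"missing Venn regions {missing}")
        if any(v < 0 for v in self.regions.values()):
            raise ValueError("region sizes must be nonnegative")

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "size": self.regions[k]} for k in self.REGION_KEYS]
        rows += [
            {"region": "pct_overlap_A", "size": self.pct_overlap_a},
            {"region": "pct_overlap_B", "size": self.pct_overlap_b},
            {"region": "pct_both_in_P", "size": self.pct_both_in_p},
        ]
        return pd.DataFrame(rows)


def cluster_spots(
    spots: SpotTable,
    n_hvg: int = 2000,
    n_pcs: int = 10,
    k: int = 20,
    prune: float = 1 / 15,
    resolution: float = 0.5,
    seed: int = 0,
    scale_factor: float = 10_000.0,
) -> ClusterLabels:
    """Unsupervised clustering of spots with the single-cell stack."""
    if spots.n_spots < 2:
        raise ValueError("need at least 2 spots")
    norm = _pre.log_normalize(spots.counts, scale_factor)
    hvgs = _pre.select_hvg_vst(spots.counts, n_hvg)
    n_pcs = min(n_pcs, len(hvgs) - 1, spots.n_spots - 1)
    emb = _pre.scale_and_pca(norm, hvgs, n_pcs)
    neighbors = _cluster.knn(emb, min(k, spots.n_spots - 1))
    graph = _cluster.snn_jaccard(neighbors, prune)
    return _cluster.louvain(graph, resolution, seed)


def designate_pericyte_spots(
    spots: SpotTable, labels: ClusterLabels, params: GateParams
) -> set[str]:
    """All spots of clusters passing the dual-positive enrichment rule.

    Cluster-level designation: entire qualifying clusters are returned (and
    pooled when several qualify); an empty set with a warning when none does.
    """
    enriched = _gate.find_enriched_clusters(spots.counts, labels, params)
    if not enriched:
        logger.warning("no spot cluster qualifies as pericyte-enriched")
        return set()
    in_enriched = np.isin(labels.labels, sorted(enriched))
    return {spots.barcodes[i] for i in np.where(in_enriched)[0]}


def spot_sets(spots: SpotTable, gene: str) -> set[str]:
    """Spots with count > 0 for ``gene`` (strictly positive)."""
    g = spots.counts.gene_index(gene)
    row = np.asarray(spots.counts.values[g].todense()).ravel()
    return {spots.barcodes[i] for i in np.where(row > 0)[0]}


def venn_colocalize(set_a: set, set_b: set, pericyte_spots: set) -> VennResult:
    """7-region Venn of marker spot sets A, B and pericyte spots P."""
    A, B, P = set(set_a), set(set_b), set(pericyte_spots)
    regions = {
        "A_only": len(A - B - P),
        "B_only": len(B - A - P),
        "P_only": len(P - A - B),
        "AB_only": len((A & B) - P),
        "AP_only": len((A & P) - B),
        "BP_only": len((B & P) - A),
        "ABP": len(A & B & P),
    }
    denom = len(P)
    pct = lambda x: 100.0 * x / denom if denom else 0.0
    return VennResult(
        regions,
        pct_overlap_a=pct(len(A & P)),
        pct_overlap_b=pct(len(B & P)),
        pct_both_in_p=pct(len(A & B & P)),
    )
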