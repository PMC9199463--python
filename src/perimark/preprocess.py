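"""Normalization, variable-gene selection, scaling and PCA.

The droplet convention throughout: counts are depth-normalized to a
``scale_factor`` (default 10,000) per cell and log-transformed with a
pseudocount of 1 (natural log). Highly variable genes are ranked by the
variance-stabilizing-transformation score: the variance of standardized
counts, where each gene's expected standard deviation comes from a local
polynomial regression (span 0.3, degree 2) of log10 variance on log10 mean,
and standardized values are clipped at sqrt(n_cells). PCA operates on
per-gene z-scores clipped at +/-10, via SVD of the re-centered matrix, with
each component's sign fixed so its largest-magnitude gene loading is
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io import CountMatrix

logger = logging.getLogger("perimark")

__all__ = ["NormMatrix", "Embedding", "log_normalize", "select_hvg_vst", "scale_and_pca"]


@dataclass
class NormMatrix:
    """Log-normalized gene x cell expression; zeros stay zero."""

    values: sparse.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    scale_factor: float = 10_000.0

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


@dataclass
class Embedding:
    """Cell x d PC scores with per-component explained variance."""

    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray          # genes (HVGs) x d
    hvgs: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained variance must be non-increasing")

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormMatrix:
    """x_gj = ln(1 + c_gj * S / L_j), L_j the cell's library size.

    Cells with zero library size are an error (their barcodes are listed).
    """
    lib = counts.library_sizes().astype(float)
    zero = np.where(lib == 0)[0]
    if zero.size:
        bad = [counts.barcodes[i] for i in zero[:10]]
        raise ValueError(
            f"{zero.size} cell(s) have zero library size, e.g. {bad}"
        )
    mat = counts.values.tocsc().astype(float)
    # scale columns by S / L_j, then log1p on stored entries only
    mat = mat @ sparse.diags(scale_factor / lib)
    mat.data = np.log1p(mat.data)
    return NormMatrix(mat.tocsr(), list(counts.gene_ids), list(counts.barcodes),
                      scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# VST highly variable genes
# ---------------------------------------------------------------------------

def _loess_quadratic(x: np.ndarray, y: np.ndarray, span: float, xout: np.ndarray) -> np.ndarray:
    """Local quadratic regression with tricube weights.

    For each output point, fits a degree-2 weighted polynomial to the
    ceil(span*n) nearest x-values. Matches the classic loess definition used
    for the mean-variance trend.
    """
    n = len(x)
    q = min(max(int(np.ceil(span * n)), 3), n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    out = np.empty(len(xout))
    for i, x0 in enumerate(xout):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        X = np.column_stack([np.ones(q), xs[idx] - x0, (xs[idx] - x0) ** 2])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def _gene_moments(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and (ddof=1) variance of raw counts."""
    n = counts.n_cells
    mat = counts.values.astype(float)
    mu = np.asarray(mat.mean(axis=1)).ravel()
    sq = np.asarray(mat.multiply(mat).mean(axis=1)).ravel()
    var = (sq - mu**2) * n / (n - 1)
    return mu, np.maximum(var, 0.0)


def vst_scores(counts: CountMatrix, span: float = 0.3) -> np.ndarray:
    """Per-gene VST variability score (variance of clipped standardized counts)."""
    if counts.n_cells < 2:
        raise ValueError("VST needs at least 2 cells")
    n = counts.n_cells
    mu, var = _gene_moments(counts)
    scores = np.zeros(counts.n_genes)
    varying = var > 1e-10 * np.maximum(mu**2, 1.0)  # guard against float dust
    if not varying.any():
        return scores
    lx = np.log10(mu[varying])
    ly = np.log10(var[varying])
    fit = _loess_quadratic(lx, ly, span, lx)
    sd_exp = np.sqrt(10.0 ** fit)
    clip = np.sqrt(n)

    csr = counts.values.tocsr()
    vidx = np.where(varying)[0]
    for pos, g in enumerate(vidx):
        row = csr.getrow(g)
        vals = row.data.astype(float)
        nnz = vals.size
        m, sd = mu[g], sd_exp[pos]
        z_nz = np.clip((vals - m) / sd, -clip, clip)
        z0 = float(np.clip((0.0 - m) / sd, -clip, clip))
        total = z_nz.sum() + z0 * (n - nnz)
        total_sq = (z_nz**2).sum() + z0**2 * (n - nnz)
        mean_z = total / n
        scores[g] = max((total_sq - n * mean_z**2) / (n - 1), 0.0)
    return scores


def select_hvg_vst(counts: CountMatrix, n_top: int = 2000, span: float = 0.3) -> list[str]:
    """Top ``n_top`` genes by VST score, ties broken by gene ID ascending.

    If ``n_top`` exceeds the gene count, all genes are returned with a
    warning.
    """
    if n_top > counts.n_genes:
        logger.warning(
            "n_top=%d exceeds %d genes; returning all", n_top, counts.n_genes
        )
        n_top = counts.n_genes
    scores = vst_scores(counts, span=span)
    order = sorted(range(counts.n_genes), key=lambda g: (-scores[g], counts.gene_ids[g]))
    return [counts.gene_ids[g] for g in order[:n_top]]


# ---------------------------------------------------------------------------
# Scaling and PCA
# ---------------------------------------------------------------------------

def scale_and_pca(
    norm: NormMatrix, hvgs: list[str], n_pcs: int, clip: float = 10.0
) -> Embedding:
    """Z-score each HVG over cells, clip at +/-``clip``, re-center, and take
    the top ``n_pcs`` principal components by SVD.

    Sign convention: each component is flipped, if needed, so that its
    largest-magnitude gene loading is positive — deterministic across
    linear-algebra backends.
    """
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in hvgs if g not in index]
    if missing:
        raise ValueError(f"HVGs not in gene universe: {missing[:5]}")
    n_cells = norm.n_cells
    if not (0 < n_pcs < min(len(hvgs), n_cells)):
        raise ValueError(
            f"n_pcs={n_pcs} must be in (0, min(n_hvg={len(hvgs)}, n_cells={n_cells}))"
        )
    rows = [index[g] for g in hvgs]
    X = np.asarray(norm.values[rows, :].todense(), dtype=float)  # hvg x cells
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)   # population sd: cell-duplication invariant
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    Zc = Z - Z.mean(axis=1, keepdims=True)          # re-center after clipping

    # SVD of cells x genes
    U, S, Vt = np.linalg.svd(Zc.T, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    loadings = Vt.T                                  # genes x d
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = (U * S) * flip

    ev = S**2 / (n_cells - 1)
    total_var = (Zc**2).sum() / (n_cells - 1)
    ratio = ev / total_var if total_var > 0 else np.zeros_like(ev)
    return Embedding(scores, ev, ratio, loadings, list(hvgs))
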