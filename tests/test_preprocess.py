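import numpy as np
import pytest
from scipy import sparse, stats

from perimark.io import CountMatrix
from perimark.preprocess import (
    log_normalize,
    scale_and_pca,
    select_hvg_vst,
    vst_scores,
)


def _counts(dense, tissue="t"):
    dense = np.asarray(dense)
    genes = [f"g{i:03d}" for i in range(dense.shape[0])]
    cells = [f"c{j:03d}" for j in range(dense.shape[1])]
    return CountMatrix(sparse.csr_matrix(dense), genes, cells, tissue=tissue)


class TestLogNormalize:
    def test_closed_form(self):
        # count 1 in a cell of library size 100 at scale 10,000 -> ln(101)
        counts = _counts([[1], [99]])
        norm = log_normalize(counts, scale_factor=10_000)
        assert norm.values[0, 0] == pytest.approx(np.log(101.0), abs=1e-9)

    def test_zero_count_stays_zero(self, random_counts):
        counts = random_counts(seed=1)
        norm = log_normalize(counts)
        assert norm.values.nnz == counts.values.nnz
        dense_c = np.asarray(counts.values.todense())
        dense_n = np.asarray(norm.values.todense())
        assert (dense_n[dense_c == 0] == 0).all()

    def test_monotone_per_gene_with_equal_libraries(self):
        # equal library sizes: per-gene value order equals count order
        dense = np.array([[5, 1, 3, 0], [0, 4, 2, 5], [5, 5, 5, 5]])
        counts = _counts(dense)
        norm = log_normalize(counts)
        vals = np.asarray(norm.values.todense())
        for g in range(3):
            assert (stats.rankdata(vals[g]) == stats.rankdata(dense[g])).all()

    def test_zero_library_cell_listed(self):
        counts = _counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c001"):
            log_normalize(counts)


def _vst_oracle(dense, span=0.3):
    """Literal step-by-step reimplementation of the VST score with dense
    python loops and an independently assembled local quadratic fit."""
    dense = np.asarray(dense, dtype=float)
    n_genes, n_cells = dense.shape
    mu = dense.mean(axis=1)
    var = dense.var(axis=1, ddof=1)
    scores = np.zeros(n_genes)
    varying = [g for g in range(n_genes) if var[g] > 0]
    lx = np.log10(mu[varying])
    ly = np.log10(var[varying])
    q = max(int(np.ceil(span * len(varying))), 3)
    clip = np.sqrt(n_cells)
    for pos, g in enumerate(varying):
        x0 = lx[pos]
        d = np.abs(lx - x0)
        nearest = np.argsort(d, kind="mergesort")[:q]
        dmax = d[nearest].max()
        if dmax == 0:
            fit0 = ly[nearest].mean()
        else:
            w = (1 - (d[nearest] / dmax) ** 3) ** 3
            A = np.vander(lx[nearest] - x0, 3, increasing=True)  # [1, dx, dx^2]
            W = np.diag(w)
            beta = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(W) @ ly[nearest], rcond=None)[0]
            fit0 = beta[0]
        sd_exp = np.sqrt(10.0 ** fit0)
        z = [min(max((c - mu[g]) / sd_exp, -clip), clip) for c in dense[g]]
        zbar = sum(z) / n_cells
        scores[g] = sum((v - zbar) ** 2 for v in z) / (n_cells - 1)
    return scores


class TestHvgVst:
    def test_constant_gene_scores_zero(self):
        dense = np.vstack([np.full(10, 4), np.arange(10), np.arange(10) * 3])
        counts = _counts(dense)
        scores = vst_scores(counts)
        assert scores[0] == 0
        top = select_hvg_vst(counts, 2)
        assert "g000" not in top

    def test_n_top_equal_to_gene_count_is_permutation(self, random_counts):
        counts = random_counts(n_genes=25, seed=2)
        top = select_hvg_vst(counts, 25)
        assert sorted(top) == sorted(counts.gene_ids)

    def test_n_top_exceeding_gene_count_warns(self, random_counts, caplog):
        counts = random_counts(n_genes=10, seed=2)
        import logging
        with caplog.at_level(logging.WARNING, logger="perimark"):
            top = select_hvg_vst(counts, 99)
        assert len(top) == 10
        assert "exceeds" in caplog.text

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(42)
        lam = rng.gamma(2.0, 1.0, size=50)
        dense = rng.poisson(lam[:, None] * rng.uniform(0.5, 2.0, size=60))
        counts = _counts(dense)
        got = vst_scores(counts)
        expected = _vst_oracle(dense)
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_invariant_under_gene_permutation(self, random_counts):
        counts = random_counts(n_genes=30, seed=5)
        perm = np.random.default_rng(0).permutation(30)
        dense = np.asarray(counts.values.todense())[perm]
        shuffled = CountMatrix(
            sparse.csr_matrix(dense),
            [counts.gene_ids[i] for i in perm], counts.barcodes,
        )
        s1 = vst_scores(counts)
        s2 = vst_scores(shuffled)
        np.testing.assert_allclose(s1[perm], s2, atol=1e-10)


class TestScaleAndPca:
    def test_collinear_cells_one_component(self):
        dense = 40 + np.outer([3, -2, 5], np.arange(12))  # exactly collinear
        counts = _counts(dense)
        norm = log_normalize(counts)
        # bypass the log transform's mild nonlinearity: feed values directly
        norm.values = sparse.csr_matrix(dense.astype(float))
        emb = scale_and_pca(norm, counts.gene_ids, n_pcs=2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        dense = rng.poisson(3.0, size=(20, 10)).astype(float)
        counts = _counts(dense.astype(int))
        norm = log_normalize(counts)
        emb = scale_and_pca(norm, counts.gene_ids, n_pcs=4, clip=10)

        X = np.asarray(norm.values.todense())
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1
        Z = np.clip((X - mu) / sd, -10, 10)
        Zc = Z - Z.mean(axis=1, keepdims=True)
        C = Zc @ Zc.T / (X.shape[1] - 1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:4]
        scores_oracle = Zc.T @ evecs[:, order]
        np.testing.assert_allclose(
            np.abs(emb.scores), np.abs(scores_oracle), atol=1e-6
        )
        np.testing.assert_allclose(
            emb.explained_variance, evals[order], atol=1e-6
        )

    def test_duplicating_cells_preserves_directions(self, random_counts):
        counts = random_counts(n_genes=15, n_cells=20, seed=9)
        norm = log_normalize(counts)
        emb1 = scale_and_pca(norm, counts.gene_ids, n_pcs=3)

        dense = np.asarray(counts.values.todense())
        doubled = CountMatrix(
            sparse.csr_matrix(np.hstack([dense, dense])),
            counts.gene_ids, counts.barcodes + [b + "_dup" for b in counts.barcodes],
        )
        emb2 = scale_and_pca(log_normalize(doubled), counts.gene_ids, n_pcs=3)
        np.testing.assert_allclose(emb2.loadings, emb1.loadings, atol=1e-8)
        np.testing.assert_allclose(emb2.scores[:20], emb1.scores, atol=1e-8)
        np.testing.assert_allclose(emb2.scores[20:], emb1.scores, atol=1e-8)

    def test_reconstruction_error_non_increasing(self, random_counts):
        counts = random_counts(n_genes=12, n_cells=18, seed=4)
        norm = log_normalize(counts)
        errors = []
        for k in range(1, 6):
            emb = scale_and_pca(norm, counts.gene_ids, n_pcs=k)
            recon = emb.scores @ emb.loadings.T
            X = np.asarray(norm.values.todense())
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            sd[sd == 0] = 1
            Z = np.clip((X - mu) / sd, -10, 10)
            Zc = Z - Z.mean(axis=1, keepdims=True)
            errors.append(np.linalg.norm(Zc.T - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_n_pcs_too_large_rejected(self, random_counts):
        counts = random_counts(n_genes=5, n_cells=8)
        norm = log_normalize(counts)
        with pytest.raises(ValueError, match="n_pcs"):
            scale_and_pca(norm, counts.gene_ids, n_pcs=5)
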