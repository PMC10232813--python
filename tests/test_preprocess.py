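"""QC boundary behavior, normalization exactness, VST-HVG ranking, scaling."""

import numpy as np
import pytest
import scipy.sparse as sp

from ifndirect import (QCThresholds, filter_cells, find_variable_genes,
                       normalize, scale_genes)
from ifndirect.preprocess import _loess_trend

from conftest import dense_matrix


def _matrix_with_detected(counts_per_cell, n_genes=2600):
    """Cells detecting exactly the requested number of genes (1 count each);
    the single mito gene row stays zero everywhere (0% mito)."""
    cols = []
    for n in counts_per_cell:
        col = np.zeros(n_genes, dtype=int)
        col[1:n + 1] = 1  # row 0 is the mito gene, left at zero
        cols.append(col)
    genes = ["mt-x"] + [f"G{i}" for i in range(n_genes - 1)]
    return dense_matrix(np.column_stack(cols), genes=genes)


class TestQC:
    def test_inclusive_bounds_and_strict_mito(self):
        cm = _matrix_with_detected([150, 200, 1000, 2000, 2500])
        filtered, report = filter_cells(cm, QCThresholds())
        assert report["kept"].tolist() == [False, True, True, True, False]
        assert filtered.n_cells == 3

    def test_pct_mito_exactly_one_dropped(self):
        # 1 mito count in 100 -> exactly 1.0% (strict bound); 1 in 101 kept
        genes = ["mt-a"] + [f"G{i}" for i in range(300)]
        col_a = np.r_[1, np.ones(99, dtype=int), np.zeros(201, dtype=int)]
        col_b = np.r_[1, np.ones(100, dtype=int), np.zeros(200, dtype=int)]
        cm = dense_matrix(np.column_stack([col_a, col_b]), genes=genes)
        _f, report = filter_cells(cm, QCThresholds(min_genes=10))
        assert report["pct_mito"].tolist() == [1.0, pytest.approx(100 / 101)]
        assert report["kept"].tolist() == [False, True]

    def test_mito_prefix_case_insensitive(self):
        genes = ["MT-a"] + [f"G{i}" for i in range(300)]
        col = np.r_[50, np.ones(250, dtype=int), np.zeros(50, dtype=int)]
        cm = dense_matrix(col[:, None], genes=genes)
        with pytest.raises(ValueError, match="empty after QC"):
            filter_cells(cm, QCThresholds(min_genes=10))

    def test_idempotent(self, small_datasets):
        cm = small_datasets["control"].counts
        once, _ = filter_cells(cm, QCThresholds())
        twice, report = filter_cells(once, QCThresholds())
        assert report["kept"].all()
        assert (once.counts != twice.counts).nnz == 0

    def test_empty_after_qc_is_error(self):
        cm = dense_matrix(np.ones((50, 3), dtype=int))
        with pytest.raises(ValueError, match="empty after QC"):
            filter_cells(cm, QCThresholds())  # only 50 genes detectable


class TestNormalize:
    def test_counts_per_ten_thousand(self):
        cm = dense_matrix(np.array([[2], [3], [5]]))
        nm = normalize(cm)
        np.testing.assert_allclose(
            np.asarray(nm.values.todense()).ravel(), [2000, 3000, 5000])

    def test_column_sums_equal_scale_total(self, small_datasets):
        cm = small_datasets["control"].counts
        nm = normalize(cm)
        sums = np.asarray(nm.values.sum(axis=0)).ravel()
        np.testing.assert_allclose(sums, 10_000.0, rtol=1e-9)

    def test_all_zero_gene_stays_zero(self):
        cm = dense_matrix(np.array([[0, 0], [1, 2]]))
        nm = normalize(cm)
        log = nm.log1p()
        assert np.asarray(nm.values.todense())[0].sum() == 0
        assert np.asarray(log.values.todense())[0].sum() == 0

    def test_zero_total_cell_names_barcode(self):
        cm = dense_matrix(np.array([[1, 0], [1, 0]]),
                          barcodes=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            normalize(cm)

    def test_log1p_matches_numpy(self):
        cm = dense_matrix(np.array([[2, 1], [3, 0], [5, 1]]))
        log = normalize(cm).log1p()
        lin = np.asarray(normalize(cm).values.todense())
        np.testing.assert_allclose(np.asarray(log.values.todense()),
                                   np.log1p(lin))


class TestHVG:
    def test_dominant_gene_ranked_first(self):
        # Poisson genes across a realistic mean range anchor the variance
        # trend; a bimodal gene in the middle of that range has far higher
        # standardized variance and must lead the ranking
        rng = np.random.default_rng(0)
        means = np.geomspace(1.0, 60.0, 40)
        base = rng.poisson(means[:, None], size=(40, 300))
        loud = np.where(rng.random(300) < 0.5, 40, 0)[None, :]
        cm = dense_matrix(np.vstack([loud, base]),
                          genes=["Loud"] + [f"G{i}" for i in range(40)])
        assert find_variable_genes(cm, n_top=10)[0] == "Loud"

    def test_n_top_larger_than_gene_count_warns(self):
        rng = np.random.default_rng(1)
        cm = dense_matrix(rng.poisson(2.0, size=(40, 100)))
        with pytest.warns(UserWarning, match="nonzero variance"):
            out = find_variable_genes(cm, n_top=1000)
        assert len(out) <= 40

    def test_too_few_expressed_genes_rejected(self):
        cm = dense_matrix(np.vstack([np.ones((3, 30), dtype=int),
                                     np.zeros((40, 30), dtype=int)]))
        with pytest.raises(ValueError, match="expressed genes"):
            find_variable_genes(cm)

    def test_deterministic_with_lexicographic_ties(self):
        # duplicated rows have identical standardized variance; the tie
        # breaks on the gene name
        rng = np.random.default_rng(2)
        row = rng.poisson(3.0, size=60)
        noise = rng.poisson(3.0, size=(20, 60))
        cm = dense_matrix(np.vstack([row, row, noise]),
                          genes=["Zed", "Abc"] + [f"G{i}" for i in range(20)])
        out1 = find_variable_genes(cm, n_top=22)
        out2 = find_variable_genes(cm, n_top=22)
        assert out1 == out2
        assert out1.index("Abc") < out1.index("Zed")

    def test_isg_genes_variable_across_pooled_conditions(self, small_datasets):
        import scipy.sparse as sp

        from ifndirect import CountMatrix

        a = small_datasets["control"].counts
        b = small_datasets["dsDNA"].counts
        pooled = CountMatrix(sp.hstack([a.counts, b.counts], format="csr"),
                             a.gene_names, a.barcodes + b.barcodes)
        ranked = find_variable_genes(pooled, n_top=len(pooled.gene_names))
        # condition-variable ISGs outrank the flat pan-macrophage marker
        flat_rank = ranked.index("Ms4a7")
        for isg in ("Isg15", "Irf7", "Ifit1", "Rsad2", "Oasl2"):
            assert ranked.index(isg) < flat_rank

    def test_loess_trend_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 4, 80))
        y = np.sin(x) + rng.normal(0, 0.05, 80)
        fitted = _loess_trend(x, y, span=0.4)
        # independent brute force: tricube-weighted quadratic at each point
        k = max(4, int(np.ceil(0.4 * len(x))))
        for i in (0, 17, 40, 79):
            d = np.abs(x - x[i])
            cutoff = np.sort(d)[k - 1]
            w = np.where(d <= cutoff,
                         (1 - np.minimum(d / max(cutoff, 1e-12), 1) ** 3) ** 3,
                         0.0)
            coef = np.polyfit(x - x[i], y, 2, w=np.sqrt(w))
            assert fitted[i] == pytest.approx(coef[-1], abs=1e-8)


class TestScale:
    def test_constant_gene_scales_to_zeros(self):
        # equal cell totals keep the first gene constant post-normalization
        cm = dense_matrix(np.array([[4, 4, 4], [2, 6, 1], [4, 0, 5]]))
        nm = normalize(cm).log1p()
        sm = scale_genes(nm)
        assert np.all(sm.values[0] == 0.0)
        assert sm.values[1].std() > 0

    def test_zscore_moments(self):
        rng = np.random.default_rng(4)
        cm = dense_matrix(rng.poisson(5.0, size=(10, 200)))
        sm = scale_genes(normalize(cm).log1p(), clip=100.0)
        np.testing.assert_allclose(sm.values.mean(axis=1), 0.0, atol=1e-9)
        sds = sm.values.std(axis=1, ddof=1)
        np.testing.assert_allclose(sds[sds > 0], 1.0, rtol=1e-6)

    def test_outlier_clipped_exactly(self):
        col = np.r_[np.ones(60, dtype=int), 4000]
        cm = dense_matrix(np.vstack([col, np.ones(61, dtype=int)]))
        sm = scale_genes(normalize(cm).log1p(), clip=2.5)
        assert sm.values.max() == pytest.approx(2.5)
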