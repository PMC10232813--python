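"""CCA embeddings, MNN anchors and anchor-weighted correction."""

import numpy as np
import pytest

from ifndirect import (ScaledMatrix, find_anchors, integrate, integrate_many,
                       run_cca)
from ifndirect.preprocess import NormalizedMatrix, scale_genes
import scipy.sparse as sp


def _scaled(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return ScaledMatrix(values, [f"{prefix}{i}" for i in range(len(values))],
                        [f"c{i}" for i in range(values.shape[1])])


def _two_subset_pair(n=120, n_genes=60, shift=0.0, seed=0):
    """Two datasets sharing a two-subset structure (planted ground truth)."""
    rng = np.random.default_rng(seed)
    truth = []
    mats = []
    for _ in range(2):
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n_genes, n))
        X[:15, labels == 1] += 4.0   # subset program
        X += shift
        mats.append(X)
        truth.append(labels)
    return mats, truth


class TestCCA:
    def test_identical_datasets_give_unit_correlations(self):
        rng = np.random.default_rng(0)
        X = _scaled(rng.normal(size=(40, 60)))
        emb = run_cca(X, X, k=5)
        np.testing.assert_allclose(emb.correlations, 1.0, atol=1e-6)

    def test_rows_l2_normalized_and_corr_sorted(self):
        (A, B), _ = _two_subset_pair()
        emb = run_cca(_scaled(A), _scaled(B), k=8)
        np.testing.assert_allclose(np.linalg.norm(emb.cc_ref, axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(emb.cc_query, axis=1), 1.0,
                                   atol=1e-9)
        assert np.all(np.diff(emb.correlations) <= 1e-12)
        assert np.all(np.abs(emb.correlations) <= 1.0)

    def test_shared_structure_beats_independent_noise(self):
        (A, B), _ = _two_subset_pair(n=200, n_genes=100)
        rng = np.random.default_rng(1)
        emb_shared = run_cca(_scaled(A), _scaled(B), k=3)
        emb_noise = run_cca(_scaled(rng.normal(size=(100, 200))),
                            _scaled(rng.normal(size=(100, 200))), k=3)
        assert emb_shared.correlations[0] > emb_noise.correlations.max()

    def test_simultaneous_sign_flip_leaves_anchors_unchanged(self):
        from ifndirect.integrate import CCAEmbedding

        (A, B), _ = _two_subset_pair()
        emb = run_cca(_scaled(A), _scaled(B), k=6)
        anchors = find_anchors(emb, k_anchor=3)
        flipped = CCAEmbedding(-emb.cc_ref, -emb.cc_query, emb.correlations)
        anchors2 = find_anchors(flipped, k_anchor=3)
        assert anchors.ref_cells.tolist() == anchors2.ref_cells.tolist()
        assert anchors.query_cells.tolist() == anchors2.query_cells.tolist()

    def test_gene_mismatch_and_bad_k_rejected(self):
        rng = np.random.default_rng(2)
        A = _scaled(rng.normal(size=(20, 30)))
        B = _scaled(rng.normal(size=(20, 30)), prefix="H")
        with pytest.raises(ValueError, match="gene sets"):
            run_cca(A, B, k=5)
        with pytest.raises(ValueError, match="cell count"):
            run_cca(A, A, k=30)


class TestAnchors:
    def test_self_pairing_with_unit_scores(self):
        rng = np.random.default_rng(3)
        X = _scaled(rng.normal(size=(30, 50)))
        emb = run_cca(X, X, k=6)
        anchors = find_anchors(emb, k_anchor=1)
        paired = dict(zip(anchors.ref_cells.tolist(),
                          anchors.query_cells.tolist()))
        assert all(paired[i] == i for i in range(50))
        np.testing.assert_allclose(anchors.scores, 1.0)

    def test_k_anchor_zero_rejected(self):
        rng = np.random.default_rng(4)
        X = _scaled(rng.normal(size=(20, 30)))
        emb = run_cca(X, X, k=4)
        with pytest.raises(ValueError, match="k_anchor"):
            find_anchors(emb, k_anchor=0)

    def test_anchor_relation_symmetric_by_construction(self):
        (A, B), _ = _two_subset_pair(seed=5)
        emb = run_cca(_scaled(A), _scaled(B), k=8)
        anchors = find_anchors(emb, k_anchor=5)
        assert len(anchors) > 0
        assert np.all((anchors.scores >= 0) & (anchors.scores <= 1))

    def test_planted_subset_purity(self):
        # keep k near the planted rank so noise components do not drown the
        # subset axis when anchoring
        (A, B), (ta, tb) = _two_subset_pair(n=160, n_genes=80, seed=6)
        emb = run_cca(_scaled(A), _scaled(B), k=3)
        anchors = find_anchors(emb, k_anchor=5)
        same = np.mean(ta[anchors.ref_cells] == tb[anchors.query_cells])
        assert same >= 0.95


class TestCorrection:
    def test_identity_correction_is_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 40))
        emb = run_cca(_scaled(X), _scaled(X), k=5)
        anchors = find_anchors(emb, k_anchor=1)
        out = integrate(X, anchors, X, k_weight=10, embedding=emb)
        corrected = out[:, 40:]
        assert np.abs(corrected - X).max() < 1e-6

    def test_single_anchor_correction_equals_difference(self):
        from ifndirect.integrate import AnchorSet

        ref = np.array([[1.0], [2.0], [3.0]])
        query = np.array([[2.0], [1.0], [0.0]])
        anchors = AnchorSet(np.array([0]), np.array([0]), np.array([0.7]))
        with pytest.warns(UserWarning, match="k_weight"):
            out = integrate(query, anchors, ref, k_weight=100)
        np.testing.assert_allclose(out[:, 1], ref[:, 0])

    def test_planted_global_shift_recovered(self):
        (A, B), _ = _two_subset_pair(n=150, n_genes=70, seed=8)
        delta = 1.5
        B_shifted = B + delta
        emb = run_cca(_scaled(A), _scaled(B_shifted), k=10)
        anchors = find_anchors(emb, k_anchor=5)
        out = integrate(B_shifted, anchors, A, k_weight=30, embedding=emb)
        correction = out[:, 150:] - B_shifted
        assert np.mean(correction) == pytest.approx(-delta, rel=0.10)

    def test_no_condition_effect_means_small_correction(self, small_config):
        """Two halves of one condition integrate with near-zero correction."""
        from ifndirect import (QCThresholds, filter_cells,
                               find_variable_genes, generate_datasets,
                               normalize)

        ds = generate_datasets(small_config, ["control"])["control"]
        cm, rep = filter_cells(ds.counts, QCThresholds())
        half = cm.n_cells // 2
        a = cm.subset_cells(np.arange(half))
        b = cm.subset_cells(np.arange(half, cm.n_cells))
        feats = find_variable_genes(a, n_top=400)
        nm_a = normalize(a).log1p()
        nm_b = normalize(b).log1p()
        corrected, order, _ = integrate_many([nm_a, nm_b], feats, k_cca=20)
        idx = {g: i for i, g in enumerate(nm_b.gene_names)}
        rows = [idx[g] for g in feats]
        query_nm = [nm_a, nm_b][order[1]]
        query = np.asarray(query_nm.values[rows, :].todense())
        n_ref = [nm_a, nm_b][order[0]].values.shape[1]
        correction = corrected[:, n_ref:] - query
        scale = np.abs(query).mean()
        # the systematic per-gene shift vanishes; per-cell corrections are
        # anchor-sampling noise that averages out
        systematic = np.abs(correction.mean(axis=1)).mean()
        assert systematic < 0.05 * scale


class TestIntegrateMany:
    def _as_nm(self, X, prefix="G"):
        X = np.asarray(X, dtype=float)
        return NormalizedMatrix(sp.csr_matrix(X),
                                [f"{prefix}{i}" for i in range(len(X))],
                                [f"c{i}" for i in range(X.shape[1])],
                                is_log=True)

    def test_two_datasets_match_single_call(self):
        (A, B), _ = _two_subset_pair(n=100, n_genes=50, seed=10)
        nm_a, nm_b = self._as_nm(A), self._as_nm(np.c_[B, B[:, :5]])
        feats = [f"G{i}" for i in range(50)]
        corrected, order, anchor_sets = integrate_many(
            [nm_a, nm_b], feats, k_cca=8, k_weight=20)
        assert order[0] == 1  # larger dataset is the reference
        assert corrected.shape == (50, 100 + 105)
        assert len(anchor_sets) == 1

    def test_fewer_than_two_rejected(self):
        (A, _B), _ = _two_subset_pair()
        with pytest.raises(ValueError, match="at least 2"):
            integrate_many([self._as_nm(A)], ["G0"])

    def test_permutation_of_queries_same_values(self):
        (A, B), _ = _two_subset_pair(n=90, n_genes=50, seed=11)
        C = B[:, :80] + 0.5
        big = np.c_[A, A[:, :10]]
        nm = [self._as_nm(big), self._as_nm(B), self._as_nm(C)]
        feats = [f"G{i}" for i in range(50)]
        out1, order1, _ = integrate_many([nm[0], nm[1], nm[2]], feats,
                                         k_cca=8, k_weight=20)
        out2, order2, _ = integrate_many([nm[0], nm[2], nm[1]], feats,
                                         k_cca=8, k_weight=20)
        # reference block identical; query blocks land in listed order
        n_ref, n_b, n_c = 100, 90, 80
        np.testing.assert_allclose(out1[:, :n_ref], out2[:, :n_ref])
        np.testing.assert_allclose(out1[:, n_ref:n_ref + n_b],
                                   out2[:, n_ref + n_c:])
        np.testing.assert_allclose(out1[:, n_ref + n_b:],
                                   out2[:, n_ref:n_ref + n_c])
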