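import math

import numpy as np
import pytest
import scipy.sparse as sp

import semnetkit as sk
from semnetkit.dsm import WordContextMatrix, unit_rows


def make_matrix(rows, row_labels=None, col_labels=None, **kw):
    arr = np.asarray(rows, dtype=float)
    return WordContextMatrix(
        sp.csr_matrix(arr),
        row_labels or [f"w{i}" for i in range(arr.shape[0])],
        col_labels or [f"c{j}" for j in range(arr.shape[1])],
        kw.pop("context_type", "document"), **kw)


class TestBuildMatrix:
    def test_document_mode(self, tiny_corpus):
        mat = sk.build_matrix(tiny_corpus, ["a", "b"], context_type="document")
        assert mat.row("a").tolist() == [2, 0]
        assert mat.row("b").tolist() == [1, 1]

    def test_word_mode_window2(self):
        corpus = sk.Corpus([["a", "b", "c"]])
        mat = sk.build_matrix(corpus, ["a"], context_type="word", window=2)
        row = dict(zip(mat.col_labels, mat.row("a")))
        assert row == {"a": 0, "b": 1, "c": 1}

    def test_word_mode_self_cooccurrence(self):
        # two tokens of the same type within the window count once per direction
        corpus = sk.Corpus([["a", "a"]])
        mat = sk.build_matrix(corpus, ["a"], context_type="word", window=2)
        assert mat.row("a")[mat.col_labels.index("a")] == 2

    def test_word_mode_symmetric_on_full_vocab(self, synth_corpus):
        vocab = sorted(synth_corpus.vocabulary)
        mat = sk.build_matrix(synth_corpus, vocab, context_type="word", window=2)
        dense = mat.matrix.toarray()
        np.testing.assert_array_equal(dense, dense.T)

    def test_windows_do_not_cross_documents(self):
        corpus = sk.Corpus([["a", "b"], ["c", "d"]])
        mat = sk.build_matrix(corpus, ["b"], context_type="word", window=2)
        assert mat.row("b")[mat.col_labels.index("c")] == 0

    def test_absent_target_keeps_zero_row(self, tiny_corpus):
        mat = sk.build_matrix(tiny_corpus, ["a", "zzz"], context_type="document")
        assert mat.row("zzz").sum() == 0

    def test_empty_targets_error(self, tiny_corpus):
        with pytest.raises(ValueError):
            sk.build_matrix(tiny_corpus, [])

    def test_mtx_round_trip(self, tmp_path, tiny_corpus):
        mat = sk.build_matrix(tiny_corpus, ["a", "b"])
        mat.write(str(tmp_path / "m"))
        back = WordContextMatrix.read(str(tmp_path / "m"))
        np.testing.assert_array_equal(mat.matrix.toarray(), back.matrix.toarray())
        assert back.row_labels == mat.row_labels


class TestWeighting:
    def test_tfidf_uniform_row_becomes_zero(self):
        # word occurring uniformly in all contexts: entropy factor 1 + (-1) = 0
        mat = make_matrix([[2, 2, 2, 2]])
        out = sk.weight(mat, "tfidf")
        assert np.allclose(out.matrix.toarray(), 0)

    def test_tfidf_single_context_row(self):
        # f=3 in exactly one of several contexts: a = log(4) * 1
        mat = make_matrix([[3, 0], [1, 1]])
        out = sk.weight(mat, "tfidf")
        assert out.matrix[0, 0] == pytest.approx(math.log(4), abs=1e-12)
        assert out.matrix[0, 1] == 0

    def test_ppmi_hand_computed_2x2(self):
        mat = make_matrix([[2, 0], [1, 1]])
        out = sk.weight(mat, "ppmi")
        expected = np.array([[math.log(4 / 3), 0.0], [0.0, math.log(2)]])
        np.testing.assert_allclose(out.matrix.toarray(), expected, atol=1e-9)

    def test_outputs_nonnegative_and_sparsity_not_reduced(self, synth_corpus):
        vocab = sorted(synth_corpus.vocabulary)
        mat = sk.build_matrix(synth_corpus, vocab, context_type="word", window=2)
        for scheme in ("tfidf", "ppmi"):
            out = sk.weight(mat, scheme)
            assert out.matrix.nnz == 0 or out.matrix.data.min() >= 0
        assert sk.weight(mat, "ppmi").sparsity() >= mat.sparsity()

    def test_double_weighting_errors(self):
        mat = make_matrix([[2, 0], [1, 1]])
        out = sk.weight(mat, "ppmi")
        with pytest.raises(ValueError, match="already weighted"):
            sk.weight(out, "tfidf")

    def test_zero_total_errors(self):
        mat = make_matrix([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="zero total"):
            sk.weight(mat, "ppmi")

    def test_zero_rows_stay_zero(self):
        mat = make_matrix([[0, 0, 0], [1, 2, 3]])
        for scheme in ("tfidf", "ppmi"):
            out = sk.weight(mat, scheme)
            assert out.matrix.toarray()[0].sum() == 0


class TestSvdSmoothing:
    def test_rank1_preserves_cosines_exactly(self):
        mat = make_matrix([[1, 2, 3], [2, 4, 6], [3, 6, 9]])
        space = sk.smooth_svd(mat, 1)
        assert sk.cosine(space, "w0", "w1") == pytest.approx(1.0)
        assert sk.cosine(space, "w0", "w2") == pytest.approx(1.0)

    def test_full_rank_reproduces_raw_cosines(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(2.0, size=(6, 9)).astype(float)
        mat = make_matrix(arr)
        space = sk.smooth_svd(mat, 6)
        for i in range(6):
            for j in range(i + 1, 6):
                raw = float(arr[i] @ arr[j] /
                            (np.linalg.norm(arr[i]) * np.linalg.norm(arr[j])))
                assert sk.cosine(space, f"w{i}", f"w{j}") == pytest.approx(raw, abs=1e-8)

    def test_against_dense_svd_oracle(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(1.5, size=(20, 30)).astype(float)
        mat = make_matrix(arr)
        space = sk.smooth_svd(mat, 5)
        u, s, vt = np.linalg.svd(arr)            # dense oracle
        recon = u[:, :5] @ np.diag(s[:5]) @ vt[:5]
        for i in range(0, 20, 3):
            for j in range(i + 1, 20, 4):
                ni, nj = np.linalg.norm(recon[i]), np.linalg.norm(recon[j])
                if ni == 0 or nj == 0:
                    continue
                oracle = float(recon[i] @ recon[j] / (ni * nj))
                assert sk.cosine(space, f"w{i}", f"w{j}") == pytest.approx(oracle, abs=1e-6)

    def test_rank_deficient_reduces_with_warning(self):
        mat = make_matrix([[1, 2, 4], [2, 4, 8], [3, 6, 12]])  # rank 1
        space = sk.smooth_svd(mat, 3)
        assert space.n_r == 1

    def test_frobenius_energy_nondecreasing_in_rank(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(2.0, size=(8, 12)).astype(float)
        mat = make_matrix(arr)
        energies = [np.sum(sk.smooth_svd(mat, r).vectors ** 2) for r in (1, 3, 5, 8)]
        assert all(a <= b + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_nr_too_large_errors(self):
        mat = make_matrix([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            sk.smooth_svd(mat, 5)


class TestCosine:
    def test_identity(self):
        space = sk.SemanticSpace(["a", "b"], np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert sk.cosine(space, "a", "b") == pytest.approx(1.0)

    def test_orthogonal(self):
        space = sk.SemanticSpace(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert sk.cosine(space, "a", "b") == pytest.approx(0.0)

    def test_hand_value(self):
        space = sk.SemanticSpace(["a", "b"],
                                 np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]]))
        assert sk.cosine(space, "a", "b") == pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_convention(self):
        space = sk.SemanticSpace(["a", "z"], np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert sk.cosine(space, "a", "z") == 0.0

    def test_unknown_word_errors(self, small_space):
        with pytest.raises(KeyError):
            sk.cosine(small_space, "w00", "nope")

    def test_unit_rows_zero_row_stays_zero(self):
        mat = make_matrix([[0, 0], [1, 1]])
        _, units = unit_rows(mat)
        assert np.all(units[0] == 0)
        assert np.linalg.norm(units[1]) == pytest.approx(1.0)
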