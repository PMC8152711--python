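from collections import Counter

import numpy as np
import pytest

from screensift.preprocess import TokenStreams
from screensift.representations import (
    RepresentationError, WordVectors, build_dfm, embed_docs, fit_topics,
    load_word_vectors, select_common_features, svd_reduce,
)


def make_streams(word_lists):
    out = {}
    for i, words in enumerate(word_lists):
        c = Counter(words)
        out[f"d{i}"] = TokenStreams(ngrams=c, nouns_verbs=c, words=c)
    return out


TOY = make_streams([
    ["apple", "apple", "banana"],
    ["banana", "cherry"],
    ["apple", "cherry", "cherry", "cherry"],
])


class TestBuildDfm:
    def test_counts_match_brute_force_oracle(self):
        dfm = build_dfm(TOY, "words")
        # independent counting pass over the raw word lists
        expected = {
            ("d0", "apple"): 2, ("d0", "banana"): 1, ("d1", "banana"): 1,
            ("d1", "cherry"): 1, ("d2", "apple"): 1, ("d2", "cherry"): 3,
        }
        dense = dfm.counts.toarray()
        for i, d in enumerate(dfm.doc_ids):
            for j, f in enumerate(dfm.features):
                assert dense[i, j] == expected.get((d, f), 0)
        assert dfm.features == sorted(dfm.features)

    def test_identical_docs_identical_rows(self):
        streams = make_streams([["x", "y"], ["x", "y"]])
        dfm = build_dfm(streams, "words")
        assert np.array_equal(dfm.counts.toarray()[0], dfm.counts.toarray()[1])

    def test_empty_doc_keeps_zero_row(self):
        streams = make_streams([["x"], []])
        dfm = build_dfm(streams, "words")
        assert dfm.zero_doc_ids() == ["d1"]

    def test_all_empty_raises(self):
        with pytest.raises(RepresentationError):
            build_dfm(make_streams([[], []]), "words")


class TestSelectCommonFeatures:
    def test_cumulative_mass_arithmetic(self):
        streams = make_streams([["a"] * 6 + ["b"] * 3 + ["c"]])
        dfm = build_dfm(streams, "words")
        kept = select_common_features(dfm, 0.7)
        assert kept.features == ["a", "b"]  # 6/10 < 0.7 <= 9/10

    def test_phi_one_keeps_everything(self):
        dfm = build_dfm(TOY, "words")
        assert select_common_features(dfm, 1.0).features == dfm.features

    def test_single_feature_survives_any_phi(self):
        dfm = build_dfm(make_streams([["only", "only"]]), "words")
        assert select_common_features(dfm, 0.01).features == ["only"]

    @pytest.mark.parametrize("phi", [0.0, -0.2, 1.5])
    def test_phi_out_of_range(self, phi):
        dfm = build_dfm(TOY, "words")
        with pytest.raises(RepresentationError):
            select_common_features(dfm, phi)

    def test_retained_mass_meets_phi(self):
        dfm = build_dfm(TOY, "words")
        for phi in (0.3, 0.5, 0.8, 0.95):
            kept = select_common_features(dfm, phi)
            assert kept.total_mass() >= phi * dfm.total_mass() - 1e-9
            assert kept.total_mass() <= dfm.total_mass()


class TestSvdReduce:
    def test_rank_one_reconstruction(self):
        streams = make_streams([["u", "v"], ["u", "u", "v", "v"]])  # rank-1 counts
        dfm = build_dfm(streams, "words")
        with pytest.warns(UserWarning):
            vecs = svd_reduce(dfm, 2)  # rank 1 < requested 2
        assert vecs.dims == 1
        # U*s reproduces row norms of the rank-1 matrix exactly
        X = dfm.counts.toarray().astype(float)
        assert np.allclose(np.abs(vecs.matrix[:, 0]), np.linalg.norm(X, axis=1), atol=1e-8)

    def test_full_rank_preserves_inner_products(self):
        rng = np.random.default_rng(3)
        streams = make_streams([
            [f"w{j}" for j in rng.integers(0, 8, size=12)] for _ in range(6)
        ])
        dfm = build_dfm(streams, "words")
        X = dfm.counts.toarray().astype(float)
        d = np.linalg.matrix_rank(X)
        vecs = svd_reduce(dfm, d)
        # oracle: dense full decomposition inner products == raw inner products
        assert np.allclose(vecs.matrix @ vecs.matrix.T, X @ X.T, atol=1e-6)

    def test_cosine_invariance_at_full_rank(self):
        from screensift.similarity import cosine_distance_matrix

        rng = np.random.default_rng(4)
        streams = make_streams([
            [f"w{j}" for j in rng.integers(0, 6, size=10)] for _ in range(5)
        ])
        dfm = build_dfm(streams, "words")
        X = dfm.counts.toarray().astype(float)
        vecs = svd_reduce(dfm, int(np.linalg.matrix_rank(X)))
        assert np.allclose(
            cosine_distance_matrix(vecs.matrix), cosine_distance_matrix(X), atol=1e-6
        )


class TestFitTopics:
    def test_single_topic_degenerate(self):
        dfm = build_dfm(TOY, "nouns_verbs")
        vecs = fit_topics(dfm, 1, seed=0)
        assert np.allclose(vecs.matrix, 1.0)

    def test_rows_on_simplex(self, tiny_synth):
        from screensift.corpus_io import screening_text
        from screensift.preprocess import extract_streams, preprocess

        docs = list(tiny_synth.corpus)[:60]
        streams = {
            c.id: extract_streams(preprocess(screening_text(c), pos_lexicon=tiny_synth.pos_lexicon))
            for c in docs
        }
        dfm = build_dfm(streams, "nouns_verbs")
        vecs = fit_topics(dfm, 5, seed=1, max_iter=20)
        assert np.all(vecs.matrix >= 0)
        assert np.allclose(vecs.matrix.sum(axis=1), 1.0, atol=1e-8)

    def test_topic_count_exceeding_vocabulary(self):
        dfm = build_dfm(TOY, "nouns_verbs")
        with pytest.raises(RepresentationError):
            fit_topics(dfm, 100, seed=0)

    def test_disjoint_topic_recovery(self):
        """Groups generated from disjoint vocabularies cluster in topic space."""
        rng = np.random.default_rng(9)
        groups = [[f"g{g}w{j}" for j in range(10)] for g in range(3)]
        word_lists, membership = [], []
        for g in range(3):
            for _ in range(12):
                word_lists.append(list(rng.choice(groups[g], size=30)))
                membership.append(g)
        dfm = build_dfm(make_streams(word_lists), "nouns_verbs")
        vecs = fit_topics(dfm, 3, seed=5, max_iter=50)
        M = vecs.matrix / np.linalg.norm(vecs.matrix, axis=1, keepdims=True)
        sims = M @ M.T
        same = np.array([[a == b for b in membership] for a in membership])
        off_diag = ~np.eye(len(membership), dtype=bool)
        assert sims[same & off_diag].mean() > sims[~same].mean()


class TestEmbedDocs:
    def test_weighted_average_hand_arithmetic(self):
        wv = WordVectors({"w": np.array([2.0, 0.0]), "u": np.array([0.0, 4.0])})
        streams = make_streams([["w"], ["w", "u"], ["w", "w", "w", "u"]])
        vecs = embed_docs(build_dfm(streams, "words"), wv)
        assert np.allclose(vecs.row("d0"), [2.0, 0.0])          # single word
        assert np.allclose(vecs.row("d1"), [1.0, 2.0])          # equal weights
        assert np.allclose(vecs.row("d2"), [1.5, 1.0])          # (3*v_w + v_u)/4

    def test_count_scaling_invariance(self):
        wv = WordVectors({"w": np.array([1.0, 2.0]), "u": np.array([3.0, -1.0])})
        single = make_streams([["w", "w", "u"]])
        double = make_streams([["w"] * 4 + ["u"] * 2])
        v1 = embed_docs(build_dfm(single, "words"), wv)
        v2 = embed_docs(build_dfm(double, "words"), wv)
        assert np.allclose(v1.matrix, v2.matrix)

    def test_out_of_vocabulary_doc_flagged(self):
        wv = WordVectors({"w": np.array([1.0, 0.0])})
        vecs = embed_docs(build_dfm(make_streams([["w"], ["zz"]]), "words"), wv)
        assert vecs.flagged == {"d1"}


class TestWordVectorIO:
    def test_parse_small_file(self, tmp_path):
        p = tmp_path / "vec.txt"
        p.write_text("alpha 1 2 3\nbeta 0.5 -1 2e-1\n")
        wv = load_word_vectors(p)
        assert len(wv) == 2 and wv.dims == 3
        assert np.allclose(wv["beta"], [0.5, -1.0, 0.2])

    def test_ragged_dimensions_error_names_line(self, tmp_path):
        p = tmp_path / "vec.txt"
        p.write_text("alpha 1 2 3\nbeta 1 2 3 4\n")
        with pytest.raises(RepresentationError, match="2"):
            load_word_vectors(p)

    def test_round_trip(self, tmp_path, toy_wv):
        p = tmp_path / "out.txt"
        toy_wv.save(p)
        back = load_word_vectors(p)
        assert set(back.vocabulary) == set(toy_wv.vocabulary)
        for w in toy_wv.vocabulary:
            assert np.allclose(back[w], toy_wv[w], atol=1e-9)

    def test_duplicate_word_last_wins(self, tmp_path):
        p = tmp_path / "vec.txt"
        p.write_text("x 1 1\nx 2 2\n")
        with pytest.warns(UserWarning, match="duplicate"):
            wv = load_word_vectors(p)
        assert np.allclose(wv["x"], [2.0, 2.0])
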