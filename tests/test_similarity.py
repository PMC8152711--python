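import itertools
import math
from collections import Counter

import numpy as np
import pytest

from screensift.representations import DocVectors, WordVectors
from screensift.similarity import (
    DistanceError, VectorCosineProvider, WMDProvider, cosine_distance,
    cosine_distance_matrix, expansion_upper_bound, knn_expand,
    relaxed_wmd, wmd_distance,
)


class TestCosine:
    def test_identity_and_orthogonality(self):
        u = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(u, u) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1, 0], [-1, 0]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DistanceError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    def test_matrix_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((10, 5))
        D = cosine_distance_matrix(M)
        for i in range(10):
            for j in range(10):
                ui, uj = M[i], M[j]
                expected = 1.0 - ui @ uj / (np.linalg.norm(ui) * np.linalg.norm(uj))
                assert abs(D[i, j] - expected) < 1e-10


def permutation_wmd_oracle(words_a, words_b, wv):
    """Independent oracle: for equal-size unit-mass docs the transport optimum
    is attained at a permutation (Birkhoff), so enumerate all of them."""
    n = len(words_a)
    Va = [wv[w] / np.linalg.norm(wv[w]) for w in words_a]
    Vb = [wv[w] / np.linalg.norm(wv[w]) for w in words_b]
    best = math.inf
    for perm in itertools.permutations(range(n)):
        cost = sum(1.0 - Va[i] @ Vb[perm[i]] for i in range(n)) / n
        best = min(best, cost)
    return best


class TestWmd:
    def test_identical_multisets_zero(self, toy_wv):
        doc = Counter({"t0": 2, "t1": 1})
        assert wmd_distance(doc, doc, toy_wv) == 0.0

    def test_single_word_docs_equal_ground_cost(self, toy_wv):
        d = wmd_distance(Counter({"t0": 3}), Counter({"t1": 5}), toy_wv)
        assert d == pytest.approx(cosine_distance(toy_wv["t0"], toy_wv["t1"]), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_permutation_oracle(self, toy_wv, seed):
        rng = np.random.default_rng(seed)
        words = [f"t{i}" for i in range(8)]
        wa = list(rng.choice(words, size=4, replace=False))
        wb = list(rng.choice(words, size=4, replace=False))
        got = wmd_distance(Counter(wa), Counter(wb), toy_wv)
        assert got == pytest.approx(permutation_wmd_oracle(wa, wb, toy_wv), abs=1e-8)

    def test_symmetry(self, toy_wv):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = Counter({f"t{i}": int(c) for i, c in
                         zip(rng.choice(10, 3, replace=False), rng.integers(1, 5, 3))})
            b = Counter({f"t{i}": int(c) for i, c in
                         zip(rng.choice(10, 3, replace=False), rng.integers(1, 5, 3))})
            assert abs(wmd_distance(a, b, toy_wv) - wmd_distance(b, a, toy_wv)) < 1e-10

    def test_relaxed_is_lower_bound(self, toy_wv):
        rng = np.random.default_rng(17)
        for _ in range(8):
            a = Counter(rng.choice([f"t{i}" for i in range(10)], size=5).tolist())
            b = Counter(rng.choice([f"t{i}" for i in range(10)], size=5).tolist())
            assert relaxed_wmd(a, b, toy_wv) <= wmd_distance(a, b, toy_wv) + 1e-9

    def test_empty_in_vocabulary_doc_rejected(self, toy_wv):
        with pytest.raises(DistanceError):
            wmd_distance(Counter({"zzz": 1}), Counter({"t0": 1}), toy_wv)


@pytest.fixture(scope="module")
def cosine_provider_200():
    rng = np.random.default_rng(23)
    M = rng.standard_normal((200, 8))
    ids = [f"c{i:03d}" for i in range(200)]
    return VectorCosineProvider(DocVectors(doc_ids=ids, kind="svd", matrix=M)), ids, M


class TestProviders:
    def test_knn_matches_full_argsort(self, cosine_provider_200):
        provider, ids, M = cosine_provider_200
        D = cosine_distance_matrix(M)
        for qi in (0, 57, 199):
            got = provider.query(ids[qi], 10)
            # oracle: full argsort over explicit distances, same tie-break
            pairs = sorted((D[qi, j], ids[j]) for j in range(200) if j != qi)
            assert got == [(cid, d) for d, cid in pairs[:10]]

    def test_query_never_returns_self_and_ranks_monotone(self, cosine_provider_200):
        provider, ids, _ = cosine_provider_200
        res = provider.query(ids[5], 25)
        assert ids[5] not in [c for c, _ in res]
        dists = [d for _, d in res]
        assert dists == sorted(dists)

    def test_enlarging_k_extends_prefix(self, cosine_provider_200):
        provider, ids, _ = cosine_provider_200
        small = provider.query(ids[3], 5)
        large = provider.query(ids[3], 15)
        assert large[:5] == small

    def test_wmd_provider_exact_agrees_with_pairwise(self, toy_wv):
        rng = np.random.default_rng(31)
        bows = {
            f"d{i}": Counter(rng.choice([f"t{j}" for j in range(10)], size=6).tolist())
            for i in range(12)
        }
        provider = WMDProvider(bows, toy_wv, exact=True)
        res = provider.query("d0", 3)
        direct = sorted(
            (wmd_distance(bows["d0"], bows[d], toy_wv, cap=50), d)
            for d in bows if d != "d0"
        )
        assert [c for c, _ in res] == [d for _, d in direct[:3]]

    def test_relaxed_provider_row_matches_pairwise_relaxed(self, toy_wv):
        rng = np.random.default_rng(37)
        bows = {
            f"d{i}": Counter(rng.choice([f"t{j}" for j in range(10)], size=6).tolist())
            for i in range(10)
        }
        provider = WMDProvider(bows, toy_wv, exact=False)
        res = dict(provider.query("d1", 9))
        for other, dist in res.items():
            assert dist == pytest.approx(relaxed_wmd(bows["d1"], bows[other], toy_wv, cap=50), abs=1e-10)


class TestKnnExpand:
    def test_upper_bound_matches_seed_k_provider_product(self, cosine_provider_200):
        provider, ids, _ = cosine_provider_200
        assert expansion_upper_bound(3, 8, 3) == 72
        out = knn_expand(ids[:3], 8, [provider, provider, provider])
        assert len(out) <= 72

    def test_k1_single_provider_is_global_argmin(self, cosine_provider_200):
        provider, ids, M = cosine_provider_200
        D = cosine_distance_matrix(M)
        out = knn_expand([ids[0]], 1, [provider])
        expected = min((D[0, j], ids[j]) for j in range(1, 200))[1]
        assert out == {expected}

    def test_all_neighbours_screened_gives_empty(self, cosine_provider_200):
        provider, ids, _ = cosine_provider_200
        out = knn_expand([ids[0]], 5, [provider], already_screened=set(ids))
        assert out == set()

    def test_monotone_in_screened_set(self, cosine_provider_200):
        provider, ids, _ = cosine_provider_200
        base = knn_expand(ids[:2], 6, [provider])
        shrunk = knn_expand(ids[:2], 6, [provider], already_screened=set(list(base)[:3]))
        assert shrunk <= base
        assert len(shrunk) <= len(base)
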