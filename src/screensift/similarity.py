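"""Pairwise document distances and k-nearest-neighbour seed expansion.

Three distance providers mirror the three representations: cosine distance
on latent-semantic vectors, cosine distance on topic proportions, and the
word-mover distance (WMD) on word embeddings. Candidate batches for human
screening are grown by taking, for every eligible seed under every provider,
the k nearest unscreened neighbours and uniting them (so a batch from s
seeds, k neighbours and p providers holds at most s*k*p documents before
de-duplication).

WMD here is the exact transportation linear program with cosine ground
cost; a cheap relaxed lower bound (the larger of the two one-sided
relaxations) is available for corpus-scale nearest-neighbour queries.
"""

from __future__ import annotations

import logging

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from sklearn.metrics.pairwise import cosine_distances

from .representations import DocVectors, WordVectors

logger = logging.getLogger(__name__)


class DistanceError(ValueError):
    pass


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); raises on zero vectors (callers must exclude flagged docs)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DistanceError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def cosine_distance_matrix(M: np.ndarray) -> np.ndarray:
    """Full pairwise 1 - cosine similarity matrix (rows of M are documents)."""
    return cosine_distances(np.asarray(M, dtype=float))


def _normalized_bow(doc: Mapping[str, float] | Counter, wv: WordVectors, cap: Optional[int]):
    items = [(w, c) for w, c in doc.items() if w in wv and c > 0]
    if not items:
        raise DistanceError("document has no in-vocabulary words; WMD undefined")
    if cap is not None and len(items) > cap:
        items = sorted(items, key=lambda t: (-t[1], t[0]))[:cap]
    words = [w for w, _ in items]
    mass = np.array([c for _, c in items], dtype=float)
    return words, mass / mass.sum()


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def wmd_distance(
    doc_a: Mapping[str, float] | Counter,
    doc_b: Mapping[str, float] | Counter,
    wv: WordVectors,
    cap: Optional[int] = None,
) -> float:
    """Exact word-mover distance between two word multisets.

    Word-frequency masses are normalized to 1 per document and transported
    at a ground cost equal to the cosine distance between word vectors; the
    minimum total transport cost is found by linear programming. ``cap``
    optionally restricts each document to its ``cap`` most frequent
    in-vocabulary words (ties by word) before solving, for scalability.
    """
    words_a, a = _normalized_bow(doc_a, wv, cap)
    words_b, b = _normalized_bow(doc_b, wv, cap)
    if Counter(dict(zip(words_a, a))) == Counter(dict(zip(words_b, b))):
        return 0.0
    Va = _unit_rows(np.vstack([wv[w] for w in words_a]))
    Vb = _unit_rows(np.vstack([wv[w] for w in words_b]))
    C = 1.0 - Va @ Vb.T  # (m, n) cosine ground costs
    m, n = C.shape
    # transportation LP: min <C, T>, row sums = a, col sums = b, T >= 0
    A_eq_rows = np.zeros((m, m * n))
    for i in range(m):
        A_eq_rows[i, i * n : (i + 1) * n] = 1.0
    A_eq_cols = np.zeros((n, m * n))
    for j in range(n):
        A_eq_cols[j, j::n] = 1.0
    # one marginal constraint is redundant; dropping it improves conditioning
    A_eq = np.vstack([A_eq_rows, A_eq_cols[:-1]])
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on transport LPs
        raise DistanceError(f"WMD transport LP failed: {res.message}")
    return float(max(res.fun, 0.0))


def relaxed_wmd(
    doc_a: Mapping[str, float] | Counter,
    doc_b: Mapping[str, float] | Counter,
    wv: WordVectors,
    cap: Optional[int] = None,
) -> float:
    """Relaxed word-mover distance: a fast lower bound on :func:`wmd_distance`.

    Each one-sided relaxation lets every unit of mass travel to its single
    nearest word on the other side; the larger of the two bounds is returned.
    """
    words_a, a = _normalized_bow(doc_a, wv, cap)
    words_b, b = _normalized_bow(doc_b, wv, cap)
    Va = _unit_rows(np.vstack([wv[w] for w in words_a]))
    Vb = _unit_rows(np.vstack([wv[w] for w in words_b]))
    C = 1.0 - Va @ Vb.T
    return float(max(a @ C.min(axis=1), b @ C.min(axis=0)))


class DistanceProvider:
    """Interface: k nearest neighbours of a document under one representation."""

    kind: str

    def query(self, doc_id: str, k: int) -> list[tuple[str, float]]:
        """The k nearest other documents as (doc_id, distance), nearest first.

        Distances are non-decreasing in rank; ties break by ascending doc_id
        so runs are bit-reproducible. The query document itself and any
        flagged (degenerate) documents are never returned.
        """
        raise NotImplementedError

    def _rank(self, doc_id: str, dists: Mapping[str, float], k: int) -> list[tuple[str, float]]:
        pairs = [(d, cid) for cid, d in dists.items() if cid != doc_id]
        pairs.sort()
        return [(cid, d) for d, cid in pairs[:k]]


class VectorCosineProvider(DistanceProvider):
    """Cosine-distance provider over a dense DocVectors matrix (precomputed)."""

    def __init__(self, vectors: DocVectors):
        self.kind = f"{vectors.kind}_cosine"
        zero_rows = {d for d, row in zip(vectors.doc_ids, vectors.matrix) if not np.any(row)}
        self._excluded = set(vectors.flagged) | zero_rows
        self._ids = [d for d in vectors.doc_ids if d not in self._excluded]
        idx = [i for i, d in enumerate(vectors.doc_ids) if d not in self._excluded]
        self._D = cosine_distance_matrix(vectors.matrix[idx])
        self._pos = {d: i for i, d in enumerate(self._ids)}

    def query(self, doc_id: str, k: int) -> list[tuple[str, float]]:
        if doc_id in self._excluded:
            raise DistanceError(f"document {doc_id!r} has a degenerate {self.kind} vector")
        row = self._D[self._pos[doc_id]]
        return self._rank(doc_id, dict(zip(self._ids, row)), k)


class WMDProvider(DistanceProvider):
    """Word-mover-distance provider over per-document word multisets.

    ``exact=True`` solves the transportation LP for every pair (small corpora
    and tests); the default uses the relaxed lower bound, which is the
    corpus-scale mode and is labelled as such in ``kind``. Query rows are
    cached, since expansion repeatedly queries the same eligible seeds.
    """

    kind = "wmd"

    def __init__(
        self,
        bows: Mapping[str, Counter],
        wv: WordVectors,
        exact: bool = False,
        cap: Optional[int] = 50,
    ):
        self.exact = exact
        self.kind = "wmd" if exact else "wmd_relaxed"
        self._wv = wv
        self._cap = cap
        self._excluded = {d for d, bow in bows.items() if not any(w in wv for w in bow)}
        if self._excluded:
            logger.warning("WMDProvider: %d document(s) excluded (no in-vocabulary words)", len(self._excluded))
        self._prepped: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        vocab_index: dict[str, int] = {}
        rows: list[np.ndarray] = []
        for d, bow in bows.items():
            if d in self._excluded:
                continue
            words, mass = _normalized_bow(bow, wv, cap)
            idx = []
            for w in words:
                if w not in vocab_index:
                    vocab_index[w] = len(rows)
                    rows.append(wv[w])
                idx.append(vocab_index[w])
            self._prepped[d] = (np.array(idx, dtype=np.intp), mass)
        self._U = _unit_rows(np.vstack(rows)) if rows else np.zeros((0, wv.dims))
        self._bows = {d: Counter(b) for d, b in bows.items()}
        self._cache: dict[str, dict[str, float]] = {}

    def _row(self, doc_id: str) -> dict[str, float]:
        if doc_id in self._cache:
            return self._cache[doc_id]
        if self.exact:
            row = {
                other: wmd_distance(self._bows[doc_id], self._bows[other], self._wv, self._cap)
                for other in self._prepped
                if other != doc_id
            }
        else:
            idx_a, a = self._prepped[doc_id]
            Ca = 1.0 - self._U[idx_a] @ self._U.T  # (m, V) costs to every vocab word
            row = {}
            for other, (idx_b, b) in self._prepped.items():
                if other == doc_id:
                    continue
                sub = Ca[:, idx_b]
                row[other] = float(max(a @ sub.min(axis=1), b @ sub.min(axis=0)))
        self._cache[doc_id] = row
        return row

    def query(self, doc_id: str, k: int) -> list[tuple[str, float]]:
        if doc_id in self._excluded:
            raise DistanceError(f"document {doc_id!r} has no in-vocabulary words")
        return self._rank(doc_id, self._row(doc_id), k)


def expansion_upper_bound(n_seeds: int, k: int, n_providers: int) -> int:
    """Largest possible batch from one expansion round, before de-duplication."""
    return n_seeds * k * n_providers


def knn_expand(
    seeds: Iterable[str],
    k: int,
    providers: Sequence[DistanceProvider],
    already_screened: Iterable[str] = (),
) -> set[str]:
    """Union of each seed's k nearest neighbours under every provider,
    minus the seeds themselves and anything already screened."""
    seeds = list(seeds)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not seeds:
        raise ValueError("knn_expand requires at least one seed")
    screened = set(already_screened)
    out: set[str] = set()
    for provider in providers:
        for s in seeds:
            try:
                neighbours = provider.query(s, k)
            except DistanceError:
                continue  # seed degenerate under this representation
            out.update(cid for cid, _ in neighbours)
    return out - set(seeds) - screened
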