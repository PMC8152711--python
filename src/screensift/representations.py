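"""Document-feature matrices and the three dense document representations.

Each corpus is summarized three ways before any screening happens:

1. a latent-semantic representation: truncated SVD of the 1/2/3-gram
   count matrix after common-feature selection (document scores are the
   left singular vectors scaled by the singular values, so inner-product
   geometry of the count space is preserved);
2. a topic representation: per-document topic proportions from latent
   Dirichlet allocation fitted to the nouns+verbs counts;
3. an embedding representation: the frequency-weighted average of word
   vectors over the in-vocabulary words of the document.

Counts are raw frequencies throughout (no tf-idf).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .preprocess import TokenStreams

logger = logging.getLogger(__name__)

STREAM_NAMES = ("ngrams", "nouns_verbs", "words")


class RepresentationError(ValueError):
    pass


@dataclass
class DocFeatureMatrix:
    """Sparse documents x features matrix of raw frequency counts."""

    doc_ids: list[str]
    features: list[str]
    counts: sp.csr_matrix  # int counts, shape (n_docs, n_features)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_mass(self) -> int:
        return int(self.counts.sum())

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def zero_doc_ids(self) -> list[str]:
        row_sums = np.asarray(self.counts.sum(axis=1)).ravel()
        return [d for d, s in zip(self.doc_ids, row_sums) if s == 0]

    def save_triplets(self, path: str | Path) -> None:
        """Persist as a (doc_id, feature, count) tab-separated triplet file."""
        coo = self.counts.tocoo()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("doc_id\tfeature\tcount\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.doc_ids[i]}\t{self.features[j]}\t{int(v)}\n")


@dataclass
class DocVectors:
    """Dense document vectors tagged by the representation that produced them."""

    doc_ids: list[str]
    kind: str  # svd | topic | embedding
    matrix: np.ndarray  # shape (n_docs, dims)
    flagged: set = field(default_factory=set)  # doc_ids with degenerate rows

    def __post_init__(self) -> None:
        if self.kind not in ("svd", "topic", "embedding"):
            raise RepresentationError(f"unknown DocVectors kind {self.kind!r}")
        if self.matrix.shape[0] != len(self.doc_ids):
            raise RepresentationError("matrix rows must match doc_ids")

    @property
    def dims(self) -> int:
        return self.matrix.shape[1]

    def row(self, doc_id: str) -> np.ndarray:
        return self.matrix[self.doc_ids.index(doc_id)]

    def save_dense(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# kind={self.kind} dims={self.dims}\n")
            for d, row in zip(self.doc_ids, self.matrix):
                fh.write(d + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


class WordVectors:
    """A word -> R^D lookup; absent words are a detectable miss, never zeros."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise RepresentationError("empty word-vector vocabulary")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise RepresentationError(f"inconsistent word-vector dimensions: {sorted(dims)}")
        self._vec = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dims = dims.pop()

    def __contains__(self, word: str) -> bool:
        return word in self._vec

    def __len__(self) -> int:
        return len(self._vec)

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vec[word]

    def get(self, word: str) -> Optional[np.ndarray]:
        return self._vec.get(word)

    @property
    def vocabulary(self) -> list[str]:
        return list(self._vec)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w, v in self._vec.items():
                fh.write(w + " " + " ".join(f"{x:.10g}" for x in v) + "\n")


def load_word_vectors(path: str | Path) -> WordVectors:
    """Parse the plain-text "word v1 ... vD" embedding format.

    Ragged dimensions raise a format error naming the offending line;
    duplicate words resolve last-wins with a warning.
    """
    vectors: dict[str, np.ndarray] = {}
    dims: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            word, vals = parts[0], parts[1:]
            if dims is None:
                dims = len(vals)
                if dims == 0:
                    raise RepresentationError(f"{path}:{lineno}: no vector components")
            elif len(vals) != dims:
                raise RepresentationError(
                    f"{path}:{lineno}: expected {dims} components, found {len(vals)}"
                )
            if word in vectors:
                warnings.warn(f"duplicate word vector for {word!r}; keeping the last occurrence")
            try:
                vectors[word] = np.array([float(x) for x in vals])
            except ValueError as exc:
                raise RepresentationError(f"{path}:{lineno}: non-numeric component ({exc})") from exc
    return WordVectors(vectors)


def build_dfm(
    streams: Mapping[str, TokenStreams] | Sequence[tuple[str, TokenStreams]],
    which: str,
) -> DocFeatureMatrix:
    """Assemble the count matrix for one of the three feature streams.

    Feature order is lexicographic; documents keep corpus order. Documents
    whose selected stream is empty keep an all-zero row (logged), but a corpus
    where *every* document is empty is a construction error.
    """
    if which not in STREAM_NAMES:
        raise RepresentationError(f"unknown stream {which!r}; expected one of {STREAM_NAMES}")
    items = list(streams.items()) if isinstance(streams, Mapping) else list(streams)
    if not items:
        raise RepresentationError("no documents supplied")
    doc_counters = [(doc_id, getattr(ts, which)) for doc_id, ts in items]
    vocab = sorted(set().union(*(c.keys() for _, c in doc_counters)))
    if not vocab:
        raise RepresentationError(f"every document has an empty {which!r} stream")
    col = {f: j for j, f in enumerate(vocab)}
    rows, cols, data = [], [], []
    n_zero = 0
    for i, (_, counter) in enumerate(doc_counters):
        if not counter:
            n_zero += 1
        for f, c in counter.items():
            rows.append(i)
            cols.append(col[f])
            data.append(int(c))
    if n_zero:
        logger.warning("build_dfm(%s): %d document(s) have an all-zero row", which, n_zero)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(doc_counters), len(vocab)), dtype=np.int64
    )
    return DocFeatureMatrix(doc_ids=[d for d, _ in doc_counters], features=vocab, counts=counts)


def select_common_features(dfm: DocFeatureMatrix, phi: float) -> DocFeatureMatrix:
    """Keep the high-frequency features that jointly cover a phi fraction of mass.

    Features are ranked by total corpus frequency (ties broken
    lexicographically) and the smallest prefix whose cumulative frequency
    reaches ``phi`` of the total token mass is retained; documents are
    re-projected onto the retained columns.
    """
    if not (0.0 < phi <= 1.0):
        raise RepresentationError(f"phi must lie in (0, 1], got {phi}")
    totals = dfm.feature_totals()
    if totals.sum() == 0:
        raise RepresentationError("cannot select features from an empty matrix")
    order = sorted(range(len(dfm.features)), key=lambda j: (-totals[j], dfm.features[j]))
    target = phi * totals.sum()
    cum = 0.0
    keep: list[int] = []
    for j in order:
        keep.append(j)
        cum += totals[j]
        if cum >= target - 1e-12:
            break
    keep_sorted = sorted(keep, key=lambda j: dfm.features[j])
    logger.info(
        "select_common_features: kept %d/%d features covering %.1f%% of mass",
        len(keep_sorted), len(dfm.features), 100.0 * cum / totals.sum(),
    )
    return DocFeatureMatrix(
        doc_ids=list(dfm.doc_ids),
        features=[dfm.features[j] for j in keep_sorted],
        counts=dfm.counts[:, keep_sorted].tocsr(),
    )


def _deterministic_svd(X: sp.csr_matrix, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-d singular triplets with deterministic signs, sorted descending."""
    n, m = X.shape
    r_bound = min(n, m)
    if d >= r_bound - 1 or r_bound <= 2:
        U, s, Vt = np.linalg.svd(np.asarray(X.todense(), dtype=float), full_matrices=False)
    else:
        U, s, Vt = svds(X.astype(float), k=d)
        order = np.argsort(-s)
        U, s, Vt = U[:, order], s[order], Vt[order]
    # sign convention: largest-|.| component of each right singular vector is positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U, s


def svd_reduce(dfm: DocFeatureMatrix, d: int) -> DocVectors:
    """Latent-semantic document vectors: rows of U * Sigma for the top-d factors.

    If the matrix rank r is below ``d``, the output has r dimensions and a
    warning is logged.
    """
    if d < 1:
        raise RepresentationError(f"d must be >= 1, got {d}")
    U, s = _deterministic_svd(dfm.counts, d)
    tol = max(dfm.counts.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int((s > max(tol, 1e-12)).sum())
    dims = min(d, rank)
    if dims < d:
        warnings.warn(f"svd_reduce: requested d={d} exceeds matrix rank {rank}; using {dims} dims")
    scores = U[:, :dims] * s[:dims]
    return DocVectors(doc_ids=list(dfm.doc_ids), kind="svd", matrix=scores)


def fit_topics(
    dfm: DocFeatureMatrix, T: int, seed: int, max_iter: int = 100, tol: float = 1e-4
) -> DocVectors:
    """Per-document topic proportions from LDA on the nouns+verbs counts.

    Priors are symmetric: document-topic alpha = 1/T, topic-word beta = 0.01.
    Documents with an all-zero row are assigned the uniform distribution and
    flagged. Reproducible for a fixed seed.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    if T < 1:
        raise RepresentationError(f"T must be >= 1, got {T}")
    if T > len(dfm.features):
        raise RepresentationError(f"T={T} exceeds vocabulary size {len(dfm.features)}")
    row_sums = np.asarray(dfm.counts.sum(axis=1)).ravel()
    flagged = {d for d, s in zip(dfm.doc_ids, row_sums) if s == 0}
    if flagged:
        logger.warning("fit_topics: %d empty document(s) get the uniform distribution", len(flagged))
    if T == 1:
        theta = np.ones((len(dfm.doc_ids), 1))
        return DocVectors(doc_ids=list(dfm.doc_ids), kind="topic", matrix=theta, flagged=flagged)
    lda = LatentDirichletAllocation(
        n_components=T,
        doc_topic_prior=1.0 / T,
        topic_word_prior=0.01,
        learning_method="batch",
        max_iter=max_iter,
        evaluate_every=5,
        perp_tol=tol,
        random_state=seed,
    )
    nonzero = row_sums > 0
    lda.fit(dfm.counts[nonzero])
    theta = np.full((len(dfm.doc_ids), T), 1.0 / T)
    theta[nonzero] = lda.transform(dfm.counts[nonzero])
    theta = theta / theta.sum(axis=1, keepdims=True)
    return DocVectors(doc_ids=list(dfm.doc_ids), kind="topic", matrix=theta, flagged=flagged)


def embed_docs(dfm: DocFeatureMatrix, wv: WordVectors) -> DocVectors:
    """Frequency-weighted average word vector per document.

    Out-of-vocabulary features are dropped; documents left with no
    in-vocabulary word get a zero row and are flagged so distance code can
    exclude them.
    """
    in_vocab = [j for j, f in enumerate(dfm.features) if f in wv]
    if not in_vocab:
        raise RepresentationError("no document feature has a word vector")
    E = np.vstack([wv[dfm.features[j]] for j in in_vocab])  # (V_in, D)
    C = dfm.counts[:, in_vocab].astype(float)
    weights = np.asarray(C.sum(axis=1)).ravel()
    flagged = {d for d, s in zip(dfm.doc_ids, weights) if s == 0}
    if flagged:
        logger.warning("embed_docs: %d document(s) have no in-vocabulary words", len(flagged))
    M = np.asarray(C @ E)
    nz = weights > 0
    M[nz] = M[nz] / weights[nz, None]
    return DocVectors(doc_ids=list(dfm.doc_ids), kind="embedding", matrix=M, flagged=flagged)
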