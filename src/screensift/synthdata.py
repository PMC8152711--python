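"""Synthetic screening corpora with known structure.

The generator emulates the statistical situation the workflow is built for:
a large set of short documents drawn from a topic model, a small eligible
class (~5% prevalence) whose documents concentrate on designated "eligible"
topics so they are semantically clustered, and a handful of known-eligible
seed documents to bootstrap from. Vocabulary is synthetic (alphabetic
letter strings with cyclically assigned POS tags), so no linguistic
resources are needed anywhere in the test suite.

Labels are assigned by construction - exactly floor(prevalence * n_docs)
documents are generated from the eligible mixture - and everything is
reproducible from the config seed alone.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .corpus_io import Citation, Corpus
from .preprocess import ADJ, ADV, NOUN, VERB
from .representations import WordVectors

logger = logging.getLogger(__name__)

_POS_CYCLE = (NOUN, VERB, NOUN, ADJ, ADV)


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generative settings for a synthetic screening corpus."""

    n_docs: int = 1000
    prevalence: float = 0.05
    n_topics: int = 10
    eligible_topic_ids: Sequence[int] = (0, 1)
    vocab_size: int = 500
    doc_length_mean: float = 150.0
    eligible_mixture_boost: float = 5.0
    n_seeds: int = 3
    topic_word_alpha: float = 0.05   # sparse symmetric topic-word prior
    doc_topic_alpha: float = 0.3     # symmetric base document-topic prior
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise SynthConfigError("prevalence must lie in (0, 1)")
        if not self.eligible_topic_ids:
            raise SynthConfigError("eligible_topic_ids must be non-empty")
        if not set(self.eligible_topic_ids) < set(range(self.n_topics)):
            raise SynthConfigError("eligible_topic_ids must be a proper subset of topics")
        if self.doc_length_mean <= 0:
            raise SynthConfigError("doc_length_mean must be positive")
        if self.eligible_mixture_boost < 1.0:
            raise SynthConfigError("eligible_mixture_boost must be >= 1")
        n_eligible = int(self.prevalence * self.n_docs)
        if n_eligible < self.n_seeds:
            raise SynthConfigError(
                f"only {n_eligible} eligible documents but {self.n_seeds} seeds requested"
            )


def _make_vocabulary(size: int) -> list[str]:
    """Purely alphabetic synthetic words: 'w' + base-26 letter code."""
    letters = string.ascii_lowercase
    width = 1
    while 26**width < size:
        width += 1
    words = []
    for i in range(size):
        code, x = [], i
        for _ in range(width):
            code.append(letters[x % 26])
            x //= 26
        words.append("w" + "".join(reversed(code)))
    return words


def pos_lexicon_for(vocabulary: Sequence[str]) -> dict[str, str]:
    """Cyclic POS assignment so the nouns/verbs stream is non-trivial."""
    return {w: _POS_CYCLE[i % len(_POS_CYCLE)] for i, w in enumerate(vocabulary)}


@dataclass
class SyntheticCorpus:
    """A generated corpus plus the ground truth used to build it."""

    corpus: Corpus
    seed_ids: list[str]
    vocabulary: list[str]
    pos_lexicon: dict[str, str]
    topic_word: np.ndarray       # (n_topics, vocab)
    doc_mixtures: np.ndarray     # (n_docs, n_topics) true theta rows
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def eligible_ids(self) -> list[str]:
        return [d for d, lab in self.labels.items() if lab == 1]


def generate_corpus(cfg: SynthConfig) -> SyntheticCorpus:
    """Draw a labelled topic-model corpus with clustered eligible documents.

    Eligible documents up-weight the eligible topics' Dirichlet mass by
    ``eligible_mixture_boost``; document lengths are Poisson. The first
    sentence of each document doubles as its title.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _make_vocabulary(cfg.vocab_size)
    lexicon = pos_lexicon_for(vocab)
    topic_word = rng.dirichlet(np.full(cfg.vocab_size, cfg.topic_word_alpha), size=cfg.n_topics)

    n_eligible = int(cfg.prevalence * cfg.n_docs)
    labels_arr = np.zeros(cfg.n_docs, dtype=int)
    labels_arr[:n_eligible] = 1
    rng.shuffle(labels_arr)

    alpha_base = np.full(cfg.n_topics, cfg.doc_topic_alpha)
    elig_topics = list(cfg.eligible_topic_ids)
    # eligible mixtures put boost/(boost+1) of their mass on the eligible
    # topics (an eligible-topics-only draw) and the rest on a background
    # draw, so the eligible class is topically clustered by construction
    lam = cfg.eligible_mixture_boost / (cfg.eligible_mixture_boost + 1.0)

    citations: list[Citation] = []
    mixtures = np.empty((cfg.n_docs, cfg.n_topics))
    width = len(str(cfg.n_docs))
    for i in range(cfg.n_docs):
        theta = rng.dirichlet(alpha_base)
        if labels_arr[i]:
            theta_e = np.zeros(cfg.n_topics)
            theta_e[elig_topics] = rng.dirichlet(alpha_base[elig_topics])
            theta = lam * theta_e + (1.0 - lam) * theta
        mixtures[i] = theta
        length = max(20, int(rng.poisson(cfg.doc_length_mean)))
        topic_counts = rng.multinomial(length, theta)
        word_idx = np.concatenate(
            [rng.choice(cfg.vocab_size, size=c, p=topic_word[t])
             for t, c in enumerate(topic_counts) if c]
        )
        rng.shuffle(word_idx)
        tokens = [vocab[j] for j in word_idx]
        title = " ".join(tokens[:6]).capitalize() + "."
        body = tokens[6:]
        sentences = [" ".join(body[j : j + 12]).capitalize() + "." for j in range(0, len(body), 12)]
        citations.append(
            Citation(
                id=f"D{i:0{width}d}",
                title=title,
                abstract=" ".join(sentences),
                ref_label=int(labels_arr[i]),
            )
        )
    corpus = Corpus(citations)
    eligible_ids = [c.id for c in citations if c.ref_label == 1]
    seed_ids = sorted(rng.choice(eligible_ids, size=cfg.n_seeds, replace=False).tolist())
    return SyntheticCorpus(
        corpus=corpus, seed_ids=seed_ids, vocabulary=vocab, pos_lexicon=lexicon,
        topic_word=topic_word, doc_mixtures=mixtures,
        labels={c.id: c.ref_label for c in citations},
    )


def train_toy_embeddings(corpus: Corpus, D: int, seed: int, window: int = 5) -> WordVectors:
    """Word vectors from a truncated decomposition of the PPMI co-occurrence matrix.

    Co-occurrences are counted in a symmetric window over each document's
    whitespace tokens (lowercased, punctuation stripped); positive pointwise
    mutual information is factorized and rows are scaled by the square root
    of the singular values. Every in-corpus word receives a vector. If the
    matrix supports fewer than D factors, D is reduced with a warning.
    """
    if D < 2:
        raise SynthConfigError("D must be >= 2")
    if corpus.N == 0:
        raise SynthConfigError("cannot train embeddings on an empty corpus")
    vocab_index: dict[str, int] = {}
    docs_tokens: list[list[int]] = []
    for c in corpus:
        text = (c.title + " " + c.abstract).lower()
        toks = [t.strip(".,;:!?()[]") for t in text.split()]
        idx = []
        for t in toks:
            if not t:
                continue
            if t not in vocab_index:
                vocab_index[t] = len(vocab_index)
            idx.append(vocab_index[t])
        docs_tokens.append(idx)
    V = len(vocab_index)
    rows, cols, data = [], [], []
    for idx in docs_tokens:
        L = len(idx)
        for i in range(L):
            for j in range(i + 1, min(i + window + 1, L)):
                rows.extend((idx[i], idx[j]))
                cols.extend((idx[j], idx[i]))
                data.extend((1.0, 1.0))
    C = sp.coo_matrix((data, (rows, cols)), shape=(V, V)).tocsr()
    total = C.sum()
    row_sums = np.asarray(C.sum(axis=1)).ravel()
    row_sums[row_sums == 0] = 1.0
    coo = C.tocoo()
    pmi = np.log((coo.data * total) / (row_sums[coo.row] * row_sums[coo.col]))
    pmi = np.maximum(pmi, 0.0)
    P = sp.coo_matrix((pmi, (coo.row, coo.col)), shape=(V, V)).tocsr()
    d_eff = min(D, V - 1)
    if d_eff < D:
        warnings.warn(f"embedding dimension reduced from {D} to {d_eff} (vocabulary rank)")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(V)
    U, s, _ = svds(P, k=d_eff, v0=v0)
    order = np.argsort(-s)
    U, s = U[:, order], s[order]
    rank = int((s > 1e-10).sum())
    if rank < d_eff:
        warnings.warn(f"PPMI matrix rank {rank} below requested {d_eff} dimensions")
        U, s = U[:, :max(rank, 2)], s[:max(rank, 2)]
    M = U * np.sqrt(s)
    # deterministic sign: largest-|.| entry of each column positive
    for j in range(M.shape[1]):
        p = np.argmax(np.abs(M[:, j]))
        if M[p, j] < 0:
            M[:, j] *= -1.0
    words = list(vocab_index)
    vectors = {w: M[vocab_index[w]] for w in words}
    # degenerate rows (words with no PPMI mass) get a tiny deterministic offset
    for w in words:
        if not np.any(vectors[w]):
            h = sum(ord(ch) * (i + 1) for i, ch in enumerate(w))  # stable across runs
            v = np.zeros(M.shape[1])
            v[h % M.shape[1]] = 1e-6
            vectors[w] = v
    return WordVectors(vectors)
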