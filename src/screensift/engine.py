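"""Two-phase screening workflow orchestration.

Phase 1 bootstraps a training set from a handful of known-eligible seed
abstracts: the seeds' nearest neighbours under every distance provider are
screened by the (simulated) reviewer pair, newly confirmed eligibles become
the next round's seeds, and the loop runs until the screened count reaches
the target training-set size r or expansion is exhausted.

Phase 2 alternates model fitting and human confirmation: a SMOTE-balanced
random forest trained on all screened documents predicts eligible abstracts,
the unscreened predictions are screened, the newly confirmed eligibles are
expanded through their nearest neighbours (also screened), everything feeds
the next fit, and the loop stops at saturation - an iteration whose
predictions contain no new eligible abstract.

Representations and distances are computed once up front and are immutable
during the loops. A single master seed derives every component seed by fixed
offsets, so a run is reproducible from (corpus, config, seed) alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .classifier import ClassifierSpec, TrainingSet, predict_eligible, train_rf_cv
from .corpus_io import Corpus, screening_text
from .preprocess import default_stopwords, extract_streams, preprocess
from .representations import (
    DocVectors, WordVectors, build_dfm, embed_docs, fit_topics,
    select_common_features, svd_reduce,
)
from .similarity import DistanceProvider, VectorCosineProvider, WMDProvider, knn_expand

logger = logging.getLogger(__name__)

# fixed seed offsets per stochastic component (single master knob)
_SEED_LDA, _SEED_SMOTE, _SEED_RF, _SEED_NOISE = 11, 23, 37, 53


class WorkflowError(ValueError):
    pass


@dataclass
class WorkflowConfig:
    """All tunable workflow parameters (mirrors the flat config file)."""

    k1: int = 8            # phase-1 neighbours per seed
    k2: int = 15           # phase-2 neighbours per newly eligible doc
    r: int = 600           # phase-1 target screened count
    phi: float = 0.70      # common-feature cumulative-mass threshold
    svd_d: int = 300
    topics_T: int = 300
    embed_D: int = 300
    n_providers: int = 3   # 3 = svd+topic+wmd, 2 = svd+wmd
    n_trees: int = 500
    n_folds: int = 5
    smote_k: int = 5
    decision_threshold: float = 0.5
    tuning_grid: Optional[Sequence[int]] = None
    lda_max_iter: int = 100
    wmd_exact: bool = False
    wmd_cap: Optional[int] = 50
    seed: int = 0
    max_iterations: int = 25

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise WorkflowError("k1 and k2 must be >= 1")
        if self.r < 1:
            raise WorkflowError("r must be >= 1")
        if not (0.0 < self.phi <= 1.0):
            raise WorkflowError("phi must lie in (0, 1]")
        if self.max_iterations < 1:
            raise WorkflowError("max_iterations must be >= 1")
        if self.n_providers not in (2, 3):
            raise WorkflowError("n_providers must be 2 or 3")

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            n_trees=self.n_trees, n_folds=self.n_folds, tuning_grid=self.tuning_grid,
            smote_k=self.smote_k, decision_threshold=self.decision_threshold,
            seed=self.seed + _SEED_RF,
        )


@dataclass(frozen=True)
class ScreeningRecord:
    doc_id: str
    phase: int                 # 1 or 2
    iteration: int
    batch_kind: str            # seed_expansion | predicted | neighbour
    reviewer_decisions: tuple  # (reviewer1, reviewer2)
    decision: int              # adjudicated final decision


class ScreeningLog:
    """Append-only record of every screening decision; one entry per document."""

    def __init__(self) -> None:
        self.records: list[ScreeningRecord] = []
        self._seen: set[str] = set()

    def append(self, record: ScreeningRecord) -> None:
        if record.doc_id in self._seen:
            raise WorkflowError(f"document {record.doc_id!r} screened twice")
        self._seen.add(record.doc_id)
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._seen

    @property
    def screened_ids(self) -> set[str]:
        return set(self._seen)

    def decisions(self) -> dict[str, int]:
        return {rec.doc_id: rec.decision for rec in self.records}

    def eligible_ids(self) -> list[str]:
        return [rec.doc_id for rec in self.records if rec.decision == 1]

    def to_rows(self) -> list[tuple]:
        return [
            (r.doc_id, r.phase, r.iteration, r.batch_kind,
             r.reviewer_decisions[0], r.reviewer_decisions[1], r.decision)
            for r in self.records
        ]


@dataclass
class WorkflowResult:
    included: set[str]        # confirmed-eligible doc ids (N_WF against reference)
    predicted_ever: set[str]  # union of all docs ever predicted eligible (N_P)
    screened: set[str]        # every doc shown to reviewers (workload)
    iterations_run: int
    log: ScreeningLog
    capped: bool = False
    phase1_screened: int = 0
    phase1_eligible: int = 0


class ReferenceOracle:
    """Simulated reviewer pair that reproduces the reference standard exactly."""

    def __init__(self, labels: Mapping[str, int]):
        self.labels = dict(labels)

    def screen(self, doc_ids: Iterable[str]) -> dict[str, tuple[tuple[int, int], int]]:
        out = {}
        for d in doc_ids:
            if d not in self.labels:
                raise WorkflowError(f"no reference label for document {d!r}")
            lab = int(self.labels[d])
            out[d] = ((lab, lab), lab)
        return out


class NoisyOracle(ReferenceOracle):
    """Reviewer pair with independent per-reviewer error rates.

    Each reviewer independently flips the true label with their error
    probability; disagreements are adjudicated back to the reference label
    (consensus assumption), so noise perturbs individual decisions but not
    the final inclusion of a screened document.
    """

    def __init__(self, labels: Mapping[str, int], error_rates: tuple[float, float], seed: int):
        super().__init__(labels)
        self.error_rates = error_rates
        self._rng = np.random.default_rng(seed)

    def screen(self, doc_ids: Iterable[str]) -> dict[str, tuple[tuple[int, int], int]]:
        out = {}
        for d in doc_ids:
            if d not in self.labels:
                raise WorkflowError(f"no reference label for document {d!r}")
            lab = int(self.labels[d])
            r1 = lab ^ int(self._rng.random() < self.error_rates[0])
            r2 = lab ^ int(self._rng.random() < self.error_rates[1])
            final = lab if r1 != r2 else r1  # adjudicate disagreements to reference
            out[d] = ((r1, r2), final)
        return out


def oracle_screen(batch: Iterable[str], oracle: ReferenceOracle) -> dict[str, tuple[tuple[int, int], int]]:
    """Screen a batch through the reviewer oracle; decisions keyed by doc id."""
    return oracle.screen(batch)


def _screen_and_log(
    batch: Iterable[str], oracle: ReferenceOracle, log: ScreeningLog,
    phase: int, iteration: int, batch_kind: str,
) -> dict[str, int]:
    decisions = oracle_screen(sorted(batch), oracle)
    for d, (reviewers, final) in decisions.items():
        log.append(ScreeningRecord(d, phase, iteration, batch_kind, reviewers, final))
    return {d: final for d, (_, final) in decisions.items()}


def run_phase1(
    corpus: Corpus,
    seeds: Sequence[str],
    providers: Sequence[DistanceProvider],
    svd_vectors: DocVectors,
    config: WorkflowConfig,
    oracle: ReferenceOracle,
    log: Optional[ScreeningLog] = None,
) -> tuple[TrainingSet, ScreeningLog]:
    """Grow the training set by nearest-neighbour expansion from eligible seeds."""
    if not seeds:
        raise WorkflowError("phase 1 requires at least one eligible seed")
    missing = [s for s in seeds if s not in corpus]
    if missing:
        raise WorkflowError(f"seed(s) not in corpus: {missing}")
    log = log if log is not None else ScreeningLog()
    seed_decisions = _screen_and_log(seeds, oracle, log, phase=1, iteration=0,
                                     batch_kind="seed_expansion")
    not_eligible = [d for d, lab in seed_decisions.items() if lab != 1]
    if not_eligible:
        raise WorkflowError(f"seed(s) screened ineligible: {not_eligible}")

    frontier = list(seeds)
    iteration = 0
    while len(log) < config.r:
        iteration += 1
        candidates = knn_expand(frontier, config.k1, providers, log.screened_ids)
        if not candidates:
            # newly-eligible frontier exhausted; one re-expansion from all eligibles
            all_eligible = log.eligible_ids()
            if sorted(frontier) != sorted(all_eligible):
                candidates = knn_expand(all_eligible, config.k1, providers, log.screened_ids)
            if not candidates:
                warnings.warn(
                    f"phase 1 exhausted expansion at {len(log)} screened documents "
                    f"(target r={config.r})"
                )
                break
        decisions = _screen_and_log(candidates, oracle, log, phase=1, iteration=iteration,
                                    batch_kind="seed_expansion")
        newly_eligible = [d for d, lab in decisions.items() if lab == 1]
        logger.info("phase1 iter %d: screened %d (newly eligible %d, total %d)",
                    iteration, len(decisions), len(newly_eligible), len(log))
        frontier = newly_eligible if newly_eligible else log.eligible_ids()

    all_decisions = log.decisions()
    pos = {d: i for i, d in enumerate(svd_vectors.doc_ids)}
    ids = [d for d in all_decisions]
    X = svd_vectors.matrix[[pos[d] for d in ids]]
    y = np.array([all_decisions[d] for d in ids], dtype=int)
    return TrainingSet(doc_ids=ids, X=X, y=y), log


def run_phase2(
    corpus: Corpus,
    training: TrainingSet,
    providers: Sequence[DistanceProvider],
    svd_vectors: DocVectors,
    config: WorkflowConfig,
    oracle: ReferenceOracle,
    log: Optional[ScreeningLog] = None,
) -> WorkflowResult:
    """Iterate classify -> screen -> expand to saturation."""
    if not training.has_both_classes():
        raise WorkflowError("phase 2 needs both classes in the training set")
    log = log if log is not None else ScreeningLog()
    phase1_screened = len(log)
    phase1_eligible = len(log.eligible_ids())
    decisions = dict(zip(training.doc_ids, (int(v) for v in training.y)))
    pos = {d: i for i, d in enumerate(svd_vectors.doc_ids)}
    predicted_ever: set[str] = set()
    capped = True
    iteration = 0
    spec0 = config.classifier_spec()
    for iteration in range(1, config.max_iterations + 1):
        ids = list(decisions)
        train = TrainingSet(
            doc_ids=ids,
            X=svd_vectors.matrix[[pos[d] for d in ids]],
            y=np.array([decisions[d] for d in ids], dtype=int),
        )
        spec = replace(spec0, seed=spec0.seed + iteration)
        fitted = train_rf_cv(train, spec)
        predicted = predict_eligible(fitted, svd_vectors)
        predicted_ever |= predicted
        to_screen = predicted - log.screened_ids
        new_decisions = _screen_and_log(to_screen, oracle, log, phase=2,
                                        iteration=iteration, batch_kind="predicted")
        decisions.update(new_decisions)
        newly_eligible = sorted(d for d, lab in new_decisions.items() if lab == 1)
        logger.info(
            "phase2 iter %d: predicted %d, screened %d new, newly eligible %d "
            "(cv sensitivity %.3f, mtry %d)",
            iteration, len(predicted), len(new_decisions), len(newly_eligible),
            fitted.cv_sensitivity, fitted.chosen_mtry,
        )
        if not newly_eligible:
            capped = False  # saturation: no new eligible abstract this iteration
            break
        neighbours = knn_expand(newly_eligible, config.k2, providers, log.screened_ids)
        if neighbours:
            decisions.update(_screen_and_log(neighbours, oracle, log, phase=2,
                                             iteration=iteration, batch_kind="neighbour"))
    if capped:
        warnings.warn(f"phase 2 hit the iteration cap ({config.max_iterations}) before saturation")
    included = {d for d, lab in decisions.items() if lab == 1}
    return WorkflowResult(
        included=included, predicted_ever=predicted_ever, screened=log.screened_ids,
        iterations_run=iteration, log=log, capped=capped,
        phase1_screened=phase1_screened, phase1_eligible=phase1_eligible,
    )


@dataclass
class PipelineArtifacts:
    """Everything the setup stage produces, reusable across runs."""

    svd: DocVectors
    topics: DocVectors
    embedding: DocVectors
    providers: list
    bows: dict


def build_representations(
    corpus: Corpus,
    config: WorkflowConfig,
    word_vectors: WordVectors,
    stopwords: Optional[frozenset] = None,
    pos_lexicon: Optional[Mapping[str, str]] = None,
) -> PipelineArtifacts:
    """One-time setup: preprocess, build the three DFMs, reduce, index distances."""
    stops = default_stopwords() if stopwords is None else stopwords
    streams = {}
    for c in corpus:
        doc = preprocess(screening_text(c), citation_id=c.id, pos_lexicon=pos_lexicon)
        streams[c.id] = extract_streams(doc, stops)

    ngram_dfm = select_common_features(build_dfm(streams, "ngrams"), config.phi)
    svd = svd_reduce(ngram_dfm, config.svd_d)
    nv_dfm = build_dfm(streams, "nouns_verbs")
    T = min(config.topics_T, len(nv_dfm.features))
    if T < config.topics_T:
        logger.warning("topics_T=%d exceeds nouns/verbs vocabulary; using T=%d", config.topics_T, T)
    topics = fit_topics(nv_dfm, T, seed=config.seed + _SEED_LDA, max_iter=config.lda_max_iter)
    word_dfm = build_dfm(streams, "words")
    embedding = embed_docs(word_dfm, word_vectors)

    bows = {cid: ts.words for cid, ts in streams.items()}
    providers: list[DistanceProvider] = [VectorCosineProvider(svd)]
    if config.n_providers == 3:
        providers.append(VectorCosineProvider(topics))
    providers.append(WMDProvider(bows, word_vectors, exact=config.wmd_exact, cap=config.wmd_cap))
    return PipelineArtifacts(svd=svd, topics=topics, embedding=embedding,
                             providers=providers, bows=bows)


def run_workflow(
    corpus: Corpus,
    seeds: Sequence[str],
    config: WorkflowConfig,
    word_vectors: WordVectors,
    oracle: Optional[ReferenceOracle] = None,
    stopwords: Optional[frozenset] = None,
    pos_lexicon: Optional[Mapping[str, str]] = None,
    artifacts: Optional[PipelineArtifacts] = None,
) -> tuple[WorkflowResult, PipelineArtifacts]:
    """End-to-end run: representations, phase 1, phase 2.

    The oracle defaults to the perfect reviewer pair over the corpus's
    reference labels. Pass precomputed ``artifacts`` to reuse the expensive
    setup stage across configurations.
    """
    if oracle is None:
        labels = corpus.labels()
        if len(labels) != corpus.N:
            raise WorkflowError("corpus is not fully labelled; supply an oracle explicitly")
        oracle = ReferenceOracle(labels)
    if artifacts is None:
        artifacts = build_representations(corpus, config, word_vectors, stopwords, pos_lexicon)
    training, log = run_phase1(corpus, seeds, artifacts.providers, artifacts.svd, config, oracle)
    result = run_phase2(corpus, training, artifacts.providers, artifacts.svd, config, oracle, log=log)
    return result, artifacts
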