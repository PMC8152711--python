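# Methods

This note documents the modelling and numerical choices behind
`screensift`, what the synthetic benchmark does and does not demonstrate,
and the package's known limitations.

## Text processing

Titles and abstracts are joined with a single space (a terminator is added
to unterminated titles so sentence segmentation stays sane). Tokenization
keeps letter-initial tokens; pure numerals never become tokens.
Lemmatization is rule-based: a table of common irregular inflections plus
conservative suffix stripping (plural `-s/-es/-ies`, `-ing`, `-ed` with
doubled-consonant and final-`e` repair). POS tagging is coarse
({NOUN, VERB, ADJ, ADV, OTHER}) and heuristic — function-word list, a small
common-verb list, suffix rules, default NOUN — and can be overridden by an
explicit word→POS lexicon; synthetic corpora always supply one, so tagging
is exact wherever tests depend on it. The heuristics are deliberately
simple: the pipeline contract is alignment and determinism, not linguistic
fidelity, and all semantic heavy lifting happens in the representations.

Stream extraction: n-grams (n ≤ 3) never cross sentence boundaries;
stop-words (scikit-learn's English list by default, or a user file) are
removed from unigrams, the nouns/verbs stream and the words stream but kept
inside bigrams/trigrams so phrases like "risk_of_bias" survive; numerals
and single-character lemmas are dropped from every stream.

## Representations

All three document-feature matrices hold raw frequency counts; no tf-idf.

- **Common-feature selection (φ).** Features are ranked by total corpus
  frequency (ties lexicographic) and the smallest prefix whose cumulative
  frequency reaches φ of total token mass is kept. Interpreting φ as
  cumulative mass (default 0.70; 0.80/0.90 as sensitivity settings) makes
  the knob independent of corpus size. Applied to the n-gram matrix only.
- **SVD.** Document scores are U·Σ rows of the truncated factorization, so
  document inner products (and hence cosine geometry) of the count space
  are preserved at full rank. Signs are fixed by making the largest-|·|
  component of each right singular vector positive; requesting more
  dimensions than the rank reduces the dimension with a warning.
- **LDA.** Symmetric priors α = 1/T (document–topic) and β = 0.01
  (topic–word); batch variational inference with a perplexity-based
  convergence check (tol 1e-4, evaluated every 5 passes, 100-pass ceiling
  by default). Empty documents receive the uniform distribution and are
  flagged. Rows are renormalized to the simplex within 1e-8.
- **Embeddings.** A document is Σ_w c_w·v_w / Σ_w c_w over its
  in-vocabulary words; out-of-vocabulary features are dropped, documents
  with no in-vocabulary word are flagged and excluded from
  embedding-based distances. Word-vector files use the plain-text
  `word v1 … vD` format; duplicate words resolve last-wins, ragged
  dimensions are a format error.

## Distances and expansion

Cosine distance is 1 − cos(u, v) — bounded and sign-stable, unlike a 1/cos
transform. Zero/degenerate vectors raise rather than silently contribute.

The word-mover distance is the exact transportation LP (HiGHS) between the
two documents' normalized word-frequency distributions with cosine ground
cost; one marginal constraint is dropped as redundant. For corpus-scale
nearest-neighbour queries the provider defaults to the *relaxed* WMD — the
larger of the two one-sided bounds in which every unit of mass travels to
its nearest counterpart — which is a lower bound on the exact distance,
vectorizes over the whole corpus, and is labelled `wmd_relaxed` in
provenance. Documents can additionally be capped to their 50 most frequent
in-vocabulary words (configurable; exact uncapped mode is used in tests).

k-NN queries break distance ties by ascending document id, so runs are
bit-reproducible. Expansion takes the union over seeds × providers of the
k nearest documents, then removes seeds and previously screened documents;
a batch from s seeds, k neighbours, p providers therefore holds at most
s·k·p documents.

## Workflow loops

Phase 1 screens the seeds' neighbour batches iteratively; the *newly*
confirmed eligibles of each round are the next round's expansion seeds.
When a round confirms nothing new, expansion falls back once to all
eligibles found so far; if that also yields no unscreened candidate the
phase stops early with a warning (the target r = 600 by default, 300 as a
sensitivity setting). On tightly clustered corpora this exhaustion is the
common exit: the eligible neighbourhood is simply walked to completion.

Phase 2 stop rule: an iteration whose *predicted* batch yields no new
eligible abstract terminates the loop (neighbour-expansion finds from the
same iteration still enter the training set). The per-iteration forest is
refit on all decisions to date; `max_iterations` (default 25) is a safety
cap and a capped run is flagged in the result rather than raised.

Classifier: 500 trees, 5-fold stratified CV, features-per-split grid
{√D/2, √D, 2√D}, SMOTE k = 5, decision threshold 0.5 (all configurable).
SMOTE runs only inside training folds — validation folds contain original
rows only, which the fitted model's CV diagnostics expose for
verification. Grid ties go to the smaller value; sensitivity is measured
at the fixed threshold rather than by threshold tuning, the simplest
operationalization of sensitivity-maximizing CV. A single master seed
derives every component seed (LDA, SMOTE, forest, oracle noise) by fixed
offsets.

The reviewer pair is simulated: the perfect oracle returns the reference
label; the noisy oracle flips each reviewer's decision independently with
configured error rates and adjudicates disagreements back to the reference
label (consensus assumption), so noise perturbs individual decisions but
not the final inclusion of a screened document.

## Evaluation conventions

Precision, sensitivity and F1 are computed from N_WF, N_P and N_S as
defined in the README. Specificity and accuracy come from the standard
confusion matrix over all N documents with "predicted eligible" = the union
of everything ever predicted; the alternative formula
100·(N − N_WF)/(N − N_S) found in some screening reports exceeds 100%
whenever the workflow misses an eligible abstract, so it is reported in a
separate field for comparison and never used as specificity. Table-style
output rounds percentages to integers (error rates to one decimal); raw
values are always retained.

## Synthetic benchmark

The generator draws topic–word distributions from a sparse symmetric
Dirichlet (α_w = 0.05) over an alphabetic synthetic vocabulary (500 words,
cyclic POS assignment), and per-document topic mixtures from a symmetric
Dirichlet (α_t = 0.3) over 10 topics. Exactly ⌊prevalence·n⌋ documents are
eligible (labels by construction, positions shuffled by seed). An eligible
document's mixture is the convex combination
λ·θ_eligible + (1 − λ)·θ_background with λ = boost/(boost + 1) and
θ_eligible supported only on the designated eligible topics, so at the
default boost = 5 every eligible document carries ≥ 5/6 of its mass on
those topics. This *deterministic* up-weighting was chosen over boosting
the Dirichlet prior after observing that prior boosting leaves a large
minority of "eligible" documents topically indistinguishable from
background, contradicting the premise the generator exists to emulate —
that eligible abstracts form a semantic cluster. Document lengths are
Poisson (mean 150 words, floor 20); the first six tokens double as the
title. Toy word vectors come from a truncated SVD of the positive-PMI
co-occurrence matrix (window 5), rows scaled by √σ.

The reference study conditions are 2,000 documents at 5% prevalence,
boost 5, three seeds, with 50-dimensional representations, 200-tree
forests, 3-fold CV and a single-point tuning grid at √D — problem sizes
chosen so a complete study runs in minutes on one core. Under these
conditions phase-1 expansion typically walks the entire eligible cluster
(~10× prevalence enrichment among screened documents), phase 2 saturates
within a couple of iterations, sensitivity is near-perfect and 10–15% of
the corpus is screened.

What passing these runs shows: the loop terminates by saturation, seed
expansion concentrates eligibles far above prevalence, and the
classifier/expansion machinery recovers an eligible class that *is*
topically clustered, at realistic prevalence. What it does not show:
performance on real abstracts, where eligibility is only partially
explained by topical proximity, vocabulary is vastly larger, and reviewer
disagreement is structured rather than independent noise. The synthetic
cluster is cleaner than any real review; real-data sensitivity in the
upper-80s with multi-iteration saturation is the realistic expectation,
not the near-perfect synthetic numbers.

## Degenerate inputs and tie-breaks

Empty documents: kept as zero DFM rows (warned), uniform topic rows
(flagged), excluded from embedding distances (flagged). Feature ranking,
k-NN and grid selection all have deterministic tie-breaks (lexicographic,
ascending id, smaller value). SMOTE requires ≥ 2 minority points and clamps
k to n_minority − 1 with a warning. An unlabelled document reaching a
reference-based oracle is an error, not a silent skip.

## Known limitations

- The lemmatizer and tagger are heuristic; on real English text some
  inflections normalize imperfectly (e.g. rarer irregular verbs), slightly
  inflating vocabulary. Supply a lexicon for exactness.
- The UMLS/concept-annotation path used for clinical reviews is exposed
  only as the pluggable stream/embedding interface; no annotator ships.
- Relaxed WMD is a lower bound; neighbour rankings can differ from exact
  WMD. Exact mode is quadratic in corpus size times an LP per pair and is
  practical only for small corpora.
- N_P counts the union of documents ever predicted eligible across
  iterations; per-iteration prediction sets can be recovered from the log.
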