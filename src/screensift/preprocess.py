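"""Rule-based tokenization, lemmatization and coarse POS tagging.

Screening corpora are short technical abstracts; the goal of this stage is
not linguistic fidelity but a deterministic, dependency-free normalization
that maps inflectional variants ("runs", "ran", "running") onto a common
lemma ("run") and assigns coarse part-of-speech tags so that three feature
streams can be derived per document:

* ``ngrams``       - 1/2/3-grams of contiguous lemmas within a sentence,
* ``nouns_verbs``  - lemmas tagged noun or verb (topic-model input),
* ``words``        - non-stopword word lemmas (embedding input).

An explicit word->POS lexicon can override the suffix heuristics; synthetic
corpora ship such a lexicon so tagging is exact there.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

# Coarse tagset
NOUN, VERB, ADJ, ADV, OTHER = "NOUN", "VERB", "ADJ", "ADV", "OTHER"

_SENT_SPLIT = re.compile(r"(?<=[.!?;])\s+")
_TOKEN = re.compile(r"[A-Za-z][A-Za-z0-9'\-]*")

# Irregular inflections that suffix stripping cannot recover.
_IRREGULAR_LEMMAS = {
    "ran": "run", "running": "run", "runs": "run",
    "is": "be", "are": "be", "was": "be", "were": "be", "am": "be", "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "doing": "do",
    "went": "go", "gone": "go", "goes": "go",
    "found": "find", "showed": "show", "shown": "show", "gave": "give", "given": "give",
    "took": "take", "taken": "take", "made": "make", "saw": "see", "seen": "see",
    "men": "man", "women": "woman", "children": "child", "mice": "mouse", "feet": "foot",
    "data": "data", "analyses": "analysis", "diagnoses": "diagnosis", "hypotheses": "hypothesis",
    "criteria": "criterion", "studies": "study", "better": "good", "worse": "bad",
}

_VOWELS = set("aeiou")

# Function words default to OTHER; a compact list is enough for coarse tagging.
_FUNCTION_WORDS = frozenset(
    """a an the and or but nor so yet of in on at by for with to from into onto over under
    about between among through during before after above below up down out off again further
    is are was were be been being am do does did done doing have has had having will would
    shall should can could may might must not no nor this that these those it its they them
    their there here we our you your he she his her him i me my who whom which what when
    where why how all any both each few more most other some such only own same than too
    very as if because while until whether per via versus vs et al
    """.split()
)

_COMMON_VERBS = frozenset(
    """use show include compare evaluate assess conduct perform treat reduce increase improve
    report measure identify examine analyze determine develop provide receive require suggest
    indicate associate observe estimate apply screen review search select find make take give
    go see run test study base follow present describe demonstrate confirm""".split()
)


def _strip_suffix(word: str) -> str:
    """Heuristic English suffix stripping to a lemma. Input is lowercase."""
    w = word
    if len(w) <= 3:
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith(("xes", "ches", "shes", "zes")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    if w.endswith("ing") and len(w) > 5:
        stem = w[:-3]
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]  # running -> run
        if len(stem) >= 2 and stem[-1] not in _VOWELS and stem[-2] in _VOWELS and len(stem) <= 3:
            return stem + "e"  # making -> make (short stems only)
        return stem
    if w.endswith("ed") and len(w) > 4:
        stem = w[:-2]
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]
        if len(stem) >= 6 and stem.endswith(("at", "iz", "ys")):
            return stem + "e"  # evaluated -> evaluate, randomized -> randomize
        return stem
    return w


def lemmatize(token: str) -> str:
    """Lowercase and map a surface token to its lemma."""
    w = token.lower()
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if not w.isalpha():
        return w  # mixed alphanumerics are left untouched
    lemma = _strip_suffix(w)
    return _IRREGULAR_LEMMAS.get(lemma, lemma)


def _tag(token: str, lemma: str, lexicon: Optional[Mapping[str, str]]) -> str:
    if lexicon is not None:
        t = lexicon.get(lemma) or lexicon.get(token.lower())
        if t is not None:
            return t
    w = token.lower()
    if w in _FUNCTION_WORDS or lemma in _FUNCTION_WORDS:
        return OTHER
    if lemma in _COMMON_VERBS:
        return VERB
    if w.endswith("ly"):
        return ADV
    if w.endswith(("ous", "ive", "able", "ible", "al", "ic", "ful", "less")):
        return ADJ
    if w.endswith(("ing", "ed", "ize", "ise", "ate")):
        return VERB
    return NOUN


@dataclass
class PreprocDoc:
    """Aligned token/lemma/POS lists for one document, with sentence spans."""

    citation_id: str
    tokens: list[str] = field(default_factory=list)
    lemmas: list[str] = field(default_factory=list)
    pos: list[str] = field(default_factory=list)
    sent_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.lemmas) == len(self.pos)):
            raise ValueError("tokens, lemmas and pos must be aligned")


@dataclass
class TokenStreams:
    """The three feature multisets extracted from one document."""

    ngrams: Counter
    nouns_verbs: Counter
    words: Counter


def preprocess(
    text: str,
    citation_id: str = "",
    pos_lexicon: Optional[Mapping[str, str]] = None,
) -> PreprocDoc:
    """Tokenize, lemmatize and POS-tag a screening text.

    Punctuation is dropped; tokens must start with a letter, so pure numerals
    never become tokens. Empty text yields an empty document, not an error.
    """
    tokens: list[str] = []
    lemmas: list[str] = []
    pos: list[str] = []
    bounds: list[tuple[int, int]] = []
    for sent in _SENT_SPLIT.split(text or ""):
        start = len(tokens)
        for m in _TOKEN.finditer(sent):
            tok = m.group(0).strip("'-")
            if not tok:
                continue
            lemma = lemmatize(tok)
            tokens.append(tok)
            lemmas.append(lemma)
            pos.append(_tag(tok, lemma, pos_lexicon))
        if len(tokens) > start:
            bounds.append((start, len(tokens)))
    return PreprocDoc(citation_id=citation_id, tokens=tokens, lemmas=lemmas, pos=pos, sent_bounds=bounds)


def _keepable(lemma: str, stopwords: frozenset | set) -> bool:
    # unigram-eligible: word-like, length >= 2, not a stopword, not numeric
    return len(lemma) >= 2 and not lemma.isdigit() and lemma not in stopwords


def extract_streams(doc: PreprocDoc, stopwords: Iterable[str] = ()) -> TokenStreams:
    """Derive the three feature streams from a preprocessed document.

    N-grams never cross sentence boundaries. Stop-words are removed from the
    unigram, nouns/verbs and words streams, but are kept *inside* bigrams and
    trigrams (phrases like "risk_of_bias" survive). Numerals and
    single-character lemmas are dropped everywhere.
    """
    stops = frozenset(w.lower() for w in stopwords)
    ngrams: Counter = Counter()
    nouns_verbs: Counter = Counter()
    words: Counter = Counter()
    for start, end in doc.sent_bounds:
        sent_lemmas = []
        sent_pos = []
        for i in range(start, end):
            lem = doc.lemmas[i]
            if len(lem) < 2 or lem.isdigit():
                continue
            sent_lemmas.append(lem)
            sent_pos.append(doc.pos[i])
        L = len(sent_lemmas)
        for i, lem in enumerate(sent_lemmas):
            if lem not in stops:
                ngrams[lem] += 1
                words[lem] += 1
                if sent_pos[i] in (NOUN, VERB):
                    nouns_verbs[lem] += 1
        for n in (2, 3):
            for i in range(L - n + 1):
                ngrams["_".join(sent_lemmas[i : i + n])] += 1
    return TokenStreams(ngrams=ngrams, nouns_verbs=nouns_verbs, words=words)


def load_stopwords(path) -> frozenset:
    """Read a plain-text stop-word list, one word per line; '#' comments allowed."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip().lower()
            if w and not w.startswith("#"):
                out.add(w)
    return frozenset(out)


def default_stopwords() -> frozenset:
    """The built-in English stop-word list (scikit-learn's)."""
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)
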