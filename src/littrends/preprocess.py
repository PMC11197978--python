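"""Text preprocessing: cleaning, stemming, phrase merging, vocabulary pruning.

The chain turns raw title+abstract text into token-id lists over a pruned
vocabulary, ready for the Gibbs sampler:

    clean -> tokenize -> stem -> detect_phrases -> prune

Cleaning lower-cases and keeps only ``[a-z0-9 -]`` (hyphens stay inside
tokens: biomedical compounds like "hpv-positive" are meaningful). Stemming
is the Porter algorithm. Phrase detection merges high-scoring adjacent
bigrams into single "a_b" tokens. Pruning removes stopwords and terms with
extreme document frequency, then re-indexes the vocabulary.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._porter import stem as porter_stem
from ._stopwords import STOPWORDS
from .corpus import Corpus

logger = logging.getLogger(__name__)

_KEEP = re.compile(r"[^a-z0-9 \-]")
_WS = re.compile(r"\s+")


@dataclass
class Tokenized:
    """A corpus as token-id lists over a shared vocabulary.

    ``doc_tokens[j]`` is the ordered token-id array for document j;
    ``doc_ids``/``years`` align positionally with ``doc_tokens``.
    """

    doc_tokens: list[np.ndarray]
    vocab: list[str]
    doc_ids: list[str]
    years: list[int]

    @property
    def V(self) -> int:
        return len(self.vocab)

    @property
    def M(self) -> int:
        return len(self.doc_tokens)

    @property
    def N_j(self) -> np.ndarray:
        return np.asarray([len(t) for t in self.doc_tokens], dtype=np.int64)

    @property
    def total_tokens(self) -> int:
        return int(self.N_j.sum())

    def word_counts(self) -> np.ndarray:
        """Corpus-wide token counts per vocabulary id."""
        counts = np.zeros(self.V, dtype=np.int64)
        for toks in self.doc_tokens:
            np.add.at(counts, toks, 1)
        return counts


def clean(text: str) -> str:
    """Lower-case; replace characters outside [a-z0-9 space hyphen]; collapse runs."""
    out = _KEEP.sub(" ", text.lower())
    return _WS.sub(" ", out).strip()


def stem(token: str) -> str:
    """Porter stem of one cleaned token (hyphenated parts stemmed separately)."""
    if "-" in token:
        return "-".join(porter_stem(p) if p else "" for p in token.split("-"))
    return porter_stem(token)


def tokenize(corpus: Corpus, do_stem: bool = True) -> list[list[str]]:
    """clean + split + (optionally) stem every document; order preserved."""
    docs = []
    for d in corpus:
        toks = clean(d.text).split()
        if do_stem:
            toks = [stem(t) for t in toks]
        docs.append([t for t in toks if t])
    return docs


def detect_phrases(docs: list[list[str]], min_count: int = 5,
                   threshold: float = 10.0) -> list[list[str]]:
    """Merge collocated adjacent bigrams into single "a_b" tokens.

    An adjacent pair (a, b) is merged when count(a,b) >= min_count and

        score(a, b) = (count(a,b) - min_count) * V / (count(a) * count(b))

    reaches ``threshold``, where V is the current vocabulary size. One
    greedy left-to-right pass per document; a token consumed by a merge
    cannot start another merge.
    """
    unigram = Counter(t for doc in docs for t in doc)
    bigram = Counter((doc[i], doc[i + 1]) for doc in docs
                     for i in range(len(doc) - 1))
    V = len(unigram)
    merge = set()
    for (a, b), nab in bigram.items():
        if nab >= min_count:
            score = (nab - min_count) * V / (unigram[a] * unigram[b])
            if score >= threshold:
                merge.add((a, b))
    if not merge:
        return [list(doc) for doc in docs]
    out = []
    for doc in docs:
        merged, i = [], 0
        while i < len(doc):
            if i + 1 < len(doc) and (doc[i], doc[i + 1]) in merge:
                merged.append(f"{doc[i]}_{doc[i + 1]}")
                i += 2
            else:
                merged.append(doc[i])
                i += 1
        out.append(merged)
    return out


def prune(docs: list[list[str]], corpus: Corpus,
          stopwords: set[str] | None = None, min_df: int = 5,
          max_df_frac: float = 0.5) -> Tokenized:
    """Drop stopwords and extreme-document-frequency terms; build Tokenized.

    Terms in fewer than ``min_df`` documents or more than
    ``max_df_frac * M`` documents are removed. Documents emptied by pruning
    are dropped (and logged); emptying every document is an error.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not 0 < max_df_frac <= 1:
        raise ValueError("max_df_frac must lie in (0, 1]")
    if len(docs) != corpus.M:
        raise ValueError("docs and corpus are misaligned")

    stop = STOPWORDS | {stem(w) for w in STOPWORDS}
    if stopwords:
        stop = stop | set(stopwords) | {stem(w) for w in stopwords}

    live = [([t for t in doc if t not in stop], record)
            for doc, record in zip(docs, corpus)]
    # Single pass: frequency thresholds are judged on the input corpus's
    # document-frequency table, then emptied documents are dropped. (Emptied
    # documents contain no surviving term, so surviving terms' document
    # frequencies are unchanged by their removal.)
    df = Counter()
    for doc, _ in live:
        df.update(set(doc))
    max_df = max_df_frac * len(live)
    keep = {t for t, n in df.items() if min_df <= n <= max_df}
    pruned = []
    for doc, record in live:
        kept = [t for t in doc if t in keep]
        if kept:
            pruned.append((kept, record))
        else:
            logger.warning("document %s empty after pruning; dropped",
                           record.doc_id)
    live = pruned
    if not live:
        raise ValueError("pruning emptied every document")

    vocab = sorted({t for doc, _ in live for t in doc})
    index = {t: i for i, t in enumerate(vocab)}
    doc_tokens = [np.asarray([index[t] for t in doc], dtype=np.int64)
                  for doc, _ in live]
    return Tokenized(doc_tokens=doc_tokens, vocab=vocab,
                     doc_ids=[r.doc_id for _, r in live],
                     years=[r.year for _, r in live])


def preprocess(corpus: Corpus, stopwords: set[str] | None = None,
               min_df: int = 5, max_df_frac: float = 0.5,
               phrase_min_count: int = 5, phrase_threshold: float = 10.0,
               phrases: bool = True) -> Tokenized:
    """Full chain: clean, stem, merge phrases, prune."""
    docs = tokenize(corpus)
    if phrases:
        docs = detect_phrases(docs, phrase_min_count, phrase_threshold)
    return prune(docs, corpus, stopwords=stopwords,
                 min_df=min_df, max_df_frac=max_df_frac)
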