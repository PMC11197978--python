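"""MeSH-term and gene trend analyses.

Documents are pooled by their dominant topic (argmax of theta). Term-level
outputs: a term-by-topic count matrix filtered to terms appearing more than
five times overall and showing a significant cross-topic association
(chi-square against the topic-size margin); a term-by-year table of
high-frequency terms (at least six occurrences in a year); and a
first-emergence table per term, flagging terms already present in the
corpus's first year as left-censored.

Gene-level outputs mirror these: lexicon-based case-sensitive matching of
gene symbols in the raw text, an optional corpus TF-IDF floor on candidate
symbols, a total-count filter of two or more mentions, the same cross-topic
association test, and annual/first-appearance tables.
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .corpus import Corpus
from .lda import TopicModel


@dataclass
class TermTopicMatrix:
    counts: pd.DataFrame           # terms x topics, nonnegative ints
    min_count: int
    alpha_level: float

    @property
    def terms(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class EmergenceTable:
    table: pd.DataFrame            # term, first_year, left_censored, total
    annual_counts: pd.DataFrame    # terms x years


def assign_documents(model: TopicModel) -> np.ndarray:
    """Dominant topic per document; ties go to the lower topic index."""
    return model.dominant_topic()


def _topic_association_ok(term_counts: np.ndarray, margin: np.ndarray,
                          alpha_level: float) -> bool:
    """Chi-square goodness-of-fit of a term's topic counts vs the margin."""
    total = term_counts.sum()
    if total == 0:
        return False
    present = margin > 0
    if present.sum() < 2:
        # a single populated topic leaves no cross-topic variation to test
        return True
    expected = margin / margin.sum() * total
    stat, p = chisquare(term_counts[present], expected[present])
    return bool(p < alpha_level)


def topic_term_matrix(corpus: Corpus, assignments: np.ndarray,
                      min_count: int = 5, alpha_level: float = 0.05,
                      K: int | None = None) -> TermTopicMatrix:
    """Term-by-topic document counts, filtered by frequency and association.

    A term is retained only if its total count exceeds ``min_count``
    (strictly: the default keeps terms appearing more than five times) and
    its distribution over topics differs significantly from the
    documents-per-topic margin at ``alpha_level``. Counting is per-document
    presence: a heading is a set member, not a repeatable token.
    """
    if len(assignments) != corpus.M:
        raise ValueError("assignments must cover all documents")
    if K is None:
        K = int(np.max(assignments)) + 1 if corpus.M else 0
    counts: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(K, dtype=np.int64))
    margin = np.zeros(K, dtype=np.int64)
    for doc, k in zip(corpus, assignments):
        margin[k] += 1
        for tag in doc.tags:
            counts[tag][k] += 1
    kept = {}
    for term, row in counts.items():
        if row.sum() <= min_count:
            continue
        if not _topic_association_ok(row.astype(float), margin.astype(float),
                                     alpha_level):
            continue
        kept[term] = row
    df = pd.DataFrame.from_dict(kept, orient="index",
                                columns=[f"topic{k}" for k in range(K)])
    df = df.sort_index()
    df.index.name = "term"
    return TermTopicMatrix(counts=df, min_count=min_count,
                           alpha_level=alpha_level)


def annual_terms(corpus: Corpus, min_count: int = 6) -> pd.DataFrame:
    """Term-by-year document counts, keeping cells with count >= min_count.

    A term appears in year y's column only if at least ``min_count``
    documents from year y carry it (inclusive threshold); other cells are 0.
    """
    raw: dict[str, Counter] = defaultdict(Counter)
    for doc in corpus:
        for tag in doc.tags:
            raw[tag][doc.year] += 1
    years = sorted({d.year for d in corpus})
    rows = {}
    for term, per_year in raw.items():
        vals = [per_year.get(y, 0) if per_year.get(y, 0) >= min_count else 0
                for y in years]
        if any(vals):
            rows[term] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=years,
                                dtype=np.int64).sort_index()
    df.index.name = "term"
    return df


def emergence(corpus: Corpus, start_year: int | None = None) -> EmergenceTable:
    """First year each term appears, regardless of frequency.

    Terms first seen in the corpus's minimum year are flagged left-censored
    (they may predate the collection window). Reporting starts at
    ``start_year`` (default: the year after the corpus minimum), but
    left-censored terms are listed with their censoring flag.
    """
    annual: dict[str, Counter] = defaultdict(Counter)
    for doc in corpus:
        for tag in doc.tags:
            annual[tag][doc.year] += 1
    if not annual:
        return EmergenceTable(
            table=pd.DataFrame(columns=["term", "first_year", "left_censored",
                                        "total"]),
            annual_counts=pd.DataFrame())
    corpus_min = min(d.year for d in corpus)
    corpus_max = max(d.year for d in corpus)
    if start_year is None:
        start_year = corpus_min + 1
    if not corpus_min <= start_year <= corpus_max:
        raise ValueError(f"start_year {start_year} outside corpus range "
                         f"{corpus_min}-{corpus_max}")
    years = list(range(corpus_min, corpus_max + 1))
    rows = []
    counts = {}
    for term, per_year in sorted(annual.items()):
        first = min(y for y, n in per_year.items() if n > 0)
        censored = first == corpus_min
        if first >= start_year or censored:
            rows.append({"term": term, "first_year": first,
                         "left_censored": censored,
                         "total": sum(per_year.values())})
            counts[term] = [per_year.get(y, 0) for y in years]
    table = pd.DataFrame(rows, columns=["term", "first_year", "left_censored",
                                        "total"])
    annual_df = pd.DataFrame.from_dict(counts, orient="index", columns=years,
                                       dtype=np.int64)
    annual_df.index.name = "term"
    return EmergenceTable(table=table, annual_counts=annual_df)


_TOKEN_RE = re.compile(r"[A-Za-z0-9\-]+")


def extract_genes(corpus: Corpus, lexicon: list[str],
                  tfidf_min: float = 0.0) -> pd.DataFrame:
    """Count gene-symbol mentions per document (case-sensitive whole tokens).

    A symbol is counted only if its corpus-level TF-IDF weight — total
    mention count times ln(M / document frequency) — reaches ``tfidf_min``.
    The default 0 passes every matched symbol through (a symbol occurring in
    every document has IDF 0 and is excluded by any positive floor).
    Returns a documents x genes count table (documents as doc_id index).
    """
    if not lexicon:
        raise ValueError("empty gene lexicon")
    lex = set(lexicon)
    M = corpus.M
    per_doc: list[Counter] = []
    for doc in corpus:
        tokens = _TOKEN_RE.findall(doc.text)
        per_doc.append(Counter(t for t in tokens if t in lex))
    tf = Counter()
    df_count = Counter()
    for c in per_doc:
        tf.update(c)
        df_count.update(c.keys())
    kept = sorted(g for g in tf
                  if tf[g] * math.log(M / df_count[g]) >= tfidf_min)
    out = pd.DataFrame(0, index=[d.doc_id for d in corpus], columns=kept,
                       dtype=np.int64)
    for doc, c in zip(corpus, per_doc):
        for g in kept:
            if c.get(g):
                out.at[doc.doc_id, g] = c[g]
    out.index.name = "doc_id"
    return out


@dataclass
class GeneTrends:
    by_year: pd.DataFrame     # genes x years mention counts
    by_topic: pd.DataFrame    # genes x topics mention counts
    new_by_year: dict[int, list[str]]


def gene_trends(gene_counts: pd.DataFrame, corpus: Corpus,
                assignments: np.ndarray, min_total: int = 2,
                alpha_level: float = 0.05) -> GeneTrends:
    """Annual and per-topic gene tables plus first-appearance years.

    Keeps genes mentioned ``min_total`` or more times in total (inclusive)
    that pass the same chi-square topic-association test applied to MeSH
    terms; mention counts (not document counts) are tabulated by default.
    """
    if len(assignments) != corpus.M:
        raise ValueError("assignments must cover all documents")
    K = int(np.max(assignments)) + 1 if corpus.M else 0
    years = sorted({d.year for d in corpus})
    year_of = {d.doc_id: d.year for d in corpus}
    topic_of = {d.doc_id: int(k) for d, k in zip(corpus, assignments)}
    margin = np.bincount(assignments, minlength=K).astype(float)

    totals = gene_counts.sum(axis=0)
    by_year = pd.DataFrame(0, index=gene_counts.columns, columns=years,
                           dtype=np.int64)
    by_topic = pd.DataFrame(0, index=gene_counts.columns,
                            columns=[f"topic{k}" for k in range(K)],
                            dtype=np.int64)
    for doc_id, row in gene_counts.iterrows():
        y = year_of[doc_id]
        k = topic_of[doc_id]
        for g, n in row[row > 0].items():
            by_year.at[g, y] += n
            by_topic.at[g, f"topic{k}"] += n

    keep = []
    for g in gene_counts.columns:
        if totals[g] < min_total:
            continue
        if not _topic_association_ok(by_topic.loc[g].to_numpy(dtype=float),
                                     margin, alpha_level):
            continue
        keep.append(g)
    by_year = by_year.loc[keep]
    by_topic = by_topic.loc[keep]
    by_year.index.name = by_topic.index.name = "gene"

    new_by_year: dict[int, list[str]] = {y: [] for y in years}
    for g in keep:
        first = min(y for y in years if by_year.at[g, y] > 0)
        new_by_year[first].append(g)
    return GeneTrends(by_year=by_year, by_topic=by_topic,
                      new_by_year=new_by_year)
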