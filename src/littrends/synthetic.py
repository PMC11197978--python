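"""Synthetic literature corpora drawn from a known LDA generative process.

Every downstream stage (sampler, K-selection, significance ranking, trend
tables) can be validated against the ground truth this module emits: the
true topic-word matrix phi, document-topic matrix theta, token labels z,
the indices of planted junk topics, and the tag/gene-to-topic maps.

Documents are rendered as text so the corpus can flow through the same
preprocessing as real records: topic words are lower-case synthetic
surface forms ("wq0017"), tags are "tag0003"-style headings, and gene
mentions are literal upper-case symbols embedded in the text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document

#: junk-plant kinds: flat word distribution / corpus-marginal word distribution
JUNK_UNIFORM = "uniform"
JUNK_VACUOUS = "vacuous"


@dataclass
class GenerativeSpec:
    """Parameters of the generating process.

    ``K_true`` counts all topics including planted junk ones; junk topics
    occupy the last ``len(junk_plants)`` indices. ``tag_enrichment`` is the
    probability that a document's tag is drawn from its dominant topic's
    preferred tags rather than uniformly from the lexicon. ``year_skew``
    optionally concentrates one topic's documents late in the year range:
    ``(topic, strength)`` re-draws the year from the final third of the
    range with probability ``strength`` for documents dominated by that
    topic (defaults off, keeping period sub-corpora balanced).
    """

    K_true: int = 6
    V: int = 300
    M: int = 400
    alpha: float = 0.1
    beta: float = 0.05
    doc_length_mean: float = 60.0
    years: tuple[int, int] = (2013, 2022)
    junk_plants: tuple[str, ...] = ()
    tag_lexicon_size: int = 60
    tags_per_doc_mean: float = 3.0
    tag_enrichment: float = 0.8
    gene_lexicon: tuple[str, ...] = ()
    gene_rate: float = 0.0
    seed: int = 0
    separated: bool = False
    year_skew: tuple[int, float] | None = None

    def validate(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.V < self.K_true:
            raise ValueError("V must be >= K_true")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0.0 <= self.tag_enrichment <= 1.0:
            raise ValueError("tag_enrichment must lie in [0, 1]")
        if len(self.junk_plants) >= self.K_true:
            raise ValueError("need at least one non-junk topic")
        for kind in self.junk_plants:
            if kind not in (JUNK_UNIFORM, JUNK_VACUOUS):
                raise ValueError(f"unknown junk plant {kind!r}")
        if self.separated and self.V % self.K_true != 0:
            raise ValueError("separated spec requires V divisible by K_true")
        if self.years[0] > self.years[1]:
            raise ValueError("years range reversed")


@dataclass
class GroundTruth:
    """True latent state behind a generated corpus."""

    phi_true: np.ndarray          # K_true x V, row-stochastic
    theta_true: np.ndarray        # M x K_true, row-stochastic
    z_true: list[np.ndarray]      # per-document token topic labels
    junk_ids: tuple[int, ...]
    tag_topic_map: dict[str, int]
    gene_topic_map: dict[str, int]
    vocab: list[str] = field(default_factory=list)  # surface form per word id

    def dominant_topics(self) -> np.ndarray:
        return np.argmax(self.theta_true, axis=1)

    def to_json(self, path: str) -> None:
        payload = {
            "phi_true": self.phi_true.tolist(),
            "theta_true": self.theta_true.tolist(),
            "z_true": [z.tolist() for z in self.z_true],
            "junk_ids": list(self.junk_ids),
            "tag_topic_map": self.tag_topic_map,
            "gene_topic_map": self.gene_topic_map,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def separated_spec(K: int, V: int, **overrides) -> GenerativeSpec:
    """Spec whose topics have disjoint word support.

    Topic k is uniform over its own block of V/K words, so any two topic
    rows are orthogonal and each row's KL divergence to the uniform
    distribution over V words is exactly ln(K) — the maximally recoverable
    fixture for sampler and K-selection validation.
    """
    if V % K != 0:
        raise ValueError(f"V={V} not divisible by K={K}")
    spec = GenerativeSpec(K_true=K, V=V, separated=True, **overrides)
    spec.validate()
    return spec


def _make_phi(spec: GenerativeSpec, rng: np.random.Generator) -> np.ndarray:
    K, V = spec.K_true, spec.V
    n_junk = len(spec.junk_plants)
    n_real = K - n_junk
    phi = np.empty((K, V))
    if spec.separated:
        block = V // K
        phi[:] = 0.0
        for k in range(K):
            phi[k, k * block:(k + 1) * block] = 1.0 / block
        return phi
    for k in range(n_real):
        phi[k] = rng.dirichlet(np.full(V, spec.beta))
    marginal = phi[:n_real].mean(axis=0)
    for j, kind in enumerate(spec.junk_plants):
        row = n_real + j
        phi[row] = 1.0 / V if kind == JUNK_UNIFORM else marginal
    return phi


def generate(spec: GenerativeSpec) -> tuple[Corpus, GroundTruth]:
    """Sample a corpus by the standard LDA process.

    Per document: theta_j ~ Dir(alpha); length ~ Poisson(doc_length_mean)
    truncated at >= 5; per token z ~ Cat(theta_j), w ~ Cat(phi_z). Years are
    uniform over the range (unless year_skew applies); tags and gene
    mentions are appended per the enrichment rules. Deterministic for a
    fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, V, M = spec.K_true, spec.V, spec.M
    n_junk = len(spec.junk_plants)
    junk_ids = tuple(range(K - n_junk, K))

    phi = _make_phi(spec, rng)
    width = len(str(V - 1))
    vocab_words = [f"wq{i:0{width}d}" for i in range(V)]

    tag_names = [f"tag{i:03d}" for i in range(spec.tag_lexicon_size)]
    tag_topic_map = {t: i % K for i, t in enumerate(tag_names)}
    topic_tags: dict[int, list[str]] = {k: [] for k in range(K)}
    for t, k in tag_topic_map.items():
        topic_tags[k].append(t)

    gene_topic_map = {g: i % K for i, g in enumerate(spec.gene_lexicon)}
    topic_genes: dict[int, list[str]] = {k: [] for k in range(K)}
    for g, k in gene_topic_map.items():
        topic_genes[k].append(g)

    y0, y1 = spec.years
    late_start = y1 - max(1, (y1 - y0 + 1) // 3) + 1

    theta = rng.dirichlet(np.full(K, spec.alpha), size=M)
    docs: list[Document] = []
    z_all: list[np.ndarray] = []
    for j in range(M):
        n_tok = max(5, rng.poisson(spec.doc_length_mean))
        z = rng.choice(K, size=n_tok, p=theta[j])
        words = [vocab_words[rng.choice(V, p=phi[k])] for k in z]
        dom = int(np.argmax(theta[j]))

        year = int(rng.integers(y0, y1 + 1))
        if spec.year_skew is not None:
            skew_topic, strength = spec.year_skew
            if dom == skew_topic and rng.random() < strength:
                year = int(rng.integers(late_start, y1 + 1))

        n_tags = rng.poisson(spec.tags_per_doc_mean)
        tags = set()
        for _ in range(n_tags):
            pool = topic_tags[dom] if (rng.random() < spec.tag_enrichment
                                       and topic_tags[dom]) else tag_names
            if pool:
                tags.add(pool[rng.integers(len(pool))])

        if spec.gene_rate > 0 and spec.gene_lexicon:
            for _ in range(rng.poisson(spec.gene_rate)):
                pool = topic_genes[dom] or list(spec.gene_lexicon)
                words.append(pool[rng.integers(len(pool))])

        docs.append(Document(doc_id=str(j + 1), year=year,
                             text=" ".join(words), tags=frozenset(tags)))
        z_all.append(np.asarray(z, dtype=np.int64))

    truth = GroundTruth(phi_true=phi, theta_true=theta, z_true=z_all,
                        junk_ids=junk_ids, tag_topic_map=tag_topic_map,
                        gene_topic_map=gene_topic_map, vocab=vocab_words)
    corpus = Corpus(docs, provenance=f"synthetic:seed={spec.seed}")
    return corpus, truth


def truth_model(truth: GroundTruth, tok) -> "object":
    """View the ground truth as a TopicModel over a tokenized corpus.

    Restricts phi_true to the tokenized vocabulary (renormalizing rows) and
    theta_true to the surviving documents, so the planted topic set can be
    scored by the significance-ranking machinery exactly as a fitted model
    would be. Raises if a tokenized term is not a generator word.
    """
    from .lda import TopicModel

    col = {w: i for i, w in enumerate(truth.vocab)}
    try:
        idx = [col[w] for w in tok.vocab]
    except KeyError as exc:
        raise ValueError(f"term {exc} not in the generator vocabulary") from exc
    phi = truth.phi_true[:, idx]
    phi = phi / phi.sum(axis=1, keepdims=True)
    rows = [int(d) - 1 for d in tok.doc_ids]
    theta = truth.theta_true[rows]
    K = truth.phi_true.shape[0]
    return TopicModel(K=K, alpha=np.nan, beta=np.nan, phi=phi, theta=theta,
                      z=[], n_kw=np.zeros((K, len(idx)), dtype=np.int64),
                      n_jk=np.zeros((len(rows), K), dtype=np.int64),
                      loglik_trace=np.zeros(1),
                      z_marginal=np.zeros((0, K)), seed=-1)
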