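"""Topic Significance Ranking (TSR).

Fitted topics are not equally meaningful: a topic may be an artifact that
spreads its probability mass evenly over the vocabulary, mirrors the corpus
word marginal, or touches every document weakly. TSR scores each topic by
its distance from three junk benchmarks and combines the scores through a
four-phase weighted-combination strategy:

1. Raw distances. Each topic is compared to the three benchmarks —
   W-Uniform (uniform over the vocabulary) and W-Vacuous (the empirical
   corpus word marginal) in word space against the topic's phi row, and
   D-BGround (uniform over documents) in document space against the topic's
   normalized theta column — under three distance metrics: KL divergence,
   one-minus-Pearson-correlation (COR), and cosine dissimilarity (COS).
2. Standardization, two ways. "Total" standardization rescales each score by
   the share of the other topics' total, C'1_k = C_k (T - C_k) / T with
   T = sum_j C_j; "range" standardization is min-max, C'2 = (C - min) /
   (max - min).
3. Intra-criterion combination: under each criterion the three metric scores
   are averaged (uniform metric weights), giving S1 (from total
   standardization) and S2 (from range standardization) per criterion.
4. Inter-criterion combination: S_hat_k = S1_k^b (psi_u S1_k^u +
   psi_v S1_k^v) weights the uniformity/vacuousness scores by the background
   score; Psi_hat_k = Psi_u S2_k^u + Psi_v S2_k^v + Psi_b S2_k^b; the final
   significance is TSR_k = Psi_hat_k * S_hat_k. Larger distance from junk
   means larger TSR, so rank 1 is the most significant topic.

Temporal ranking fixes the topics from the global model and recomputes TSR
on each year-period's sub-corpus (theta rows restricted to the period's
documents, benchmarks rebuilt from the period's tokens), yielding a
topic-by-period rank trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lda import TopicModel
from .preprocess import Tokenized

logger = logging.getLogger(__name__)

EPS = 1e-12
METRICS = ("KL", "COR", "COS")
CRITERIA = ("U", "V", "B")

#: year periods used by default for temporal ranking
DEFAULT_PERIODS = ((2013, 2015), (2016, 2018), (2019, 2022))


@dataclass(frozen=True)
class TsrWeights:
    """Inner (psi_u + psi_v = 1) and outer (Psi_* summing to 1) weights."""

    psi_u: float = 0.5
    psi_v: float = 0.5
    Psi_u: float = 1.0 / 3.0
    Psi_v: float = 1.0 / 3.0
    Psi_b: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.psi_u, self.psi_v, self.Psi_u, self.Psi_v, self.Psi_b) < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.psi_u + self.psi_v - 1.0) > 1e-9:
            raise ValueError("psi_u + psi_v must equal 1")
        if abs(self.Psi_u + self.Psi_v + self.Psi_b - 1.0) > 1e-9:
            raise ValueError("Psi_u + Psi_v + Psi_b must equal 1")


@dataclass(frozen=True)
class JunkBenchmark:
    kind: str      # W-Uniform | W-Vacuous | D-BGround
    space: str     # "word" | "document"
    dist: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.dist.sum() - 1.0) > 1e-9 or (self.dist < 0).any():
            raise ValueError(f"{self.kind}: dist is not a probability vector")


@dataclass
class TsrTable:
    """Full per-topic TSR decomposition.

    ``raw[k, m, c]`` is topic k's distance under metric m (KL, COR, COS) to
    criterion c's benchmark (U, V, B); the remaining arrays follow the
    four-phase chain. ``rank[k]`` is 1 for the most significant topic.
    """

    raw: np.ndarray        # K x 3 x 3
    std_total: np.ndarray  # K x 3 x 3
    std_range: np.ndarray  # K x 3 x 3
    S1: np.ndarray         # K x 3 criteria
    S2: np.ndarray         # K x 3 criteria
    S_hat: np.ndarray      # K
    psi_hat: np.ndarray    # K
    tsr: np.ndarray        # K
    rank: np.ndarray       # K, permutation of 1..K

    @property
    def K(self) -> int:
        return len(self.tsr)

    def to_frame(self) -> pd.DataFrame:
        cols = {"topic": np.arange(self.K)}
        for mi, m in enumerate(METRICS):
            for ci, c in enumerate(CRITERIA):
                cols[f"raw_{m}_{c}"] = self.raw[:, mi, ci]
        for ci, c in enumerate(CRITERIA):
            cols[f"S1_{c}"] = self.S1[:, ci]
            cols[f"S2_{c}"] = self.S2[:, ci]
        cols["S_hat"] = self.S_hat
        cols["psi_hat"] = self.psi_hat
        cols["tsr"] = self.tsr
        cols["rank"] = self.rank
        return pd.DataFrame(cols)


def benchmarks(model: TopicModel,
               corpus: Tokenized) -> dict[str, JunkBenchmark]:
    """The three junk references for a fitted model on its corpus."""
    V = corpus.V
    counts = corpus.word_counts().astype(float)
    uniform = JunkBenchmark("W-Uniform", "word", np.full(V, 1.0 / V))
    vacuous = JunkBenchmark("W-Vacuous", "word", counts / counts.sum())
    bground = JunkBenchmark("D-BGround", "document",
                            np.full(model.M, 1.0 / model.M))
    return {"U": uniform, "V": vacuous, "B": bground}


def distance(p: np.ndarray, q: np.ndarray, metric: str) -> float:
    """Distance between two probability vectors under KL, COR, or COS.

    KL uses epsilon smoothing on q with the 0·log 0 = 0 convention; COR is
    1 - Pearson correlation (a zero-variance vector has its correlation
    defined as 0, so COR = 1); COS is cosine dissimilarity.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries")
    if metric == "KL":
        mask = p > 0
        val = float(np.sum(p[mask] * np.log(p[mask] / (q[mask] + EPS))))
    elif metric == "COR":
        if p.std() < EPS or q.std() < EPS:
            return 1.0
        val = 1.0 - float(np.corrcoef(p, q)[0, 1])
    elif metric == "COS":
        denom = np.linalg.norm(p) * np.linalg.norm(q)
        if denom < EPS:
            return 1.0
        val = 1.0 - float(p @ q / denom)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # self-distances can land at -1e-16; distances are nonnegative by definition
    return max(val, 0.0)


def standardize_total(scores: np.ndarray, mode: str = "printed") -> np.ndarray:
    """Recalibrate scores against the cross-topic total.

    ``printed`` mode is C'_k = C_k (T - C_k) / T — each score times the
    complementary share of the total. ``share`` mode is the plain
    proportional C_k / T, provided for sensitivity analysis.
    """
    s = np.asarray(scores, dtype=float)
    if (s < 0).any():
        raise ValueError("scores must be nonnegative")
    T = s.sum()
    if T <= 0:
        logger.warning("standardize_total: all scores zero")
        return np.zeros_like(s)
    if mode == "printed":
        return s * (T - s) / T
    if mode == "share":
        return s / T
    raise ValueError(f"unknown mode {mode!r}")


def standardize_range(scores: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all 0.5."""
    s = np.asarray(scores, dtype=float)
    lo, hi = s.min(), s.max()
    if hi - lo < EPS:
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def intra_criterion(std_scores: dict[str, np.ndarray]) -> np.ndarray:
    """Average the three metric scores within one criterion."""
    missing = [m for m in METRICS if m not in std_scores]
    if missing:
        raise ValueError(f"missing metrics: {missing}")
    return (std_scores["KL"] + std_scores["COR"] + std_scores["COS"]) / 3.0


def combine(S1: np.ndarray, S2: np.ndarray,
            weights: TsrWeights = TsrWeights()
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inter-criterion combination: returns (S_hat, psi_hat, tsr).

    ``S1``/``S2`` are K x 3 arrays with columns ordered (U, V, B).
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape or S1.ndim != 2 or S1.shape[1] != 3:
        raise ValueError("S1 and S2 must both be K x 3 (U, V, B)")
    s_hat = S1[:, 2] * (weights.psi_u * S1[:, 0] + weights.psi_v * S1[:, 1])
    psi_hat = (weights.Psi_u * S2[:, 0] + weights.Psi_v * S2[:, 1]
               + weights.Psi_b * S2[:, 2])
    return s_hat, psi_hat, psi_hat * s_hat


def _ranks(tsr: np.ndarray) -> np.ndarray:
    """1 = largest TSR; ties broken by lower topic index."""
    order = np.lexsort((np.arange(len(tsr)), -tsr))
    rank = np.empty(len(tsr), dtype=np.int64)
    rank[order] = np.arange(1, len(tsr) + 1)
    return rank


def score_raw_table(raw: np.ndarray, weights: TsrWeights = TsrWeights(),
                    total_mode: str = "printed") -> TsrTable:
    """Run the phase 2-4 chain on a K x metrics x criteria raw-distance table."""
    K = raw.shape[0]
    std_total = np.empty_like(raw)
    std_range = np.empty_like(raw)
    for mi in range(len(METRICS)):
        for ci in range(len(CRITERIA)):
            std_total[:, mi, ci] = standardize_total(raw[:, mi, ci], total_mode)
            std_range[:, mi, ci] = standardize_range(raw[:, mi, ci])
    S1 = std_total.mean(axis=1)   # average over metrics -> K x criteria
    S2 = std_range.mean(axis=1)
    s_hat, psi_hat, tsr_vals = combine(S1, S2, weights)
    return TsrTable(raw=raw, std_total=std_total, std_range=std_range,
                    S1=S1, S2=S2, S_hat=s_hat, psi_hat=psi_hat,
                    tsr=tsr_vals, rank=_ranks(tsr_vals))


def raw_distances(model: TopicModel, corpus: Tokenized,
                  doc_index: np.ndarray | None = None) -> np.ndarray:
    """K x metric x criterion distances of each topic to each benchmark.

    ``doc_index`` restricts the document-space criterion (and the vacuous
    benchmark) to a sub-corpus, as temporal ranking requires.
    """
    if doc_index is None:
        doc_index = np.arange(corpus.M)
    sub_counts = np.zeros(corpus.V, dtype=float)
    for j in doc_index:
        np.add.at(sub_counts, corpus.doc_tokens[j], 1)
    n_docs = len(doc_index)
    bench = {
        "U": np.full(corpus.V, 1.0 / corpus.V),
        "V": sub_counts / sub_counts.sum(),
        "B": np.full(n_docs, 1.0 / n_docs),
    }
    theta_sub = model.theta[doc_index]
    raw = np.empty((model.K, len(METRICS), len(CRITERIA)))
    for k in range(model.K):
        doc_dist = theta_sub[:, k] / theta_sub[:, k].sum()
        for mi, m in enumerate(METRICS):
            for ci, c in enumerate(CRITERIA):
                topic_side = model.phi[k] if c in ("U", "V") else doc_dist
                raw[k, mi, ci] = distance(topic_side, bench[c], m)
    return raw


def rank_topics(model: TopicModel, corpus: Tokenized,
                weights: TsrWeights = TsrWeights(),
                total_mode: str = "printed") -> TsrTable:
    """Full four-phase TSR of a fitted model's topics."""
    return score_raw_table(raw_distances(model, corpus), weights, total_mode)


def temporal_tsr(model: TopicModel, corpus: Tokenized,
                 periods=DEFAULT_PERIODS,
                 weights: TsrWeights = TsrWeights(),
                 total_mode: str = "printed"
                 ) -> tuple[dict[tuple[int, int], TsrTable], pd.DataFrame]:
    """TSR per year period with topics fixed from the global model.

    Returns the per-period tables and a topic x period rank matrix (the
    rank-trajectory data). Periods must be disjoint; a period with no
    documents is an error.
    """
    periods = [tuple(p) for p in periods]
    for i, (a0, a1) in enumerate(periods):
        if a0 > a1:
            raise ValueError(f"period {a0}-{a1} reversed")
        for b0, b1 in periods[i + 1:]:
            if a0 <= b1 and b0 <= a1:
                raise ValueError(f"periods {a0}-{a1} and {b0}-{b1} overlap")
    years = np.asarray(corpus.years)
    tables: dict[tuple[int, int], TsrTable] = {}
    rank_cols = {}
    for y0, y1 in periods:
        idx = np.flatnonzero((years >= y0) & (years <= y1))
        if idx.size == 0:
            raise ValueError(f"no documents in period {y0}-{y1}")
        table = score_raw_table(raw_distances(model, corpus, idx),
                                weights, total_mode)
        tables[(y0, y1)] = table
        rank_cols[f"{y0}-{y1}"] = table.rank
    trajectory = pd.DataFrame(rank_cols, index=pd.Index(
        np.arange(model.K), name="topic"))
    return tables, trajectory
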