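"""Metrics for choosing the number of topics K.

Four statistics computed over a grid of candidate K, following the metric
authors' published definitions:

* ``arun2010`` (minimize): symmetric KL divergence between the L1-normalized
  singular-value spectrum of phi and the L1-normalized topic mass vector
  doc_lengths · theta.
* ``caojuan2009`` (minimize): mean pairwise cosine similarity between
  topic-word rows — low values mean well-separated topics.
* ``deveaud2014`` (maximize): mean pairwise symmetrized KL divergence
  between topic-word rows.
* ``griffiths2004`` (maximize): harmonic-mean estimator of the marginal
  log likelihood log P(W|K) from post-burn-in likelihood samples.

The report never auto-commits a K: the per-metric optima are advisory and
the final choice belongs to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .lda import TopicModel, fit
from .preprocess import Tokenized

EPS = 1e-12


@dataclass
class SelectionReport:
    k_grid: list[int]
    arun2010: list[float]
    caojuan2009: list[float]
    deveaud2014: list[float]
    griffiths2004: list[float]

    def recommended(self) -> dict[str, int]:
        """Per-metric optimal K (min for Arun/CaoJuan, max for the others)."""
        g = np.asarray(self.k_grid)
        return {
            "arun2010": int(g[np.argmin(self.arun2010)]),
            "caojuan2009": int(g[np.argmin(self.caojuan2009)]),
            "deveaud2014": int(g[np.argmax(self.deveaud2014)]),
            "griffiths2004": int(g[np.argmax(self.griffiths2004)]),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "k": self.k_grid, "arun2010": self.arun2010,
            "caojuan2009": self.caojuan2009, "deveaud2014": self.deveaud2014,
            "griffiths2004": self.griffiths2004,
        })


def _sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    p = p + EPS
    q = q + EPS
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def caojuan2009(model: TopicModel) -> float:
    """Mean cosine similarity over all topic-row pairs (lower is better)."""
    if model.K < 2:
        raise ValueError("caojuan2009 requires K >= 2")
    phi = model.phi
    norms = np.linalg.norm(phi, axis=1)
    sim = (phi @ phi.T) / np.outer(norms, norms)
    iu = np.triu_indices(model.K, k=1)
    return float(sim[iu].mean())


def deveaud2014(model: TopicModel) -> float:
    """Mean symmetrized KL divergence over topic-row pairs (higher is better)."""
    if model.K < 2:
        raise ValueError("deveaud2014 requires K >= 2")
    phi = model.phi + EPS
    logphi = np.log(phi)
    total = 0.0
    n = 0
    for i in range(model.K):
        for j in range(i + 1, model.K):
            kl_ij = np.sum(phi[i] * (logphi[i] - logphi[j]))
            kl_ji = np.sum(phi[j] * (logphi[j] - logphi[i]))
            total += 0.5 * (kl_ij + kl_ji)
            n += 1
    return float(total / n)


def arun2010(model: TopicModel, doc_lengths: np.ndarray) -> float:
    """Divergence between singular-value and topic-mass spectra (lower is better)."""
    sv = np.linalg.svd(model.phi, compute_uv=False)[: model.K]
    p = sv / sv.sum()
    mass = np.asarray(doc_lengths, dtype=float) @ model.theta
    q = mass / mass.sum()
    # both spectra sorted descending, as in the original formulation
    return _sym_kl(np.sort(p)[::-1], np.sort(q)[::-1])


def griffiths2004(loglik_samples: np.ndarray) -> float:
    """Harmonic-mean estimate of log P(W|K), computed in log space."""
    ll = np.asarray(loglik_samples, dtype=float)
    if ll.size == 0:
        raise ValueError("need at least one post-burn-in sample")
    return float(-(logsumexp(-ll) - np.log(ll.size)))


def select_k(corpus: Tokenized, k_grid: list[int], alpha: float | None = None,
             beta: float = 0.1, n_iter: int = 300, burn_in: int = 150,
             seed: int = 0, n_restarts: int = 1) -> SelectionReport:
    """Fit one model per candidate K (seed policy: seed + K) and score all metrics."""
    if not k_grid:
        raise ValueError("empty k_grid")
    if min(k_grid) < 2:
        raise ValueError("k_grid values must be >= 2")
    rows = {m: [] for m in ("arun2010", "caojuan2009", "deveaud2014",
                            "griffiths2004")}
    lengths = corpus.N_j
    for K in k_grid:
        model = fit(corpus, K=K, alpha=alpha, beta=beta, n_iter=n_iter,
                    burn_in=burn_in, seed=seed + K, n_restarts=n_restarts)
        rows["arun2010"].append(arun2010(model, lengths))
        rows["caojuan2009"].append(caojuan2009(model))
        rows["deveaud2014"].append(deveaud2014(model))
        rows["griffiths2004"].append(griffiths2004(model.loglik_trace))
    return SelectionReport(k_grid=list(k_grid), **rows)
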