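"""Latent Dirichlet Allocation fitted by collapsed Gibbs sampling.

The sampler integrates out the topic-word distributions phi and the
document-topic distributions theta and resamples each token's topic
assignment z from the count-based conditional

    p(z = k | rest)  ∝  (n_kw + beta) / (n_k + V beta) · (n_jk + alpha),

where the n counts exclude the token being resampled. Point estimates of
phi and theta are posterior means from the final Gibbs state:

    phi[k, w]  = (n_kw + beta) / (n_k + V beta)
    theta[j, k] = (n_jk + alpha) / (N_j + K alpha)

Hyperparameters are symmetric (defaults alpha = 50/K, beta = 0.1, the
common practice for literature-sized corpora). Runs are single-chain and
deterministic for a fixed seed. The per-iteration complete-data log
likelihood log P(W | Z, beta) + log P(Z | alpha) is recorded after burn-in
for the harmonic-mean marginal-likelihood estimator used in K selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .preprocess import Tokenized


@dataclass
class TopicModel:
    """Fitted LDA state."""

    K: int
    alpha: float
    beta: float
    phi: np.ndarray          # K x V, row-stochastic, strictly positive
    theta: np.ndarray        # M x K, row-stochastic, strictly positive
    z: list[np.ndarray]      # per-document token assignments
    n_kw: np.ndarray         # K x V topic-word counts
    n_jk: np.ndarray         # M x K document-topic counts
    loglik_trace: np.ndarray  # complete-data log likelihood per kept iteration
    z_marginal: np.ndarray   # total-tokens x K post-burn-in assignment frequencies
    seed: int
    coassign: np.ndarray | None = None  # pairwise P(z_s = z_t), upper triangle

    @property
    def V(self) -> int:
        return self.phi.shape[1]

    @property
    def M(self) -> int:
        return self.theta.shape[0]

    def dominant_topic(self) -> np.ndarray:
        """Per-document argmax of theta; ties go to the lower topic index."""
        return np.argmax(self.theta, axis=1)

    def save(self, prefix: str, vocab: list[str] | None = None) -> None:
        """Write phi/theta as TSV plus a JSON sidecar of run metadata."""
        import pandas as pd

        cols = vocab if vocab is not None else [f"w{i}" for i in range(self.V)]
        pd.DataFrame(self.phi, columns=cols).to_csv(
            f"{prefix}.phi.tsv", sep="\t", index_label="topic")
        pd.DataFrame(self.theta,
                     columns=[f"topic{k}" for k in range(self.K)]).to_csv(
            f"{prefix}.theta.tsv", sep="\t", index_label="doc")
        meta = {"K": self.K, "alpha": self.alpha, "beta": self.beta,
                "seed": self.seed, "iterations": int(len(self.loglik_trace))}
        with open(f"{prefix}.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)


@njit(cache=False)
def _gibbs(doc_of, word_of, z, n_kw, n_k, n_jk, n_j, K, V, alpha, beta,
           n_iter, burn_in, seed, ll_trace, z_marg, coassign,
           track_coassign):  # pragma: no cover - jit
    np.random.seed(seed)
    T = word_of.shape[0]
    M = n_jk.shape[0]
    probs = np.empty(K)
    for it in range(n_iter):
        for t in range(T):
            j = doc_of[t]
            w = word_of[t]
            k_old = z[t]
            n_kw[k_old, w] -= 1
            n_k[k_old] -= 1
            n_jk[j, k_old] -= 1
            total = 0.0
            for k in range(K):
                p = ((n_kw[k, w] + beta) / (n_k[k] + V * beta)
                     * (n_jk[j, k] + alpha))
                total += p
                probs[k] = total
            u = np.random.random() * total
            k_new = 0
            while probs[k_new] < u:
                k_new += 1
            z[t] = k_new
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
            n_jk[j, k_new] += 1
        if it >= burn_in:
            ll = 0.0
            for k in range(K):
                ll += math.lgamma(V * beta) - V * math.lgamma(beta)
                ll -= math.lgamma(n_k[k] + V * beta)
                for w in range(V):
                    if n_kw[k, w] > 0:
                        ll += math.lgamma(n_kw[k, w] + beta)
                    else:
                        ll += math.lgamma(beta)
            for j in range(M):
                ll += math.lgamma(K * alpha) - K * math.lgamma(alpha)
                ll -= math.lgamma(n_j[j] + K * alpha)
                for k in range(K):
                    ll += math.lgamma(n_jk[j, k] + alpha)
            ll_trace[it - burn_in] = ll
            for t in range(T):
                z_marg[t, z[t]] += 1.0
            if track_coassign:
                for t1 in range(T):
                    for t2 in range(t1 + 1, T):
                        if z[t1] == z[t2]:
                            coassign[t1, t2] += 1.0


def fit(corpus: Tokenized, K: int, alpha: float | None = None,
        beta: float = 0.1, n_iter: int = 300, burn_in: int = 150,
        seed: int = 0, n_restarts: int = 1,
        track_coassign: bool = False) -> TopicModel:
    """Fit LDA with K topics by collapsed Gibbs sampling.

    ``alpha`` defaults to 50/K. ``n_iter`` total sweeps, the first
    ``burn_in`` discarded from the likelihood trace and the assignment
    marginals; phi/theta come from the final state.

    ``track_coassign`` additionally accumulates the posterior pairwise
    co-assignment frequencies P(z_s = z_t) (upper triangle), the
    label-permutation-invariant summary used to compare against exact
    posterior enumeration on tiny corpora; it is quadratic in corpus size,
    so leave it off except for such fixtures.

    ``n_restarts`` > 1 runs that many independent chains (seeds offset by
    fixed strides) and keeps the one with the highest final complete-data
    log likelihood: a single chain occasionally freezes in a mode where two
    topics are merged and another split, and the likelihood gap between
    such modes and the dominant one is large, so best-of-restarts reliably
    discards them. The default stays single-chain.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best = None
    for r in range(n_restarts):
        model = _fit_single(corpus, K, alpha, beta, n_iter, burn_in,
                            seed + 7919 * r, track_coassign)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    return best


def _fit_single(corpus: Tokenized, K: int, alpha: float | None,
                beta: float, n_iter: int, burn_in: int, seed: int,
                track_coassign: bool = False) -> TopicModel:
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if not 0 <= burn_in < n_iter:
        raise ValueError("need n_iter > burn_in >= 0")
    if corpus.M == 0:
        raise ValueError("empty corpus")
    if alpha is None:
        alpha = 50.0 / K
    V = corpus.V
    M = corpus.M
    doc_of = np.concatenate([np.full(len(t), j, dtype=np.int64)
                             for j, t in enumerate(corpus.doc_tokens)])
    word_of = np.concatenate(corpus.doc_tokens).astype(np.int64)
    T = word_of.shape[0]
    if K > T:
        raise ValueError(f"K={K} exceeds total token count {T}")

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=T).astype(np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    n_jk = np.zeros((M, K), dtype=np.int64)
    n_j = corpus.N_j
    np.add.at(n_kw, (z, word_of), 1)
    np.add.at(n_k, z, 1)
    np.add.at(n_jk, (doc_of, z), 1)

    n_kept = n_iter - burn_in
    ll_trace = np.zeros(n_kept)
    z_marg = np.zeros((T, K))
    coassign = np.zeros((T, T)) if track_coassign else np.zeros((1, 1))
    # numba's np.random.seed needs a 32-bit unsigned value
    _gibbs(doc_of, word_of, z, n_kw, n_k, n_jk, n_j, K, V,
           float(alpha), float(beta), n_iter, burn_in,
           int(seed) % (2**32), ll_trace, z_marg, coassign, track_coassign)
    z_marg /= n_kept
    coassign /= n_kept

    phi = (n_kw + beta) / (n_k + V * beta)[:, None]
    theta = (n_jk + alpha) / (n_j + K * alpha)[:, None]
    bounds = np.cumsum([0] + [len(t) for t in corpus.doc_tokens])
    z_docs = [z[bounds[j]:bounds[j + 1]].copy() for j in range(M)]
    return TopicModel(K=K, alpha=float(alpha), beta=float(beta), phi=phi,
                      theta=theta, z=z_docs, n_kw=n_kw, n_jk=n_jk,
                      loglik_trace=ll_trace, z_marginal=z_marg, seed=seed,
                      coassign=coassign if track_coassign else None)


def loglik(model: TopicModel, corpus: Tokenized) -> float:
    """Complete-data log likelihood log P(W|Z, beta) + log P(Z|alpha).

    Recomputed from the count tables via the collapsed Dirichlet-multinomial
    closed form; matches the trace recorded during sampling.
    """
    from scipy.special import gammaln

    K, V = model.K, model.V
    a, b = model.alpha, model.beta
    n_k = model.n_kw.sum(axis=1)
    n_j = model.n_jk.sum(axis=1)
    ll = K * (gammaln(V * b) - V * gammaln(b))
    ll += gammaln(model.n_kw + b).sum() - gammaln(n_k + V * b).sum()
    ll += model.M * (gammaln(K * a) - K * gammaln(a))
    ll += gammaln(model.n_jk + a).sum() - gammaln(n_j + K * a).sum()
    return float(ll)


def rebuild_counts(model: TopicModel,
                   corpus: Tokenized) -> tuple[np.ndarray, np.ndarray]:
    """Recompute the count tables from z (consistency check)."""
    n_kw = np.zeros((model.K, model.V), dtype=np.int64)
    n_jk = np.zeros((model.M, model.K), dtype=np.int64)
    for j, (toks, zj) in enumerate(zip(corpus.doc_tokens, model.z)):
        np.add.at(n_kw, (zj, toks), 1)
        np.add.at(n_jk[j], zj, 1)
    return n_kw, n_jk


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray) -> np.ndarray:
    """Greedy matching of estimated to true topics by total-variation distance.

    Returns ``perm`` with ``perm[i] = j`` meaning estimated topic i matches
    true topic j; repeatedly takes the globally closest unmatched pair.
    """
    K = phi_est.shape[0]
    tv = 0.5 * np.abs(phi_est[:, None, :] - phi_true[None, :, :]).sum(axis=2)
    perm = np.full(K, -1, dtype=np.int64)
    used_e, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(tv, axis=None), tv.shape))[0]
    for i, j in order:
        if i in used_e or j in used_t:
            continue
        perm[i] = j
        used_e.add(int(i))
        used_t.add(int(j))
        if len(used_e) == K:
            break
    return perm
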