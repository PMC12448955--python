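"""Explore stage: word-correlation edges and LDA topic modelling.

Two complementary views of theme structure in a necropsy corpus:

* **Word correlations** — the phi coefficient (Pearson correlation of the
  binary document-presence indicators) for every pair of sufficiently
  common terms.  Clusters of strongly correlated words ("freeze", "thaw",
  "artifact") hint at recurring concepts regardless of word position.
* **Topic modelling** — latent Dirichlet allocation fitted by collapsed
  Gibbs sampling.  Documents are mixtures over k topics, topics are
  distributions over the vocabulary; the number of topics k is the only
  required input, and the word cloud assigns each displayed word to its
  argmax topic.

The Gibbs sampler is implemented here (rather than delegated) so that its
seeding, per-sweep count conservation and final state are all directly
inspectable and testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigurationError, EmptyCorpusError
from .text_prep import DocumentTermMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# word correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationEdge:
    """One unordered term pair with its phi coefficient.

    ``contingency`` is the 2×2 document co-occurrence table
    ``(n11, n10, n01, n00)``: both present, only a, only b, neither.
    """

    term_a: str
    term_b: str
    phi: float
    contingency: tuple[int, int, int, int]


def phi_coefficient(n11: int, n10: int, n01: int, n00: int) -> float:
    """Phi from a 2×2 table; NaN when any marginal is zero (undefined)."""
    denom = math.sqrt(
        float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    if denom == 0.0:
        return math.nan
    return (n11 * n00 - n10 * n01) / denom


def word_correlations(
    dtm: DocumentTermMatrix,
    min_count: int = 5,
    min_corr: float = 0.0,
) -> list[CorrelationEdge]:
    """Pairwise phi over presence/absence indicators.

    Only terms occurring in at least *min_count* documents enter (hapax
    pairs otherwise produce spurious perfect correlations); only edges with
    ``phi >= min_corr`` are returned, one per unordered pair with
    ``term_a < term_b``.  Pairs with an undefined phi (a zero marginal,
    e.g. a term present in every document) are skipped.
    """
    if not 0.0 <= min_corr <= 1.0:
        raise ConfigurationError("min_corr must lie in [0, 1]")
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    eligible = np.flatnonzero(dtm.doc_freq >= min_count)
    if eligible.size == 0:
        raise EmptyCorpusError(
            f"no eligible terms: none occur in >= {min_count} documents"
        )
    n_docs = dtm.n_docs
    binary = (dtm.counts[:, eligible] > 0).astype(np.int64)
    co = (binary.T @ binary).toarray()  # n11 for every pair
    present = np.asarray(binary.sum(axis=0)).ravel()
    terms = [dtm.vocabulary[j] for j in eligible]

    edges = []
    for a in range(len(terms)):
        for b in range(a + 1, len(terms)):
            n11 = int(co[a, b])
            n10 = int(present[a]) - n11
            n01 = int(present[b]) - n11
            n00 = n_docs - n11 - n10 - n01
            phi = phi_coefficient(n11, n10, n01, n00)
            if math.isnan(phi) or phi < min_corr:
                continue
            term_a, term_b = sorted((terms[a], terms[b]))
            edges.append(
                CorrelationEdge(term_a, term_b, phi, (n11, n10, n01, n00))
            )
    return edges


# ---------------------------------------------------------------------------
# latent Dirichlet allocation, collapsed Gibbs
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gibbs_sweep(doc_of, word_of, z, ndk, nkw, nk, alpha, beta, uniforms, cum):
    """One full Gibbs sweep over all token instances, in place."""
    n_topics, n_terms = nkw.shape
    for i in range(doc_of.size):
        d = doc_of[i]
        w = word_of[i]
        k = z[i]
        ndk[d, k] -= 1
        nkw[k, w] -= 1
        nk[k] -= 1
        total = 0.0
        for kk in range(n_topics):
            p = (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + n_terms * beta)
            total += p
            cum[kk] = total
        u = uniforms[i] * total
        k = 0
        while cum[k] < u and k < n_topics - 1:
            k += 1
        z[i] = k
        ndk[d, k] += 1
        nkw[k, w] += 1
        nk[k] += 1


@dataclass(frozen=True)
class TopicModel:
    """Fitted LDA state.

    ``phi_topic_word`` (k×V) and ``theta_doc_topic`` (N×k) are estimated
    from the final sampler state with Dirichlet-prior smoothing; ``z`` holds
    the final per-token topic assignments.
    """

    k: int
    alpha: float
    beta: float
    phi_topic_word: np.ndarray
    theta_doc_topic: np.ndarray
    z: np.ndarray
    doc_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]
    seed: int
    iterations: int


class GibbsLda:
    """Latent Dirichlet allocation fitted by collapsed Gibbs sampling.

    A scikit-learn-style estimator: construct with hyperparameters, call
    :meth:`fit` on a :class:`~necromine.text_prep.DocumentTermMatrix`, read
    the fitted distributions from ``components_`` and ``doc_topic_``.

    Parameters
    ----------
    n_topics:
        Number of topics k (>= 2) — the only input the method requires.
    alpha:
        Symmetric Dirichlet concentration over document-topic mixtures.
        Default ``50 / k``, a common heuristic that keeps the expected
        total prior mass per document constant as k varies.
    beta:
        Symmetric Dirichlet concentration over topic-word distributions
        (default 0.1; smaller values favour sparser topics).
    n_iter:
        Gibbs sweeps over all tokens (default 1000); the estimate is taken
        from the last sample, no averaging across sweeps.
    random_state:
        Seed; the same seed, matrix and parameters reproduce the token
        assignments bitwise.
    check_conservation:
        Assert after every sweep that the sampler's count tables still sum
        to the token count (cheap; guards against state corruption).

    Attributes
    ----------
    components_ : ndarray of shape (n_topics, n_terms)
        Topic-word distributions, rows summing to 1.
    doc_topic_ : ndarray of shape (n_docs, n_topics)
        Document-topic mixtures, rows summing to 1.
    z_ : ndarray
        Final topic assignment of every token instance.
    doc_ids_, vocabulary_ : labels of the fitted axes (documents with zero
        tokens are excluded from ``doc_ids_`` with a warning).
    """

    def __init__(
        self,
        n_topics: int = 2,
        alpha: float | None = None,
        beta: float = 0.1,
        n_iter: int = 1000,
        random_state: int = 0,
        check_conservation: bool = True,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.random_state = random_state
        self.check_conservation = check_conservation

    # minimal sklearn protocol -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_topics": self.n_topics,
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iter": self.n_iter,
            "random_state": self.random_state,
            "check_conservation": self.check_conservation,
        }

    def set_params(self, **params) -> "GibbsLda":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # fitting -------------------------------------------------------------
    def fit(self, dtm: DocumentTermMatrix) -> "GibbsLda":
        if self.n_topics < 2:
            raise ConfigurationError("n_topics must be >= 2")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        if self.n_topics > dtm.n_terms:
            raise ConfigurationError(
                f"n_topics={self.n_topics} exceeds vocabulary size {dtm.n_terms}"
            )
        alpha = (50.0 / self.n_topics) if self.alpha is None else float(self.alpha)
        beta = float(self.beta)

        dense = dtm.toarray()
        row_tokens = dense.sum(axis=1)
        keep = row_tokens > 0
        dropped = [i for i, ok in enumerate(keep) if not ok]
        if dropped:
            logger.warning(
                "excluding %d document(s) with zero tokens after stop-word "
                "removal: %s", len(dropped),
                ", ".join(dtm.doc_ids[i] for i in dropped),
            )
        dense = dense[keep]
        doc_ids = tuple(d for d, ok in zip(dtm.doc_ids, keep) if ok)
        if dense.shape[0] == 0:
            raise EmptyCorpusError("no documents with tokens to model")

        docs, words = np.nonzero(dense)
        reps = dense[docs, words]
        doc_of = np.repeat(docs, reps).astype(np.int64)
        word_of = np.repeat(words, reps).astype(np.int64)
        n_tokens = doc_of.size
        n_docs, n_terms = dense.shape
        k = self.n_topics

        rng = np.random.Generator(np.random.PCG64(self.random_state))
        z = rng.integers(0, k, size=n_tokens).astype(np.int64)
        ndk = np.zeros((n_docs, k), dtype=np.int64)
        nkw = np.zeros((k, n_terms), dtype=np.int64)
        nk = np.zeros(k, dtype=np.int64)
        np.add.at(ndk, (doc_of, z), 1)
        np.add.at(nkw, (z, word_of), 1)
        np.add.at(nk, z, 1)

        cum = np.empty(k, dtype=np.float64)
        for _ in range(self.n_iter):
            uniforms = rng.random(n_tokens)
            _gibbs_sweep(doc_of, word_of, z, ndk, nkw, nk, alpha, beta, uniforms, cum)
            if self.check_conservation:
                if int(nk.sum()) != n_tokens or int(nkw.sum()) != n_tokens:
                    raise RuntimeError("Gibbs sampler lost tokens mid-sweep")

        phi = (nkw + beta) / (nk[:, None] + n_terms * beta)
        theta = (ndk + alpha) / (row_tokens[keep][:, None] + k * alpha)
        self.components_ = phi
        self.doc_topic_ = theta
        self.z_ = z
        self.doc_ids_ = doc_ids
        self.vocabulary_ = dtm.vocabulary
        self.alpha_ = alpha
        self.beta_ = beta
        return self

    def to_topic_model(self) -> TopicModel:
        return TopicModel(
            k=self.n_topics,
            alpha=self.alpha_,
            beta=self.beta_,
            phi_topic_word=self.components_,
            theta_doc_topic=self.doc_topic_,
            z=self.z_,
            doc_ids=self.doc_ids_,
            vocabulary=self.vocabulary_,
            seed=self.random_state,
            iterations=self.n_iter,
        )


def fit_lda(
    dtm: DocumentTermMatrix,
    k: int,
    alpha: float | None = None,
    beta: float = 0.1,
    iterations: int = 1000,
    seed: int = 0,
) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling; thin wrapper over :class:`GibbsLda`."""
    estimator = GibbsLda(
        n_topics=k, alpha=alpha, beta=beta, n_iter=iterations, random_state=seed
    )
    return estimator.fit(dtm).to_topic_model()


# ---------------------------------------------------------------------------
# word-cloud topic assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopicWordCloudSpec:
    """Renderable word-cloud content: top words per topic, one colour per word.

    ``top_words[t]`` lists (word, weight) pairs, weight = P(word | topic t);
    ``assigned_topic[word]`` is the topic under which the word is most
    probable, determining its colour — each rendered word belongs to exactly
    one topic even when it ranks highly under several.
    """

    top_words: tuple[tuple[tuple[str, float], ...], ...]
    assigned_topic: dict[str, int]


def topic_word_cloud(model: TopicModel, words_per_topic: int = 20) -> TopicWordCloudSpec:
    """Top-ranked words per topic with argmax-topic assignment."""
    if words_per_topic < 1:
        raise ConfigurationError("words_per_topic must be >= 1")
    vocab = np.asarray(model.vocabulary)
    assigned = model.phi_topic_word.argmax(axis=0)
    top = []
    for t in range(model.k):
        weights = model.phi_topic_word[t]
        order = np.lexsort((vocab, -weights))[:words_per_topic]
        top.append(tuple((str(vocab[j]), float(weights[j])) for j in order))
    return TopicWordCloudSpec(
        top_words=tuple(top),
        assigned_topic={str(w): int(t) for w, t in zip(vocab, assigned)},
    )
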