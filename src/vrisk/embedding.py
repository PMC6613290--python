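"""Paragraph-vector document embeddings.

Learns a fixed-length vector per admission document in an unsupervised way
(never reading outcome labels), following the paragraph-vector family of
log-bilinear models trained with negative sampling:

* distributed bag-of-words (DBOW, default): the document vector alone is
  trained to predict each word occurring in the document;
* distributed memory (DM): the document vector is averaged with the input
  vectors of the words in a sliding context window to predict the center word.

Both variants share one output (prediction) matrix over the vocabulary.
Held-out documents are embedded by gradient steps on a fresh document vector
with all word parameters frozen, so train- and test-fold documents can be
embedded identically. Training and inference are single-threaded and fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

_VARIANTS = {
    "dbow": "dbow",
    "distributed-bag-of-words": "dbow",
    "dm": "dm",
    "distributed-memory": "dm",
}


@dataclass
class EmbeddingConfig:
    """Settings of the paragraph-vector model.

    Defaults follow common literature practice for clinical text (300
    dimensions, context window 5, 20 epochs, minimum term count 5, DBOW);
    all are exposed for desk-scale runs.
    """

    dimension: int = 300
    context_window: int = 5
    epochs: int = 20
    min_term_count: int = 5
    variant: str = "distributed-bag-of-words"
    seed: int = 0
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def validate(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.min_term_count < 1:
            raise ValueError("min_term_count must be >= 1")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {sorted(_VARIANTS)}")
        if self.negative < 1:
            raise ValueError("negative must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class ParagraphVectors:
    """Paragraph-vector model with negative sampling.

    Parameters are learned by :meth:`fit` on a token-sequence corpus (which
    may be a superset of the analysis documents); vectors for any document,
    seen or unseen, come from :meth:`infer_vector` / :meth:`embed`.
    """

    def __init__(self, config: EmbeddingConfig):
        config.validate()
        self.config = config
        self.variant = _VARIANTS[config.variant]
        self.vocab_: dict[str, int] = {}
        self.counts_: np.ndarray | None = None
        self.syn0_: np.ndarray | None = None   # input word vectors (DM)
        self.syn1_: np.ndarray | None = None   # output word matrix
        self.doc_vectors_: np.ndarray | None = None
        self._noise_cdf: np.ndarray | None = None

    # -- training ------------------------------------------------------------

    def fit(self, corpus: list[list[str]]) -> "ParagraphVectors":
        """Train on a nonempty corpus of token sequences. Label-blind."""
        if not corpus:
            raise ValueError("training corpus must be nonempty")
        cfg = self.config
        counter: Counter[str] = Counter()
        for doc in corpus:
            counter.update(doc)
        vocab = sorted(t for t, c in counter.items() if c >= cfg.min_term_count)
        if not vocab:
            raise ValueError("no term reaches min_term_count; corpus too small")
        self.vocab_ = {t: i for i, t in enumerate(vocab)}
        self.counts_ = np.array([counter[t] for t in vocab], dtype=float)
        noise = self.counts_ ** 0.75
        self._noise_cdf = np.cumsum(noise / noise.sum())

        rng = np.random.default_rng(cfg.seed)
        V, d, n = len(vocab), cfg.dimension, len(corpus)
        self.syn1_ = np.zeros((V, d))
        self.syn0_ = (rng.random((V, d)) - 0.5) / d
        self.doc_vectors_ = (rng.random((n, d)) - 0.5) / d

        docs_idx = [
            np.array([self.vocab_[t] for t in doc if t in self.vocab_], dtype=np.intp)
            for doc in corpus
        ]
        for epoch in range(cfg.epochs):
            lr = cfg.alpha - (cfg.alpha - cfg.min_alpha) * epoch / max(cfg.epochs - 1, 1)
            order = rng.permutation(n)
            for j in order:
                w = docs_idx[j]
                if len(w) == 0:
                    continue
                if self.variant == "dbow":
                    self._dbow_step(self.doc_vectors_, j, w, lr, rng, update_words=True)
                else:
                    self._dm_step(self.doc_vectors_, j, w, lr, rng, update_words=True)
        return self

    def _negatives(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return np.searchsorted(self._noise_cdf, rng.random(size))

    def _dbow_step(self, docvecs, j, w, lr, rng, update_words):
        k = self.config.negative
        L = len(w)
        neg = self._negatives(L * k, rng)
        targets = np.concatenate([w, neg])
        label = np.zeros(L * (k + 1))
        label[:L] = 1.0
        d = docvecs[j]
        U = self.syn1_[targets]
        g = (label - _sigmoid(U @ d)) * lr
        grad_d = g @ U
        if update_words:
            np.add.at(self.syn1_, targets, g[:, None] * d[None, :])
        docvecs[j] = d + grad_d

    def _dm_step(self, docvecs, j, w, lr, rng, update_words):
        k = self.config.negative
        win = self.config.context_window
        L = len(w)
        d = docvecs[j]
        for i in range(L):
            lo, hi = max(0, i - win), min(L, i + win + 1)
            ctx = np.concatenate([w[lo:i], w[i + 1:hi]])
            n_in = len(ctx) + 1
            h = (d + self.syn0_[ctx].sum(axis=0)) / n_in
            targets = np.concatenate([[w[i]], self._negatives(k, rng)])
            label = np.zeros(k + 1)
            label[0] = 1.0
            U = self.syn1_[targets]
            g = (label - _sigmoid(U @ h)) * lr
            grad_h = (g @ U) / n_in
            if update_words:
                np.add.at(self.syn1_, targets, g[:, None] * h[None, :])
                np.add.at(self.syn0_, ctx, grad_h[None, :])
            d = d + grad_h
        docvecs[j] = d

    # -- inference -------------------------------------------------------------

    def infer_vector(
        self, tokens: list[str], epochs: int | None = None, seed: int | None = None
    ) -> np.ndarray:
        """Embed one token sequence with all word parameters frozen.

        A document with zero in-vocabulary tokens yields the random inference
        prior (with a warning) so the pipeline can continue.
        """
        if self.syn1_ is None:
            raise ValueError("model is not trained")
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
        vec = np.empty((1, cfg.dimension))
        vec[0] = (rng.random(cfg.dimension) - 0.5) / cfg.dimension
        w = np.array([self.vocab_[t] for t in tokens if t in self.vocab_], dtype=np.intp)
        if len(w) == 0:
            warnings.warn(
                "document has no in-vocabulary tokens; returning inference prior",
                stacklevel=2,
            )
            return vec[0].copy()
        for epoch in range(epochs):
            lr = cfg.alpha - (cfg.alpha - cfg.min_alpha) * epoch / max(epochs - 1, 1)
            if self.variant == "dbow":
                self._dbow_step(vec, 0, w, lr, rng, update_words=False)
            else:
                self._dm_step(vec, 0, w, lr, rng, update_words=False)
        return vec[0].copy()

    def embed(
        self, documents: list[list[str]], epochs: int | None = None, seed: int | None = None
    ) -> np.ndarray:
        """Infer one vector per document, order-preserving; deterministic for
        a fixed seed. Each document gets an independent sub-seed so the result
        for document i does not depend on the other documents."""
        base = self.config.seed + 1 if seed is None else seed
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = np.stack(
                [
                    self.infer_vector(doc, epochs=epochs, seed=base + 7919 * i)
                    for i, doc in enumerate(documents)
                ]
            )
        return out

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            syn0=self.syn0_,
            syn1=self.syn1_,
            doc_vectors=self.doc_vectors_,
            counts=self.counts_,
        )
        sidecar = {
            "format_version": 1,
            "config": asdict(self.config),
            "vocab": list(self.vocab_),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "ParagraphVectors":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(EmbeddingConfig(**sidecar["config"]))
        arrays = np.load(path.with_suffix(".npz"))
        model.vocab_ = {t: i for i, t in enumerate(sidecar["vocab"])}
        model.syn0_ = arrays["syn0"]
        model.syn1_ = arrays["syn1"]
        model.doc_vectors_ = arrays["doc_vectors"]
        model.counts_ = arrays["counts"]
        noise = model.counts_ ** 0.75
        model._noise_cdf = np.cumsum(noise / noise.sum())
        return model


def train_embedding(corpus: list[list[str]], config: EmbeddingConfig) -> ParagraphVectors:
    """Train a paragraph-vector model on a token-sequence corpus."""
    return ParagraphVectors(config).fit(corpus)


def embed_documents(
    model: ParagraphVectors, documents: list[list[str]], seed: int | None = None
) -> np.ndarray:
    """Infer one vector per document (rows align with the input order)."""
    return model.embed(documents, seed=seed)
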