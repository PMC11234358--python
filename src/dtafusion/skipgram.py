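"""Skip-gram token embeddings with negative sampling.

Both 1D featurizers (substructure sentences for drugs, k-mer sentences for
proteins) train the same model: given a center token, predict its context
tokens inside a symmetric window, against negatives drawn from the
unigram^0.75 distribution. Molecule- or protein-level vectors are the sum
(optionally mean) of their token vectors, so the 1D embedding is a bag of
learned substructure/k-mer semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from ._util import logger


@dataclass
class SkipGramModel:
    vocabulary: Dict[str, int]
    token_vectors: np.ndarray  # |V| x width
    window: int
    width: int
    seed: int
    counts: Dict[str, int] = field(default_factory=dict)

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        return self.token_vectors[self.vocabulary[token]]

    def embed_tokens(self, tokens: Sequence[str], aggregate: str = "sum") -> np.ndarray:
        """Aggregate token vectors into one fixed-width vector.

        Unknown tokens contribute nothing; if no token is known the result
        is the zero vector (warned, not an error).
        """
        if aggregate not in ("sum", "mean"):
            raise ValueError("aggregate must be 'sum' or 'mean'")
        known = [t for t in tokens if t in self.vocabulary]
        if not known:
            logger.warning("skip-gram embed: no known tokens; returning zero vector")
            return np.zeros(self.width)
        idx = [self.vocabulary[t] for t in known]
        vec = self.token_vectors[idx].sum(axis=0)
        if aggregate == "mean":
            vec = vec / len(idx)
        return vec


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    corpus: List[Sequence[str]],
    width: int = 100,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negatives: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
) -> SkipGramModel:
    """Train skip-gram with negative sampling (SGNS) on token sentences.

    Deterministic for a fixed seed. Sized for desk-scale corpora (10^2-10^4
    sentences); the learning rate decays linearly to ``min_lr``.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if width <= 0:
        raise ValueError("width must be positive")

    counts: Dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = {tok: i for i, tok in enumerate(sorted(counts))}
    nv = len(vocab)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((nv, width)) - 0.5) / width
    w_out = np.zeros((nv, width))

    # unigram^0.75 negative-sampling table
    freqs = np.array([counts[tok] for tok in sorted(counts)], dtype=float) ** 0.75
    neg_probs = freqs / freqs.sum()

    encoded = [np.array([vocab[t] for t in sent], dtype=np.int64) for sent in corpus]
    total_steps = max(1, epochs * sum(len(s) for s in encoded))
    step = 0
    for _epoch in range(epochs):
        for sent in encoded:
            n = len(sent)
            for pos in range(n):
                alpha = max(min_lr, lr * (1.0 - step / total_steps))
                step += 1
                center = sent[pos]
                lo, hi = max(0, pos - window), min(n, pos + window + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if ctx.size == 0:
                    continue
                neg = rng.choice(nv, size=(ctx.size, negatives), p=neg_probs)
                # one positive + `negatives` negatives per context token
                v = w_in[center]  # (width,)
                targets = np.concatenate([ctx[:, None], neg], axis=1)  # (c, 1+k)
                labels = np.zeros(targets.shape)
                labels[:, 0] = 1.0
                u = w_out[targets]  # (c, 1+k, width)
                scores = _sigmoid(u @ v)  # (c, 1+k)
                g = (scores - labels) * alpha  # (c, 1+k)
                grad_v = np.einsum("ck,ckw->w", g, u)
                np.add.at(w_out, targets, -g[:, :, None] * v)
                w_in[center] = v - grad_v
    return SkipGramModel(
        vocabulary=vocab,
        token_vectors=w_in,
        window=window,
        width=width,
        seed=seed,
        counts=counts,
    )
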