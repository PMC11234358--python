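"""Protein embeddings in three dimensions.

1D: overlapping k-mer tokens (k=3 by convention) embedded by skip-gram and
    summed per sequence.
2D: a small multi-head self-attention encoder over the residue sequence —
    softmax(Q K^T / sqrt(d)) V per head, heads concatenated and mixed, mean
    pooled. A desk-scale transformer encoder, not a large pretrained
    language model; the precomputed-embedding adapter below serves users
    who have such embeddings on disk.
3D: adapter only — structure-model embeddings are loaded from columnar
    text files (default width 1280).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._util import EmbeddingSet, derive_seed, load_embedding_file, logger
from .data_io import AMINO_ACIDS, ProteinRecord
from .drug_featurizers import FeaturizationError
from .skipgram import SkipGramModel  # noqa: F401  (re-export for 1D training)

#: truncation cap; longest benchmark kinase sequence is 2,549 residues
MAX_SEQUENCE_LENGTH = 2600

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def protein_tokenize(protein: ProteinRecord, k: int = 3) -> List[str]:
    """Overlapping k-mers in order; exactly len(sequence) - k + 1 tokens."""
    seq = protein.sequence
    if len(seq) < k:
        raise FeaturizationError(
            protein.id, f"sequence length {len(seq)} shorter than k={k}"
        )
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def protvec_embed(
    protein: ProteinRecord, model: SkipGramModel, k: int = 3, aggregate: str = "sum"
) -> np.ndarray:
    """Aggregate (sum by default) of the sequence's k-mer vectors."""
    return model.embed_tokens(protein_tokenize(protein, k=k), aggregate=aggregate)


@dataclass
class AttentionEncoderConfig:
    n_heads: int = 4
    model_width: int = 64
    n_layers: int = 2
    key_width: Optional[int] = None  # defaults to model_width // n_heads
    output_width: int = 768
    pooling: str = "mean"
    max_length: int = MAX_SEQUENCE_LENGTH

    def __post_init__(self) -> None:
        if self.model_width % self.n_heads != 0:
            raise ValueError("model_width must be divisible by n_heads")
        if self.output_width <= 0:
            raise ValueError("output_width must be positive")
        if self.pooling not in ("mean", "first-token"):
            raise ValueError("pooling must be 'mean' or 'first-token'")
        if self.key_width is None:
            self.key_width = self.model_width // self.n_heads


def init_attention_params(config: AttentionEncoderConfig, seed: int = 0) -> dict:
    """Seeded random parameters: residue embedding table, per-layer per-head
    query/key/value projections, head mixer W_o, and the output projection."""
    rng = np.random.default_rng(derive_seed(seed, "attention"))
    d, dk, nh = config.model_width, config.key_width, config.n_heads
    scale = 1.0 / np.sqrt(d)
    params = {
        "embed": rng.normal(0.0, scale, (len(AMINO_ACIDS), d)),
        "layers": [],
        "out": rng.normal(0.0, scale, (d, config.output_width)),
    }
    for _ in range(config.n_layers):
        params["layers"].append(
            {
                "wq": rng.normal(0.0, scale, (nh, d, dk)),
                "wk": rng.normal(0.0, scale, (nh, d, dk)),
                "wv": rng.normal(0.0, scale, (nh, d, dk)),
                "wo": rng.normal(0.0, scale, (nh * dk, d)),
            }
        )
    return params


def _positional_encoding(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / (10000.0 ** (2 * i / d))
    pe = np.zeros((n, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles[:, : d - d // 2])
    return pe


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_layer(x: np.ndarray, layer: dict, return_weights: bool = False):
    """One multi-head scaled dot-product attention layer.

    Per head: softmax(x W_q (x W_k)^T / sqrt(d_k)) (x W_v); head outputs are
    concatenated and mixed by W_o. Attention rows sum to one by softmax
    normalization.
    """
    dk = layer["wq"].shape[2]
    heads, weights = [], []
    for h in range(layer["wq"].shape[0]):
        q = x @ layer["wq"][h]
        k = x @ layer["wk"][h]
        v = x @ layer["wv"][h]
        att = _softmax(q @ k.T / np.sqrt(dk), axis=1)
        heads.append(att @ v)
        weights.append(att)
    out = np.concatenate(heads, axis=1) @ layer["wo"]
    if return_weights:
        return out, np.stack(weights)
    return out


def attention_encode(
    protein: ProteinRecord, config: AttentionEncoderConfig, params: dict
) -> np.ndarray:
    """Encode a protein sequence into one vector of ``output_width``.

    Residues are embedded (plus sinusoidal positional encodings), passed
    through the attention layers, pooled (mean by default) and projected.
    Over-length sequences are tail-truncated with a warning.
    """
    seq = protein.sequence
    if len(seq) > config.max_length:
        logger.warning(
            "attention_encode: %s truncated from %d to %d residues",
            protein.id, len(seq), config.max_length,
        )
        seq = seq[: config.max_length]
    idx = np.array([_AA_INDEX[aa] for aa in seq])
    x = params["embed"][idx] + _positional_encoding(len(seq), config.model_width)
    for layer in params["layers"]:
        x = attention_layer(x, layer)
    pooled = x.mean(axis=0) if config.pooling == "mean" else x[0]
    return pooled @ params["out"]


def load_protein_embeddings(path, dim_tag: str = "3D", strict_width: bool = False) -> EmbeddingSet:
    """Adapter for precomputed protein embeddings (columnar text); the
    conventional widths are 100 (1D), 768 (2D) and 1280 (3D).

    With ``strict_width`` on, a file whose width differs from the dimension
    tag's convention triggers a width-mismatch warning (not an error: custom
    widths are legitimate, the tag convention is only a default).
    """
    eset = load_embedding_file(path, "protein", dim_tag)
    from ._util import DEFAULT_WIDTHS

    expected = DEFAULT_WIDTHS["protein"][dim_tag]
    if strict_width and eset.width != expected:
        logger.warning(
            "load_protein_embeddings: %s tagged %s has width %d "
            "(conventional width is %d)",
            path, dim_tag, eset.width, expected,
        )
    return eset


def project_embedding_set(eset: EmbeddingSet, width: int, seed: int = 0) -> EmbeddingSet:
    """Optional linear projection of an embedding set to a lower width.

    A seeded random Gaussian projection (scaled by 1/sqrt(width)) applied
    to every vector — useful when wide pretrained embeddings should enter
    the fusion blocks at a reduced dimension. Off by default everywhere.
    """
    if width <= 0:
        raise ValueError("projection width must be positive")
    rng = np.random.default_rng(derive_seed(seed, f"project-{eset.entity_kind}-{eset.dim_tag}"))
    proj = rng.standard_normal((eset.width, width)) / np.sqrt(eset.width)
    return EmbeddingSet(
        entity_kind=eset.entity_kind,
        dim_tag=eset.dim_tag,
        width=width,
        vectors={k: v @ proj for k, v in eset.vectors.items()},
    )
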