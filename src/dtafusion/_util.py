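"""Small shared helpers: seeding, vector normalization, embedding containers."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import numpy as np

logger = logging.getLogger("dtafusion")

#: default embedding widths per entity and dimension tag
DEFAULT_WIDTHS: Mapping[str, Mapping[str, int]] = {
    "drug": {"1D": 100, "2D": 300, "3D": 512},
    "protein": {"1D": 100, "2D": 768, "3D": 1280},
}

DIM_TAGS = ("1D", "2D", "3D")
ENTITY_KINDS = ("drug", "protein")


def derive_seed(seed: int, label: str) -> int:
    """Derive a child seed < 2**31 from a master seed and a purpose label.

    Every source of randomness in the library draws its seed through this
    function so that a single integer reproduces a whole run while distinct
    components never share a stream.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def l2_normalize(v: np.ndarray) -> np.ndarray:
    """Scale a vector to unit Euclidean norm, preserving direction.

    A zero vector is returned unchanged (with a logged warning) rather than
    raising: an all-unknown-token featurization legitimately produces it.
    """
    v = np.asarray(v, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        logger.warning("l2_normalize: zero vector left unchanged")
        return v
    return v / norm


def l2_normalize_rows(m: np.ndarray) -> np.ndarray:
    """Row-wise unit normalization; zero rows pass through unchanged."""
    m = np.asarray(m, dtype=np.float64)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    safe = np.where(norms == 0.0, 1.0, norms)
    return m / safe


@dataclass
class EmbeddingSet:
    """A mapping id -> fixed-width real vector for one entity kind and
    dimension tag (1D sequence-level, 2D graph/contact-level, 3D spatial)."""

    entity_kind: str
    dim_tag: str
    width: int
    vectors: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise ValueError(f"entity_kind must be one of {ENTITY_KINDS}")
        if self.dim_tag not in DIM_TAGS:
            raise ValueError(f"dim_tag must be one of {DIM_TAGS}")
        for key, vec in self.vectors.items():
            self.vectors[key] = self._check(key, vec)

    def _check(self, key: str, vec) -> np.ndarray:
        arr = np.asarray(vec, dtype=float).ravel()
        if arr.shape[0] != self.width:
            raise ValueError(
                f"vector for {key!r} has length {arr.shape[0]}, expected {self.width}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"vector for {key!r} contains non-finite values")
        return arr

    def add(self, key: str, vec) -> None:
        if key in self.vectors:
            raise ValueError(f"duplicate id {key!r}")
        self.vectors[key] = self._check(key, vec)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, key: str) -> bool:
        return key in self.vectors

    def __getitem__(self, key: str) -> np.ndarray:
        try:
            return self.vectors[key]
        except KeyError:
            raise KeyError(
                f"no {self.dim_tag} {self.entity_kind} embedding for id {key!r}"
            ) from None

    def matrix(self, ids: Iterable[str]) -> np.ndarray:
        """Stack vectors for the given ids (raises on a missing id)."""
        return np.stack([self[i] for i in ids])

    def save(self, path) -> None:
        """Write as tab-separated `id\\tv1...vW` with a `#` metadata header."""
        with open(path, "w") as fh:
            fh.write(
                f"# entity_kind={self.entity_kind} dim_tag={self.dim_tag} "
                f"width={self.width}\n"
            )
            for key, vec in self.vectors.items():
                vals = "\t".join(repr(float(x)) for x in vec)
                fh.write(f"{key}\t{vals}\n")


def load_embedding_file(path, entity_kind: str, dim_tag: str) -> EmbeddingSet:
    """Read a columnar embedding file: first column id, rest floats.

    The width is inferred from the first data row; ragged rows and duplicate
    ids raise format errors carrying the offending line number.
    """
    vectors: Dict[str, np.ndarray] = {}
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: no vector values")
            key = parts[0]
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if width is None:
                width = vec.shape[0]
            elif vec.shape[0] != width:
                raise ValueError(
                    f"{path}: line {lineno}: row width {vec.shape[0]} != {width}"
                )
            if key in vectors:
                raise ValueError(f"{path}: line {lineno}: duplicate id {key!r}")
            vectors[key] = vec
    if width is None:
        raise ValueError(f"{path}: no embedding rows found")
    return EmbeddingSet(entity_kind=entity_kind, dim_tag=dim_tag, width=width, vectors=vectors)
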