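"""The multi-dimensional fusion network for affinity regression.

Each selected embedding dimension (drug 1D/2D/3D, protein 1D/2D/3D) is L2
normalized and passed through its own dense+ReLU block; block outputs are
concatenated per entity, the fused drug and protein embeddings are
concatenated, and a three-layer fully connected head (FC1, FC2, FC3, each
followed by dropout) feeds a single linear output neuron:

    a = FC3(FC2(FC1([f_d ; f_p])))  ->  linear(1)

Training minimizes mean squared error with Adam, mini-batches, and early
stopping on validation MSE (best weights restored). Everything runs on CPU
in float32; a single seed makes initialization, batching and dropout
reproducible.

The concatenation order is fixed: drug 1D, 2D, 3D, then protein 1D, 2D, 3D
(restricted to the selected dimensions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._util import DIM_TAGS, EmbeddingSet, derive_seed, l2_normalize, l2_normalize_rows, logger
from .data_io import InteractionTable

__all__ = [
    "FusionConfig",
    "FusionModel",
    "build_model",
    "predict",
    "train_model",
    "assemble_features",
    "l2_normalize",
]

Key = Tuple[str, str]  # (entity_kind, dim_tag)


@dataclass
class FusionConfig:
    drug_dims: Tuple[str, ...] = ("1D", "2D", "3D")
    protein_dims: Tuple[str, ...] = ("1D", "2D", "3D")
    block_dense_width: int = 1024
    head_widths: Tuple[int, int, int] = (1024, 1024, 512)
    dropout: float = 0.3
    learning_rate: float = 0.0001
    batch_size: int = 64
    max_epochs: int = 500
    early_stop_patience: int = 20
    seed: int = 0
    #: False bypasses the per-dimension blocks: inputs are concatenated raw
    #: and fed straight to the head (the single-dimension ablation protocol)
    use_fusion_blocks: bool = True
    #: L2-normalize each input embedding (unit vectors, consistent scales)
    normalize_inputs: bool = True
    #: optional dropout after the per-dimension block layers as well
    block_dropout: bool = False

    def __post_init__(self) -> None:
        self.drug_dims = tuple(self.drug_dims)
        self.protein_dims = tuple(self.protein_dims)
        if not self.drug_dims or not self.protein_dims:
            raise ValueError("select at least one drug and one protein dimension")
        for dim in (*self.drug_dims, *self.protein_dims):
            if dim not in DIM_TAGS:
                raise ValueError(f"unknown dimension tag {dim!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.head_widths) != 3:
            raise ValueError("head_widths must be a triple (FC1, FC2, FC3)")

    @property
    def keys(self) -> List[Key]:
        """Selected (entity, dim) inputs in fixed concatenation order."""
        return [("drug", d) for d in DIM_TAGS if d in self.drug_dims] + [
            ("protein", d) for d in DIM_TAGS if d in self.protein_dims
        ]


def _he_uniform(rng: np.random.Generator, w_in: int, w_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / w_in)
    return rng.uniform(-bound, bound, (w_in, w_out)).astype(np.float32)


class FusionModel:
    """Trainable fusion network; construct through :func:`build_model`."""

    def __init__(self, config: FusionConfig, widths: Mapping[Key, int]):
        self.config = config
        self.widths: Dict[Key, int] = {}
        for key in config.keys:
            if key not in widths:
                raise ValueError(f"missing input width for dimension {key}")
            self.widths[key] = int(widths[key])
        rng = np.random.default_rng(derive_seed(config.seed, "init"))
        self.params: Dict[str, np.ndarray] = {}
        if config.use_fusion_blocks:
            for kind, dim in config.keys:
                name = f"block_{kind}_{dim}"
                self.params[f"{name}_W"] = _he_uniform(
                    rng, self.widths[(kind, dim)], config.block_dense_width
                )
                self.params[f"{name}_b"] = np.zeros(config.block_dense_width, np.float32)
            head_in = len(config.keys) * config.block_dense_width
        else:
            head_in = sum(self.widths[k] for k in config.keys)
        h1, h2, h3 = config.head_widths
        for name, (w_in, w_out) in {
            "fc1": (head_in, h1),
            "fc2": (h1, h2),
            "fc3": (h2, h3),
            "out": (h3, 1),
        }.items():
            self.params[f"{name}_W"] = _he_uniform(rng, w_in, w_out)
            self.params[f"{name}_b"] = np.zeros(w_out, np.float32)
        self.head_in = head_in

    # -- introspection ------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------------

    def _branch_inputs(self, features: Mapping[Key, np.ndarray]) -> List[np.ndarray]:
        out = []
        for key in self.config.keys:
            x = np.asarray(features[key], dtype=np.float32)
            if x.shape[1] != self.widths[key]:
                raise ValueError(
                    f"width mismatch for {key[0]} {key[1]}: "
                    f"got {x.shape[1]}, expected {self.widths[key]}"
                )
            if self.config.normalize_inputs:
                x = l2_normalize_rows(x).astype(np.float32)
            out.append(x)
        return out

    def _forward(
        self,
        features: Mapping[Key, np.ndarray],
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ):
        cfg = self.config
        cache: Dict[str, object] = {}
        branches = self._branch_inputs(features)
        cache["z"] = branches
        if cfg.use_fusion_blocks:
            hs, pre = [], []
            for key, z in zip(cfg.keys, branches):
                name = f"block_{key[0]}_{key[1]}"
                p = z @ self.params[f"{name}_W"] + self.params[f"{name}_b"]
                h = np.maximum(p, 0.0)
                if cfg.block_dropout and training and cfg.dropout > 0:
                    mask = (rng.random(h.shape) >= cfg.dropout).astype(np.float32)
                    h = h * mask / (1.0 - cfg.dropout)
                    pre.append((p, mask))
                else:
                    pre.append((p, None))
                hs.append(h)
            cache["block_pre"] = pre
            f = np.concatenate(hs, axis=1)
        else:
            f = np.concatenate(branches, axis=1)
        cache["f"] = f
        h = f
        for name in ("fc1", "fc2", "fc3"):
            p = h @ self.params[f"{name}_W"] + self.params[f"{name}_b"]
            a = np.maximum(p, 0.0)
            if training and cfg.dropout > 0:
                mask = (rng.random(a.shape) >= cfg.dropout).astype(np.float32)
                a = a * mask / (1.0 - cfg.dropout)
            else:
                mask = None
            cache[name] = (p, mask, a)
            h = a
        out = (h @ self.params["out_W"] + self.params["out_b"])[:, 0]
        cache["head_out_in"] = h
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> Dict[str, np.ndarray]:
        cfg = self.config
        grads: Dict[str, np.ndarray] = {}
        dout = dout[:, None].astype(np.float32)
        h = cache["head_out_in"]
        grads["out_W"] = h.T @ dout
        grads["out_b"] = dout.sum(axis=0)
        dh = dout @ self.params["out_W"].T
        for name in ("fc3", "fc2", "fc1"):
            p, mask, _ = cache[name]
            if mask is not None:
                dh = dh * mask / (1.0 - cfg.dropout)
            dp = dh * (p > 0)
            inp = cache["f"] if name == "fc1" else cache["fc2" if name == "fc3" else "fc1"][2]
            grads[f"{name}_W"] = inp.T @ dp
            grads[f"{name}_b"] = dp.sum(axis=0)
            dh = dp @ self.params[f"{name}_W"].T
        if cfg.use_fusion_blocks:
            offset = 0
            for key, z, (p, mask) in zip(cfg.keys, cache["z"], cache["block_pre"]):
                name = f"block_{key[0]}_{key[1]}"
                width = cfg.block_dense_width
                dslice = dh[:, offset : offset + width]
                if mask is not None:
                    dslice = dslice * mask / (1.0 - cfg.dropout)
                dp = dslice * (p > 0)
                grads[f"{name}_W"] = z.T @ dp
                grads[f"{name}_b"] = dp.sum(axis=0)
                offset += width
        return grads

    # -- inference ----------------------------------------------------------

    def predict_matrix(self, features: Mapping[Key, np.ndarray], chunk: int = 2048) -> np.ndarray:
        """Deterministic batched inference (dropout disabled)."""
        n = next(iter(features.values())).shape[0]
        out = np.empty(n)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            piece = {k: np.asarray(v)[sl] for k, v in features.items()}
            out[sl], _ = self._forward(piece, training=False)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Save parameters (.npz) plus a text manifest (.json sidecar)."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz", **self.params)
        manifest = {
            "config": asdict(self.config),
            "widths": {f"{k}:{d}": w for (k, d), w in self.widths.items()},
            "n_parameters": self.n_parameters,
        }
        with open(path.removesuffix(".npz") + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FusionModel":
        path = str(path)
        base = path.removesuffix(".npz")
        with open(base + ".manifest.json") as fh:
            manifest = json.load(fh)
        cfg_dict = manifest["config"]
        for key in ("drug_dims", "protein_dims", "head_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = FusionConfig(**cfg_dict)
        widths = {tuple(k.split(":")): w for k, w in manifest["widths"].items()}
        model = cls(config, widths)
        data = np.load(base + ".npz")
        for name in model.params:
            model.params[name] = data[name].astype(np.float32)
        return model


def build_model(config: FusionConfig, widths: Mapping[Key, int]) -> FusionModel:
    """Construct the fusion network for the given per-dimension input widths."""
    return FusionModel(config, widths)


def predict(
    model: FusionModel,
    drug_vectors: Mapping[str, np.ndarray],
    protein_vectors: Mapping[str, np.ndarray],
) -> float:
    """Predicted affinity for one (drug, protein) pair given its per-dimension
    embedding vectors; deterministic (inference mode)."""
    features = {}
    for kind, vecs in (("drug", drug_vectors), ("protein", protein_vectors)):
        for dim in model.config.keys:
            if dim[0] != kind:
                continue
            if dim[1] not in vecs:
                raise ValueError(f"missing {kind} {dim[1]} vector")
            features[dim] = np.asarray(vecs[dim[1]], dtype=float)[None, :]
    return float(model.predict_matrix(features)[0])


def assemble_features(
    table: InteractionTable,
    embeddings: Mapping[Key, EmbeddingSet],
    keys: Sequence[Key],
) -> Dict[Key, np.ndarray]:
    """Row-aligned feature matrices for every selected (entity, dim).

    Raises a lookup error naming the first missing id and its dimension.
    """
    features: Dict[Key, np.ndarray] = {}
    for key in keys:
        if key not in embeddings:
            raise ValueError(f"no embedding set provided for {key[0]} {key[1]}")
        eset = embeddings[key]
        ids = table.df["drug_id"] if key[0] == "drug" else table.df["protein_id"]
        features[key] = eset.matrix(ids)
    return features


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class TrainingLog:
    epochs: List[dict] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = -1

    def append(self, **kwargs) -> None:
        self.epochs.append(kwargs)


def train_model(
    model: FusionModel,
    train_table: InteractionTable,
    embeddings: Mapping[Key, EmbeddingSet],
    validation_table: Optional[InteractionTable] = None,
    config: Optional[FusionConfig] = None,
) -> Tuple[FusionModel, TrainingLog]:
    """Fit the fusion network by mini-batch Adam on MSE.

    Stops at ``max_epochs`` or when validation MSE has not improved for
    ``early_stop_patience`` epochs (best weights restored). Without a
    validation table, training runs for ``max_epochs``. Returns the model
    and a per-epoch loss log.
    """
    cfg = config or model.config
    keys = model.config.keys
    x_train = assemble_features(train_table, embeddings, keys)
    y_train = train_table.affinities.astype(np.float32)
    x_val = y_val = None
    if validation_table is not None and len(validation_table):
        x_val = assemble_features(validation_table, embeddings, keys)
        y_val = validation_table.affinities

    # start the output neuron at the training mean so the head learns
    # residual structure rather than spending epochs drifting the bias
    model.params["out_b"] = np.array([float(y_train.mean())], np.float32)

    rng = np.random.default_rng(derive_seed(cfg.seed, "train"))
    optimizer = _Adam(model.params, cfg.learning_rate)
    log = TrainingLog()
    n = len(y_train)
    best_val = np.inf
    best_params = None
    patience_left = cfg.early_stop_patience
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            batch = {k: v[idx] for k, v in x_train.items()}
            out, cache = model._forward(batch, training=True, rng=rng)
            resid = out - y_train[idx]
            sq_sum += float(np.sum(resid**2))
            grads = model._backward(2.0 * resid / len(idx), cache)
            optimizer.step(model.params, grads)
        train_mse = sq_sum / n
        entry = {"epoch": epoch, "train_mse": train_mse}
        if x_val is not None:
            val_mse = float(np.mean((model.predict_matrix(x_val) - y_val) ** 2))
            entry["val_mse"] = val_mse
            if val_mse < best_val - 1e-9:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in model.params.items()}
                log.best_epoch = epoch
                patience_left = cfg.early_stop_patience
            else:
                patience_left -= 1
        log.append(**entry)
        if x_val is not None and patience_left <= 0:
            log.stopped_early = True
            logger.info("early stop at epoch %d (best %d)", epoch, log.best_epoch)
            break
    if best_params is not None:
        model.params = best_params
    return model, log
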