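"""Drug embeddings in three dimensions.

1D: circular-substructure tokens (Morgan atom environments, radius 0..r)
    embedded by skip-gram and summed per molecule.
2D: a graph isomorphism network (GIN) over the molecular graph; each layer
    computes MLP((1 + eps) * h_i + sum_{j in N(i)} h_j), node states are
    aggregated by a sum/mean readout and pushed through a final MLP.
3D: distance-featured message passing over a conformer; messages see the
    geometry only through pairwise distances, so the embedding is exactly
    invariant to rigid rotations and translations of the coordinates.

The GIN and 3D embedders run with seeded random frozen parameters: the
fusion head consumes fixed-width vectors, and the structural information
(neighborhood multisets, interatomic distances) is carried by the
architecture rather than by pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from ._util import EmbeddingSet, derive_seed, load_embedding_file
from .data_io import DrugRecord
from .skipgram import SkipGramModel, train_skipgram  # noqa: F401  (re-export)

RDLogger.DisableLog("rdApp.*")


class FeaturizationError(ValueError):
    """Raised when an entity cannot be featurized; carries the entity id."""

    def __init__(self, entity_id: str, message: str):
        self.entity_id = entity_id
        super().__init__(f"{entity_id}: {message}")


_ELEMENTS = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")  # + other
_MAX_DEGREE = 5
N_ATOM_FEATURES = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1  # element, degree, aromatic
N_BOND_FEATURES = 4  # single, double, triple, aromatic

_BOND_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


@dataclass
class MolecularGraph:
    """G = (A, R, X, E): adjacency, optional 3D coordinates, atom attributes
    and bond attributes for one molecule (heavy atoms only)."""

    n_atoms: int
    A: np.ndarray  # n x n symmetric 0/1
    X: np.ndarray  # n x K atom attributes
    E: np.ndarray  # n x n x D bond attributes
    R: Optional[np.ndarray] = None  # n x 3 coordinates
    mol: Optional[Chem.Mol] = None  # parser handle, used for conformers

    def __post_init__(self) -> None:
        n = self.n_atoms
        if self.A.shape != (n, n):
            raise ValueError("A must be n x n")
        if not np.array_equal(self.A, self.A.T) or np.any(np.diag(self.A) != 0):
            raise ValueError("A must be symmetric with zero diagonal")
        if self.X.shape[0] != n:
            raise ValueError("X must have one row per atom")
        if self.E.shape[:2] != (n, n):
            raise ValueError("E must be n x n x D")
        if np.any((self.E.sum(axis=2) > 0) & (self.A == 0)):
            raise ValueError("E may be nonzero only on edges of A")
        if self.R is not None and self.R.shape != (n, 3):
            raise ValueError("R must be n x 3")


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    vec = np.zeros(N_ATOM_FEATURES)
    sym = atom.GetSymbol()
    vec[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    deg = min(atom.GetDegree(), _MAX_DEGREE)
    vec[len(_ELEMENTS) + 1 + deg] = 1.0
    vec[-1] = 1.0 if atom.GetIsAromatic() else 0.0
    return vec


def smiles_to_graph(drug: DrugRecord) -> MolecularGraph:
    """Parse SMILES into an undirected molecular graph (atoms = nodes,
    bonds = edges; hydrogens implicit)."""
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise FeaturizationError(drug.id, f"unparseable SMILES {drug.smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise FeaturizationError(drug.id, "molecule has no atoms")
    A = np.zeros((n, n), dtype=int)
    E = np.zeros((n, n, N_BOND_FEATURES))
    X = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1
        k = _BOND_INDEX.get(bond.GetBondType(), 0)
        E[i, j, k] = E[j, i, k] = 1.0
    return MolecularGraph(n_atoms=n, A=A, X=X, E=E, mol=mol)


def tokenize_substructures(drug: DrugRecord, radius: int = 1) -> List[str]:
    """Circular atom-environment identifier tokens, radius 0..radius.

    For each atom in the parser's canonical order, one token per available
    environment radius (Morgan invariants), so a molecule reads as a
    deterministic sentence of substructure identifiers.
    """
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise FeaturizationError(drug.id, f"unparseable SMILES {drug.smiles!r}")
    info: Dict[int, tuple] = {}
    AllChem.GetMorganFingerprint(mol, radius, bitInfo=info)
    per_atom: Dict[tuple, int] = {}
    for identifier, sites in info.items():
        for atom_idx, rad in sites:
            per_atom[(atom_idx, rad)] = identifier
    tokens = []
    for atom_idx in range(mol.GetNumAtoms()):
        for rad in range(radius + 1):
            if (atom_idx, rad) in per_atom:
                tokens.append(str(per_atom[(atom_idx, rad)]))
    return tokens


def embed_1d(
    drug: DrugRecord, model: SkipGramModel, radius: int = 1, aggregate: str = "sum"
) -> np.ndarray:
    """Sum (default) of the skip-gram vectors of the drug's substructure
    tokens; unknown tokens contribute zero."""
    return model.embed_tokens(tokenize_substructures(drug, radius=radius), aggregate=aggregate)


# ---------------------------------------------------------------------------
# GIN (2D)
# ---------------------------------------------------------------------------


@dataclass
class GINConfig:
    n_layers: int = 3
    hidden_width: int = 64
    epsilon: float = 0.0
    mlp_depth: int = 2
    readout: str = "sum"
    output_width: int = 300

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.output_width <= 0:
            raise ValueError("output_width must be positive")
        if self.readout not in ("sum", "mean"):
            raise ValueError("readout must be 'sum' or 'mean'")


def _init_mlp(rng: np.random.Generator, widths: Sequence[int]):
    layers = []
    for w_in, w_out in zip(widths[:-1], widths[1:]):
        bound = np.sqrt(6.0 / w_in)
        layers.append((rng.uniform(-bound, bound, (w_in, w_out)), np.zeros(w_out)))
    return layers


def _run_mlp(layers, h: np.ndarray, final_relu: bool = True) -> np.ndarray:
    for i, (w, b) in enumerate(layers):
        h = h @ w + b
        if final_relu or i < len(layers) - 1:
            h = np.maximum(h, 0.0)
    return h


def init_gin_params(config: GINConfig, n_features: int = N_ATOM_FEATURES, seed: int = 0) -> dict:
    """Seeded random frozen GIN parameters shaped per the config."""
    rng = np.random.default_rng(derive_seed(seed, "gin"))
    params = {"n_features": n_features, "layers": [], "eps": []}
    width = n_features
    for _ in range(config.n_layers):
        widths = [width] + [config.hidden_width] * config.mlp_depth
        params["layers"].append(_init_mlp(rng, widths))
        params["eps"].append(config.epsilon)
        width = config.hidden_width
    params["out"] = _init_mlp(rng, [width, config.output_width])
    return params


def gin_embed(graph: MolecularGraph, config: GINConfig, params: dict) -> np.ndarray:
    """GIN forward pass: per layer h_i <- MLP((1+eps) h_i + sum_{j~i} h_j),
    then sum/mean readout and a final MLP to ``output_width``.

    Permutation-invariant by construction: relabeling nodes permutes rows
    of A and X consistently and leaves the readout unchanged.
    """
    if params["n_features"] != graph.X.shape[1]:
        raise ValueError(
            f"params expect {params['n_features']} atom features, "
            f"graph has {graph.X.shape[1]}"
        )
    h = graph.X.astype(float)
    for mlp, eps in zip(params["layers"], params["eps"]):
        h = _run_mlp(mlp, (1.0 + eps) * h + graph.A @ h)
    g = h.sum(axis=0) if config.readout == "sum" else h.mean(axis=0)
    return _run_mlp(params["out"], g, final_relu=False)


# ---------------------------------------------------------------------------
# Invariant 3D embedder
# ---------------------------------------------------------------------------


@dataclass
class Invariant3DConfig:
    n_layers: int = 2
    hidden_width: int = 64
    output_width: int = 512

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_width <= 0 or self.output_width <= 0:
            raise ValueError("layer counts and widths must be positive")


def init_3d_params(
    config: Invariant3DConfig, n_features: int = N_ATOM_FEATURES, seed: int = 0
) -> dict:
    rng = np.random.default_rng(derive_seed(seed, "egnn"))
    h = config.hidden_width
    params = {
        "n_features": n_features,
        "embed": _init_mlp(rng, [n_features, h]),
        "layers": [],
    }
    for _ in range(config.n_layers):
        params["layers"].append(
            {
                "edge": _init_mlp(rng, [2 * h + 1 + N_BOND_FEATURES, h, h]),
                "node": _init_mlp(rng, [2 * h, h, h]),
            }
        )
    params["out"] = _init_mlp(rng, [h, config.output_width])
    return params


def embed_3d(graph: MolecularGraph, config: Invariant3DConfig, params: dict) -> np.ndarray:
    """Message passing over bonded pairs with squared-distance edge features.

    The coordinates enter only through ||R_i - R_j||^2, so any proper rigid
    motion of R leaves the embedding unchanged; stretching a bond does not.
    """
    if graph.R is None:
        raise FeaturizationError(
            "<graph>", "no 3D coordinates; run generate_conformer first"
        )
    if params["n_features"] != graph.X.shape[1]:
        raise ValueError("atom-feature width mismatch between params and graph")
    n = graph.n_atoms
    src, dst = np.nonzero(graph.A)
    h = _run_mlp(params["embed"], graph.X.astype(float))
    if src.size:
        d2 = np.sum((graph.R[src] - graph.R[dst]) ** 2, axis=1, keepdims=True)
        e_attr = graph.E[src, dst]
    for layer in params["layers"]:
        if src.size:
            m_in = np.concatenate([h[src], h[dst], d2, e_attr], axis=1)
            messages = _run_mlp(layer["edge"], m_in)
            agg = np.zeros_like(h)
            np.add.at(agg, src, messages)
        else:
            agg = np.zeros_like(h)
        h = _run_mlp(layer["node"], np.concatenate([h, agg], axis=1))
    return _run_mlp(params["out"], h.sum(axis=0), final_relu=False)


def generate_conformer(graph: MolecularGraph, seed: int = 0, max_tries: int = 5) -> MolecularGraph:
    """Fill R with 3D coordinates: distance-geometry embedding through the
    structure kit when a parsed molecule is attached, else a deterministic
    3D spring layout of the adjacency. Seed-reproducible."""
    if graph.mol is not None:
        mol = Chem.AddHs(Chem.Mol(graph.mol))
        for attempt in range(max_tries):
            params = AllChem.ETKDGv3()
            params.randomSeed = derive_seed(seed, f"conf{attempt}")
            if AllChem.EmbedMolecule(mol, params) == 0:
                conf = mol.GetConformer()
                R = np.array(
                    [list(conf.GetAtomPosition(i)) for i in range(graph.n_atoms)]
                )
                return MolecularGraph(graph.n_atoms, graph.A, graph.X, graph.E, R, graph.mol)
    g = nx.from_numpy_array(graph.A)
    pos = nx.spring_layout(g, dim=3, seed=derive_seed(seed, "spring"))
    R = np.array([pos[i] for i in range(graph.n_atoms)])
    if graph.n_atoms == 1:
        R = np.zeros((1, 3))
    return MolecularGraph(graph.n_atoms, graph.A, graph.X, graph.E, R, graph.mol)


def load_embeddings(path, entity_kind: str = "drug", dim_tag: str = "1D") -> EmbeddingSet:
    """Adapter for precomputed embeddings (e.g. outputs of large pretrained
    models): columnar `id<TAB>v1..vW` text, width inferred from row one."""
    return load_embedding_file(path, entity_kind, dim_tag)
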