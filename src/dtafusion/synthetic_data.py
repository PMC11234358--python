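"""Self-contained synthetic benchmarks shaped like the public DTA data sets.

The generator emulates the shape of kinase-panel affinity benchmarks
(hundreds of drugs x hundreds of proteins, continuous affinities in a
bounded range, dense to sparse interaction matrices) while giving full
control over where the predictive signal lives:

* each drug i carries a latent vector u_i, each protein j a latent v_j
  (standard normal, ``latent_width``);
* the noiseless affinity is the bilinear form dot(u_i, v_j), affinely
  rescaled into ``affinity_range`` (mean +- 2.5 sd of the dot product maps
  onto the range, so ~99% of pairs fall inside it, mirroring how such
  benchmarks concentrate near the range floor), plus Gaussian noise;
* each of the six embeddings (drug 1D/2D/3D, protein 1D/2D/3D) is an
  informativeness-weighted mix of a fixed random projection of the latent
  and independent noise, at the conventional widths (100/300/512 drug,
  100/768/1280 protein).

With informativeness 1 the affinity is exactly learnable from any one
drug-side and one protein-side embedding; with informativeness 0 every
embedding is pure noise and chance-level concordance is the ceiling.
The bilinear target is deliberately not linear in any concatenation of
embeddings — recovering it requires cross-modal interaction, which is the
claim the fusion architecture makes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._util import DEFAULT_WIDTHS, DIM_TAGS, EmbeddingSet, derive_seed
from .data_io import AMINO_ACIDS, DrugRecord, InteractionTable, ProteinRecord
from .drug_featurizers import MolecularGraph, smiles_to_graph

#: pool of small valid structures: alkanes, rings, simple heteroatom compounds
SMILES_POOL = (
    "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CC(C)(C)C",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1",
    "CO", "CCO", "CCCO", "CC(C)O", "OCCO",
    "CN", "CCN", "CNC", "CC(N)C", "NCCN",
    "C=C", "CC=C", "C#C", "CC#N", "C=O", "CC=O", "CC(C)=O", "CC(=O)O",
    "CS", "CCS", "CSC", "CF", "CCF", "FC(F)F", "CCl", "CBr",
    "COC", "CCOC", "C1COC1", "C1CCOC1", "C1CCNC1", "C1CCSC1",
    "OC1CCCCC1", "NC1CCCCC1", "CC1CCCCC1",
)

Key = Tuple[str, str]


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic benchmark (counts, signal, noise, range)."""

    n_drugs: int = 200
    n_proteins: int = 100
    latent_width: int = 8
    drug_informativeness: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    protein_informativeness: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.25
    affinity_range: Tuple[float, float] = (5.0, 10.0)
    density: float = 1.0
    seed: int = 0
    widths: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_WIDTHS.items()}
    )

    def __post_init__(self) -> None:
        if self.n_drugs < 2 or self.n_proteins < 2:
            raise ValueError("need at least 2 drugs and 2 proteins")
        if self.affinity_range[0] >= self.affinity_range[1]:
            raise ValueError("affinity_range must satisfy low < high")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for w in (*self.drug_informativeness, *self.protein_informativeness):
            if not 0.0 <= w <= 1.0:
                raise ValueError("informativeness weights must lie in [0, 1]")

    def informativeness(self, kind: str, dim: str) -> float:
        weights = self.drug_informativeness if kind == "drug" else self.protein_informativeness
        return weights[DIM_TAGS.index(dim)]


def generate_entities(
    spec: SyntheticSpec,
) -> Tuple[List[DrugRecord], List[ProteinRecord], Dict[str, MolecularGraph]]:
    """Drug records (drawn from a pool of valid small SMILES), random protein
    sequences with lengths uniform in [200, 1500], and per-drug graphs."""
    rng = np.random.default_rng(derive_seed(spec.seed, "entities"))
    drugs = [
        DrugRecord(f"D{i:04d}", SMILES_POOL[i % len(SMILES_POOL)])
        for i in range(spec.n_drugs)
    ]
    proteins = []
    aa20 = AMINO_ACIDS[:20]
    for j in range(spec.n_proteins):
        length = int(rng.integers(200, 1501))
        seq = "".join(rng.choice(list(aa20), size=length))
        proteins.append(ProteinRecord(f"P{j:04d}", seq))
    graphs = {d.id: smiles_to_graph(d) for d in drugs}
    return drugs, proteins, graphs


def _latents(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray]:
    rng_u = np.random.default_rng(derive_seed(spec.seed, "latent-drug"))
    rng_v = np.random.default_rng(derive_seed(spec.seed, "latent-protein"))
    u = rng_u.standard_normal((spec.n_drugs, spec.latent_width))
    v = rng_v.standard_normal((spec.n_proteins, spec.latent_width))
    return u, v


def generate_embeddings_and_affinity(
    spec: SyntheticSpec,
) -> Tuple[Dict[Key, EmbeddingSet], InteractionTable]:
    """Six embedding sets plus the interaction table.

    Embedding for entity e in dimension d: w * (latent_e @ P_d) + (1 - w) * eps,
    with P_d a fixed seeded random projection to the dimension's width and
    eps independent standard noise (w = that dimension's informativeness).
    Affinity: the latent dot product rescaled into ``affinity_range`` plus
    N(0, noise_sd^2) noise. Changing only ``noise_sd`` changes affinities
    but not embeddings (independent seed streams).
    """
    u, v = _latents(spec)
    drug_ids = [f"D{i:04d}" for i in range(spec.n_drugs)]
    protein_ids = [f"P{j:04d}" for j in range(spec.n_proteins)]

    embeddings: Dict[Key, EmbeddingSet] = {}
    for kind, latent, ids in (("drug", u, drug_ids), ("protein", v, protein_ids)):
        for dim in DIM_TAGS:
            width = spec.widths[kind][dim]
            w = spec.informativeness(kind, dim)
            rng = np.random.default_rng(derive_seed(spec.seed, f"embed-{kind}-{dim}"))
            proj = rng.standard_normal((spec.latent_width, width)) / np.sqrt(spec.latent_width)
            noise = rng.standard_normal((latent.shape[0], width))
            mat = w * (latent @ proj) + (1.0 - w) * noise
            embeddings[(kind, dim)] = EmbeddingSet(
                entity_kind=kind,
                dim_tag=dim,
                width=width,
                vectors={i: mat[k] for k, i in enumerate(ids)},
            )

    # pair selection: exact count without replacement, seed-reproducible
    n_pairs_total = spec.n_drugs * spec.n_proteins
    n_emit = max(1, int(round(spec.density * n_pairs_total)))
    rng_pairs = np.random.default_rng(derive_seed(spec.seed, "pairs"))
    chosen = np.sort(rng_pairs.permutation(n_pairs_total)[:n_emit])
    di, pj = np.divmod(chosen, spec.n_proteins)

    raw = np.einsum("ik,ik->i", u[di], v[pj])
    # mean +- 2.5 sd of the dot product maps onto the affinity range
    sd = np.sqrt(spec.latent_width)
    low, high = spec.affinity_range
    scale = (high - low) / (5.0 * sd)
    signal = (low + high) / 2.0 + raw * scale
    rng_noise = np.random.default_rng(derive_seed(spec.seed, "noise"))
    affinity = signal + rng_noise.normal(0.0, spec.noise_sd, size=signal.shape)

    table = InteractionTable(
        pd.DataFrame(
            {
                "drug_id": [drug_ids[i] for i in di],
                "protein_id": [protein_ids[j] for j in pj],
                "affinity": affinity,
            }
        ),
        scale="pKd",
    )
    return embeddings, table


def write_fixture_directory(spec: SyntheticSpec, out_dir) -> Dict[str, str]:
    """Materialize a full text fixture: drugs.smi, proteins.fasta,
    interactions.csv, six embedding files and a manifest. Returns paths."""
    import json
    from pathlib import Path

    from .data_io import write_drugs, write_proteins

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drugs, proteins, _ = generate_entities(spec)
    embeddings, table = generate_embeddings_and_affinity(spec)
    paths = {}
    write_drugs(drugs, out / "drugs.smi")
    paths["drugs"] = str(out / "drugs.smi")
    write_proteins(proteins, out / "proteins.fasta")
    paths["proteins"] = str(out / "proteins.fasta")
    table.save(out / "interactions.csv")
    paths["interactions"] = str(out / "interactions.csv")
    for (kind, dim), eset in embeddings.items():
        p = out / f"{kind}_{dim}.emb.tsv"
        eset.save(p)
        paths[f"{kind}_{dim}"] = str(p)
    manifest = {
        "spec": {
            "n_drugs": spec.n_drugs,
            "n_proteins": spec.n_proteins,
            "latent_width": spec.latent_width,
            "drug_informativeness": list(spec.drug_informativeness),
            "protein_informativeness": list(spec.protein_informativeness),
            "noise_sd": spec.noise_sd,
            "affinity_range": list(spec.affinity_range),
            "density": spec.density,
            "seed": spec.seed,
        }
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = str(out / "manifest.json")
    return paths
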