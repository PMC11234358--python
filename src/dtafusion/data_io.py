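"""Reading interaction tables, drugs and proteins; affinity transforms; splits.

Interaction tables are CSV/TSV files with a ``drug_id,protein_id,affinity``
header. Affinity scales are carried as explicit metadata (``Kd_nM``, ``pKd``,
``KIBA_score`` or ``arbitrary``); nothing is ever auto-detected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.model_selection import KFold

from ._util import derive_seed

AFFINITY_SCALES = ("Kd_nM", "pKd", "KIBA_score", "arbitrary")

#: 20 standard amino acids plus X for unknown
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"
_AA_RE = re.compile(f"^[{AMINO_ACIDS}]+$")


@dataclass
class InteractionTable:
    """Rows of (drug_id, protein_id, affinity) plus an affinity-scale tag."""

    df: pd.DataFrame
    scale: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.scale not in AFFINITY_SCALES:
            raise ValueError(f"scale must be one of {AFFINITY_SCALES}")
        required = ["drug_id", "protein_id", "affinity"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"interaction table missing column(s): {missing}")
        self.df = self.df[required].reset_index(drop=True)
        self.df["drug_id"] = self.df["drug_id"].astype(str)
        self.df["protein_id"] = self.df["protein_id"].astype(str)
        aff = pd.to_numeric(self.df["affinity"], errors="raise")
        if not np.all(np.isfinite(aff.to_numpy(dtype=float))):
            raise ValueError("affinity values must be finite")
        self.df["affinity"] = aff.astype(float)
        dup = self.df.duplicated(subset=["drug_id", "protein_id"])
        if dup.any():
            first = self.df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (drug_id, protein_id) pair: "
                f"({first['drug_id']!r}, {first['protein_id']!r})"
            )
        if self.scale == "Kd_nM" and (self.df["affinity"] <= 0).any():
            raise ValueError("Kd_nM affinities must be strictly positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def drug_ids(self) -> List[str]:
        return list(dict.fromkeys(self.df["drug_id"]))

    @property
    def protein_ids(self) -> List[str]:
        return list(dict.fromkeys(self.df["protein_id"]))

    @property
    def affinities(self) -> np.ndarray:
        return self.df["affinity"].to_numpy(dtype=float)

    def subset(self, index: Sequence[int]) -> "InteractionTable":
        return InteractionTable(self.df.iloc[list(index)].reset_index(drop=True), self.scale)

    def save(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class DrugRecord:
    id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"drug {self.id!r}: empty SMILES")


@dataclass
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if not _AA_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set(AMINO_ACIDS))
            raise ValueError(
                f"protein {self.id!r}: invalid residue(s) {bad}; "
                f"alphabet is the 20 amino acids plus X"
            )


@dataclass
class SplitSpec:
    """Held-out test fraction plus k validation folds of the training rows
    (80/20 with 5 folds by default).

    ``unit`` selects what is held out: "pair" (the benchmark protocol —
    random interaction rows; entities appear on both sides), or the harder
    cold-entity modes "cold_drug" / "cold_protein" where whole entities are
    held out with all their rows.
    """

    test_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0
    unit: str = "pair"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.unit not in ("pair", "cold_drug", "cold_protein"):
            raise ValueError("unit must be 'pair', 'cold_drug' or 'cold_protein'")


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_interaction_table(path, scale: str = "arbitrary") -> InteractionTable:
    """Read a CSV/TSV interaction table (header required).

    Non-numeric affinities raise a row-level error citing the file line.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("drug_id", "protein_id", "affinity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    aff = pd.to_numeric(df["affinity"], errors="coerce")
    bad = aff.isna() & df["affinity"].notna() | df["affinity"].isna()
    if bad.any():
        row = int(bad.idxmax())
        # +2: one for the header, one for 1-based numbering
        raise ValueError(
            f"{path}: line {row + 2}: non-numeric affinity {df['affinity'].iloc[row]!r}"
        )
    df = df.assign(affinity=aff)
    return InteractionTable(df, scale=scale)


def read_drugs(path) -> List[DrugRecord]:
    """Read drugs from a tab-separated `id<TAB>smiles` file or a CSV with
    ``id,smiles`` columns (detected from the header)."""
    with open(path) as fh:
        first = fh.readline()
    if "," in first and "id" in first.split(",")[0].lower():
        df = pd.read_csv(path, dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "id" not in cols or "smiles" not in cols:
            raise ValueError(f"{path}: drug CSV needs 'id' and 'smiles' columns")
        return [DrugRecord(str(r[cols["id"]]), str(r[cols["smiles"]])) for _, r in df.iterrows()]
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>smiles'")
            records.append(DrugRecord(parts[0], parts[1]))
    return records


def read_proteins(path) -> List[ProteinRecord]:
    """Read proteins from FASTA; the id is the header up to first whitespace."""
    return [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_drugs(records: Sequence[DrugRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.smiles}\n")


def write_proteins(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def kd_to_pkd(kd: float) -> float:
    """Dissociation constant in nM -> pKd = -log10(Kd / 1e9).

    Maps the molar-rescaled Kd onto the negative log scale: 1 nM -> 9,
    10 uM -> 5 (the floor of the DAVIS benchmark), 1 M -> 0.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd must be strictly positive (nM)")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


def pkd_to_kd(pkd: float) -> float:
    """Inverse of :func:`kd_to_pkd`; returns Kd in nM."""
    pkd = np.asarray(pkd, dtype=float)
    out = 1e9 * 10.0 ** (-pkd)
    return float(out) if out.ndim == 0 else out


def binarize_affinity(values, threshold: float, positive_if: str = "ge") -> np.ndarray:
    """Threshold continuous affinities into 0/1 interaction labels.

    Values equal to the threshold count as positive under the default ``ge``
    rule (use ``gt`` for a strict rule). The canonical thresholds are 7 on
    the pKd scale and 12.1 on the KIBA score scale.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if positive_if not in ("ge", "gt"):
        raise ValueError("positive_if must be 'ge' or 'gt'")
    values = np.asarray(values, dtype=float)
    if positive_if == "ge":
        return (values >= threshold).astype(int)
    return (values > threshold).astype(int)


def split_data(
    table: InteractionTable, spec: SplitSpec
) -> Tuple[InteractionTable, InteractionTable, List[Tuple[np.ndarray, np.ndarray]]]:
    """Deterministic random-pair split into train/test plus CV folds.

    Returns (train, test, folds) where folds is a list of
    (fold-train, fold-validation) positional index arrays into the train
    table. The test size is round(test_fraction * N); folds partition the
    training rows. The same seed reproduces the split exactly.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(derive_seed(spec.seed, "split"))
    if spec.unit == "pair":
        n_test = int(round(spec.test_fraction * n))
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
    else:
        col = "drug_id" if spec.unit == "cold_drug" else "protein_id"
        entities = sorted(table.df[col].unique())
        n_test_entities = int(round(spec.test_fraction * len(entities)))
        held_out = set(np.array(entities)[rng.permutation(len(entities))[:n_test_entities]])
        mask = table.df[col].isin(held_out).to_numpy()
        test_idx = np.flatnonzero(mask)
        train_idx = np.flatnonzero(~mask)
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError(f"cold split produced an empty side (unit={spec.unit})")
    if spec.n_folds > len(train_idx):
        raise ValueError(
            f"n_folds={spec.n_folds} exceeds the {len(train_idx)} training rows"
        )
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=derive_seed(spec.seed, "folds"))
    folds = [(tr.copy(), va.copy()) for tr, va in kf.split(train_idx)]
    return table.subset(train_idx), table.subset(test_idx), folds
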