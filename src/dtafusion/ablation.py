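"""Ablation protocols: leave-one-embedding-out and single-dimension pairs.

Both studies retrain the fusion network per variant on identical train/test
indices and initialization seeds, so metric differences are attributable to
the input change alone.

* Exclusion study: the full six-input model plus six variants, each with
  one embedding dimension removed (the head input shrinks by one block
  output; block width is not re-widened to match capacity).
* Pairwise study: all nine (drug dim, protein dim) pairs, with the fusion
  blocks bypassed — the two embeddings are concatenated raw and fed to the
  three-layer head — plus the full fusion model as reference. By default
  the inputs are still L2 normalized before concatenation so the two sides
  enter at comparable scale regardless of width (a flag disables this).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from ._util import DIM_TAGS, EmbeddingSet
from .data_io import InteractionTable, SplitSpec, split_data
from .fusion_model import FusionConfig, FusionModel, assemble_features, train_model
from .metrics import EvaluationReport, evaluate

Key = Tuple[str, str]


@dataclass
class AblationResult:
    variant: str
    report: EvaluationReport


@dataclass
class DataBundle:
    """Everything one training run needs: the table, the six embedding sets,
    a split spec and the classification threshold."""

    table: InteractionTable
    embeddings: Mapping[Key, EmbeddingSet]
    split: SplitSpec
    threshold: float = 7.0

    def split_hash(self) -> str:
        """Digest of the train/test indices; equal across study variants."""
        train, test, _ = split_data(self.table, self.split)
        payload = (
            ",".join(map(str, train.df.index)) + "|" +
            ",".join(train.df["drug_id"]) + "|" + ",".join(test.df["drug_id"])
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _train_and_evaluate(bundle: DataBundle, config: FusionConfig) -> EvaluationReport:
    train, test, folds = split_data(bundle.table, bundle.split)
    # hold out the first CV fold's validation rows for early stopping
    tr_idx, va_idx = folds[0]
    widths = {k: bundle.embeddings[k].width for k in config.keys}
    model = FusionModel(config, widths)
    train_model(
        model,
        train.subset(tr_idx),
        bundle.embeddings,
        validation_table=train.subset(va_idx),
    )
    features = assemble_features(test, bundle.embeddings, config.keys)
    preds = model.predict_matrix(features)
    return evaluate(test.affinities, preds, bundle.threshold)


def run_exclusion_study(
    bundle: DataBundle, base_config: Optional[FusionConfig] = None
) -> List[AblationResult]:
    """Leave-one-embedding-out: the full model plus one variant per excluded
    dimension (7 rows), identical split and seed throughout."""
    config = base_config or FusionConfig()
    for key in config.keys:
        if key not in bundle.embeddings:
            raise ValueError(f"missing embedding set for {key[0]} {key[1]}")
    results = [AblationResult("full", _train_and_evaluate(bundle, config))]
    for kind in ("drug", "protein"):
        for dim in DIM_TAGS:
            if kind == "drug":
                variant_cfg = replace(
                    config, drug_dims=tuple(d for d in config.drug_dims if d != dim)
                )
            else:
                variant_cfg = replace(
                    config,
                    protein_dims=tuple(d for d in config.protein_dims if d != dim),
                )
            label = f"exclude:{kind}-{dim}"
            results.append(AblationResult(label, _train_and_evaluate(bundle, variant_cfg)))
    return results


def run_pairwise_study(
    bundle: DataBundle,
    base_config: Optional[FusionConfig] = None,
    normalize: bool = True,
) -> List[AblationResult]:
    """Single-dimension concatenation: nine (drug dim, protein dim) pairs
    without fusion blocks, plus the full fusion model (10 rows)."""
    config = base_config or FusionConfig()
    for key in config.keys:
        if key not in bundle.embeddings:
            raise ValueError(f"missing embedding set for {key[0]} {key[1]}")
    results = []
    for ddim in DIM_TAGS:
        for pdim in DIM_TAGS:
            pair_cfg = replace(
                config,
                drug_dims=(ddim,),
                protein_dims=(pdim,),
                use_fusion_blocks=False,
                normalize_inputs=normalize,
            )
            label = f"pair:{ddim}+{pdim}"
            results.append(AblationResult(label, _train_and_evaluate(bundle, pair_cfg)))
    results.append(AblationResult("full", _train_and_evaluate(bundle, config)))
    return results


def results_table(results: List[AblationResult]) -> pd.DataFrame:
    """Flatten study results into a table mirroring the published layout
    (variant, MSE, CI, r_m^2, AUPR)."""
    labels = [r.variant for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("variant labels must be unique within a study")
    rows = [
        {
            "variant": r.variant,
            "mse": r.report.mse,
            "ci": r.report.ci,
            "rm2": r.report.rm2,
            "aupr": r.report.aupr,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
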