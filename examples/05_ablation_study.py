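"""Leave-one-embedding-out ablation on a benchmark whose signal lives only
in the 3D embeddings.

Each variant retrains the model on identical splits; the two 3D exclusions
should show the largest MSE because they remove the only informative input
on their side.
"""

from dtafusion import (
    DataBundle, FusionConfig, SplitSpec, SyntheticSpec,
    generate_embeddings_and_affinity, results_table, run_exclusion_study,
)

spec = SyntheticSpec(
    n_drugs=80, n_proteins=50, density=0.5, noise_sd=0.25, seed=2,
    drug_informativeness=(0.0, 0.0, 1.0),
    protein_informativeness=(0.0, 0.0, 1.0),
)
embeddings, table = generate_embeddings_and_affinity(spec)
bundle = DataBundle(table=table, embeddings=embeddings,
                    split=SplitSpec(seed=2), threshold=7.0)
config = FusionConfig(block_dense_width=64, head_widths=(128, 128, 64),
                      max_epochs=150, early_stop_patience=40, seed=2)

results = run_exclusion_study(bundle, config)
df = results_table(results).sort_values("mse")
print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print("\nRows are sorted by MSE: variants that still contain both 3D "
      "embeddings cluster at the top; excluding either 3D embedding removes "
      "the signal on that side and MSE rises toward the affinity variance.")
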