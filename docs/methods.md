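# Methods

## The prediction problem

Drug-target affinity (DTA) prediction is treated as regression: given a
small molecule (SMILES) and a protein (amino-acid sequence), predict a
continuous binding strength. Affinities arrive on one of several scales,
carried as explicit metadata and never auto-detected:

* `Kd_nM` — dissociation constants in nM; the transform
  pKd = −log10(Kd/10⁹) maps them to the familiar log scale on which the
  dense kinase panels span roughly [5, 10] (10 µM → 5, 1 nM → 9);
* `pKd` — already transformed;
* `KIBA_score` — the composite kinase-inhibitor score integrating Ki, Kd
  and IC50, living roughly in [9, 16];
* `arbitrary` — anything else.

For classification-style evaluation (AUPR), affinities are binarized at a
scale-specific threshold: 7 on the pKd scale, 12.1 on the KIBA scale.
Values exactly at the threshold count as positive (the `ge` rule; the
boundary convention is not standardized, so a strict `gt` flag exists).

## The fusion network

Each selected embedding dimension (drug 1D/2D/3D, protein 1D/2D/3D) is
L2-normalized — every input enters as a unit vector, so dimensions of very
different widths (100 to 1280) and norms contribute at a common scale — and
passes through its own dense + ReLU block (default 1024 units). Block
outputs concatenate into the fused drug and fused protein embeddings; their
concatenation feeds a head of three fully connected layers (defaults 1024,
1024, 512), each followed by dropout (0.3), ending in a single linear
neuron. Training minimizes MSE with Adam (η = 1e-4), batch size 64, at most
500 epochs with early stopping.

Decisions where the design was genuinely open:

* **Early stopping** monitors validation MSE with patience 20 and restores
  the best weights. Without a validation table, training runs the full
  epoch budget.
* **Concatenation order** is fixed (drug 1D, 2D, 3D, protein 1D, 2D, 3D)
  purely for reproducibility; the architecture is otherwise symmetric.
* **Dropout placement**: after each head layer only. A `block_dropout` flag
  additionally applies it after the per-dimension blocks; in every setting
  we measured it did not help, so it defaults off.
* **Zero vectors** pass through L2 normalization unchanged (with a logged
  warning) instead of raising: a molecule whose tokens are all unknown to
  the skip-gram vocabulary legitimately produces a zero 1D embedding.
* **Output-bias initialization** at the training-target mean: with a small
  learning rate, Adam would otherwise spend most of the epoch budget
  drifting the output bias toward the affinity scale's center.
* **Blocks are independent** per dimension (no parameter sharing), matching
  the three parallel per-dimension paths of the architecture.
* Weights use He-uniform fan-in initialization from the config seed;
  computation is float32 on CPU.

## Featurizers

The six embedding slots can be filled by the built-in desk-scale
featurizers or by precomputed files (tab-separated `id v1 ... vW`).
Conventional widths: drug 100/300/512, protein 100/768/1280.

* **Drug 1D** — circular substructure tokens (Morgan atom environments,
  radius 0..1 by default, one token per atom per radius in canonical atom
  order) embedded by skip-gram with negative sampling; the molecule vector
  is the sum of its token vectors (mean optional). Sum aggregation makes
  the embedding additive over token multisets, which the tests exploit.
* **Drug 2D** — a graph isomorphism network: per layer,
  h_i ← MLP((1+ε)·h_i + Σ_{j∈N(i)} h_j); sum (or mean) readout; final MLP
  to the output width. Atom attributes: element one-hot (C, N, O, S, F, P,
  Cl, Br, I, other), degree one-hot (0–5), aromaticity. Bond attributes:
  single/double/triple/aromatic one-hot. Sum aggregation over neighbor
  multisets makes the embedding exactly invariant to node relabeling.
* **Drug 3D** — message passing over bonded pairs where the geometry enters
  only through squared interatomic distances, so the embedding is exactly
  invariant to proper rigid motions of the conformer while remaining
  sensitive to bond lengths and conformational change. Conformers come
  from the structure kit's distance-geometry embedding (seeded), with a
  deterministic 3-D spring layout as fallback for graphs without a parsed
  molecule.
* **Protein 1D** — overlapping 3-mers (window count = L−k+1) embedded by
  the same skip-gram machinery, summed.
* **Protein 2D** — a small multi-head self-attention encoder: residue
  embeddings plus sinusoidal positional encodings, per layer
  softmax(QKᵀ/√d_k)V per head, heads concatenated and mixed by W_o, mean
  pooling, linear projection to the output width. This is a deliberately
  compact transformer encoder with seeded random parameters; attention
  rows sum to one and the uniform-attention limit (zeroed query/key) is
  covered by tests. Sequences longer than 2,600 residues are tail-truncated
  with a warning (the longest kinase-panel sequence is 2,549).
* **Protein 3D** — file adapter only. Structure-model embeddings are
  large-model outputs by nature; the slot accepts any fixed-width vector
  file.

The graph-based featurizers run with **seeded random frozen parameters**:
the fusion head consumes fixed-width vectors, and for these architectures
the structural information (neighborhood multisets, distances) is carried
by the message-passing structure itself. Pretraining at corpus scale is out
of scope, and end-to-end backpropagation through per-molecule featurizers
is deliberately not supported — featurization is a precompute step
producing embedding sets, which keeps every downstream experiment (splits,
ablations) comparable across shared embeddings.

## Metrics

* **MSE** — mean squared residual, also the training loss.
* **CI** — concordance index: over all pairs with distinct true
  affinities, the fraction ranked correctly by the predictions (prediction
  ties score ½; pairs tied in truth are excluded from the denominator, the
  dominant convention). Implementation is a vectorized upper-triangle
  count; tests compare it against an O(n²) brute-force oracle and a
  survival-analysis library.
* **r_m²** — r²·(1 − √|r² − r₀²|) with r² the squared Pearson correlation
  (with intercept) and r₀² the coefficient of determination of the
  through-origin least-squares fit of predictions on observations. This is
  the original single-variant form; the averaged/delta variants are not
  implemented. Always ≤ r², and 1 only for a perfect fit.
* **AUPR** — average precision (step summation, no linear interpolation,
  ties broken by stable descending-score order), computed on thresholded
  labels.
* **McNemar** — exact two-sided binomial p-value on the discordant counts
  when b+c < 25, else the continuity-corrected chi-square approximation.
  At exactly balanced discordance the two-sided exact p caps at 1, where
  the chi-square approximation cannot follow; elsewhere near the cutover
  the two branches agree within 0.02. McNemar applies to binarized
  predictions only; for continuous metrics a paired-bootstrap test is
  provided as the documented alternative.

Fold-wise standard deviations of CI, r_m² and AUPR are computed from
per-fold (or per-repeat) predictions when supplied; the pooled point
metrics always come from the full test set.

## Splits and studies

Splitting is by interaction row (random pair split): round(0.2·N) test
rows, the rest training, partitioned into 5 validation folds — so the same
drugs and proteins appear on both sides of the split, and only *pairs* are
held out. Cold-entity generalization is a different, harder task and is not
what the protocol measures; optional `cold_drug` / `cold_protein` split
modes hold out whole entities with all their rows for users who want it.
All indices are reproducible from a single seed.

The two ablation protocols retrain the model per variant on identical
splits and seeds:

* **Exclusion** — the full six-input model plus six variants each missing
  one embedding (head input shrinks by one block; capacity is not
  re-matched).
* **Pairwise** — all nine (drug dim, protein dim) single-dimension pairs
  with the fusion blocks bypassed (raw concatenation into the head), plus
  the full model as reference. Inputs remain L2-normalized by default so
  that a width-100 and a width-1280 embedding enter comparably; a flag
  disables this.

## Synthetic benchmark

The generator produces fully self-contained benchmarks shaped like the
public kinase panels: drugs drawn from a pool of small valid structures,
random protein sequences with lengths uniform in [200, 1500], and an
interaction table of controllable density (a dense 68×442-style panel or a
sparse large one).

Signal structure: each drug carries a latent u_i, each protein a latent v_j
(standard normal, width 8 by default — bounded-range affinity panels are
approximately low-rank, and 8 keeps the interaction genuinely
multi-dimensional at desk scale). The noiseless affinity is the bilinear
form ⟨u_i, v_j⟩, affinely rescaled so that mean ± 2.5 sd of the dot product
spans the affinity range (≈99% of pairs inside the range; scaling by the
sample min/max would tie the affinity scale to the table size), plus
Gaussian noise. The resulting distribution is symmetric about the range
center — unlike real panels, which pile up at the weak-binding floor. Each
of the six embeddings is w·(latent @ P) + (1−w)·ε with a fixed seeded
random projection P to the conventional width, independent noise ε, and
per-dimension informativeness w ∈ [0, 1]. Independent noise across
dimensions gives exclusion ablations a well-defined expected ordering.

A bilinear target is deliberately **not** linear in any concatenation of
embeddings: recovering it requires the model to combine drug-side and
protein-side information multiplicatively, which is precisely the claim a
fusion architecture makes. Two consequences worth knowing:

* L2 normalization discards the latent magnitude ‖u‖ from every individual
  embedding (a normalized random projection depends only on the latent
  direction). The network can still recover per-entity magnitudes because
  the entity sets are finite and the pair split is transductive — the
  direction identifies the entity and its magnitude is learnable from its
  training pairs — but this memorization is statistically expensive and
  dominates the remaining test error at desk-scale sample sizes.
* With informativeness 0 every embedding is pure noise and test
  concordance has no signal to exploit; trained models sit at CI ≈ 0.5,
  which the no-signal control checks.

What the generator does **not** emulate: real chemistry or biology beyond
shape (repeated pool structures stand in for distinct drugs), measurement
heterogeneity, assay censoring (real panels truncate at the weakest
measurable affinity), or cold-entity structure. Passing tests on this
benchmark demonstrates that the architecture, training loop, metrics and
ablation harness behave as designed — not that the model reaches
literature-level accuracy on real panels, which requires the large
pretrained embedding models these desk-scale featurizers stand in for.

## Scaled-down study sizes

The bundled studies run at reduced widths and sizes so a full pass stays
within minutes on one CPU: signal recovery uses a 200×100 panel at 30%
density with block width 128 and a (512, 512, 256) head, trained per
cross-validation fold (≤200 epochs, patience 30) with fold-averaged test
predictions; the ablation orderings use a 100×60 panel with block width 64;
the chance-level control uses 60×40 panels over 10 seeds. The per-fold
prediction average is the cross-validation protocol's natural test
predictor and is what the recovery study reports.

## Numerical notes and degenerate inputs

* CI is undefined (error) when all true values coincide; r_m² when either
  sequence is constant or n < 3; AUPR when labels are single-class.
  `evaluate` propagates these with the failing metric named.
* McNemar with no discordant pairs returns p = 1 with a warning.
* Duplicate (drug, protein) pairs, non-finite affinities, and non-positive
  Kd values are rejected at table construction.
* Embedding files must be rectangular; ragged rows and duplicate ids raise
  errors citing the line.
* All randomness flows from explicit integer seeds through a hash-based
  fan-out, so no two components share a stream and every artifact is
  bit-reproducible given its seed.

## Known limitations

* The featurizers are desk-scale stand-ins: frozen random GIN/3D networks
  and a small attention encoder capture structure through architecture,
  not learned chemistry; users wanting literature-level accuracy should
  supply precomputed embeddings from large pretrained models through the
  file adapters.
* The fusion network at desk-scale sample sizes does not reach the
  noise-floor ceiling on the bilinear benchmark (see the recovery study's
  reported CI/MSE); closing that gap requires either more interaction data
  or a model class with an explicit multiplicative interaction.
* McNemar on regression models depends on a binarization rule; p-values
  for continuous metrics are protocol-dependent and the paired bootstrap
  is the safer tool.
* Only one conformer per molecule is used for the 3D embedding.
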