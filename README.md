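# gofuse

Multi-modal Gene Ontology (GO) term prediction for proteins. `gofuse`
layers three sources of GO knowledge — term **text descriptions**, the
protein's **species** and the GO **relation graph** — on top of pluggable
per-residue sequence embeddings produced by any protein language model
(PLM), and evaluates predictions with CAFA-style metrics. A synthetic
cohort generator with planted, recoverable signal makes the whole
pipeline testable at desk scale, with no GPU and no external data.

It is written for computational biologists who already have frozen PLM
embeddings for their proteins (the linear-probing setting) and want the
extra accuracy that GO-side knowledge provides, without fine-tuning the
PLM itself.

## The model

Proteins are annotated in three GO aspects — biological process (BP),
molecular function (MF), cellular component (CC) — each a DAG of terms
connected by `is_a`/`part_of` edges; one model is trained per aspect.
Given a protein's residue-level embedding X_seq ∈ R^{d×l} and candidate
term-description embeddings X_text ∈ R^{d′×l′}:

1. **Text alignment.** Each description is projected to width d by a
   learnable linear map and scored by the mean per-position cosine with
   the sequence, cos(x_text, x_seq) = (1/K) Σ_k x_k_text·x_k_seq /
   (‖x_k_text‖‖x_k_seq‖), K = min(l, l′). Descriptions with positive
   relevance (best first, capped at top-k) are concatenated with the
   sequence after sinusoidal positional encoding, and fused by
   parameter-free multi-head dot-product attention,
   softmax(X_cat X_catᵀ/√d_h) X_cat over 8 head slices, in fragments of
   at most 512 positions, followed by a position-wise feed-forward
   network with a residual connection.
2. **Taxonomy encoding.** The fused features are mean-pooled over all
   l + l′ positions to a protein-level vector X_pro, and the species code
   is mixed in through a learned label-encoding table:
   X_mix = LE(species)·w_tax + X_pro, with w_tax = 0.1.
3. **Graph-convolution head.** Scores for the γ retained terms are
   F(X_mix) = σ( (ReLU(X_mix W₁ + b₁) W₂ + b₂) Â W_A ), where
   Â = D^{-1/2}(A+I)D^{-1/2} is the normalized adjacency of the pruned
   GO subgraph. Terms annotated fewer than a frequency threshold
   (default 21, ≈ 0.015 % of a CAFA5-sized cohort) are pruned, with each
   pruned node's parents reconnected to its children so hierarchy paths
   survive.

All learnable parts (projection, FFN, species table, head) are trained
jointly with element-wise binary cross-entropy under Adam (β₁ 0.9,
β₂ 0.999, ε 1e-9), initial learning rate 2e-4 decayed ×0.6 every 5
epochs, batch size 16. Evaluation reports protein-centric **Fmax** (CAFA
convention, threshold grid 0.01…1.00), example-based **F1** at τ = 0.5,
micro-**AUPR** and **MCC**. Every module has an ablation switch, so the
contribution of each knowledge source is measurable.

## Worked example

`examples/02_train_and_evaluate.py` generates a 200-protein synthetic
cohort (15 BP terms, planted signal), trains the full pipeline for 10
epochs and evaluates on the held-out split:

```
train/test: 180/20 proteins, γ = 15
BCE loss: 1.121 (epoch 1) -> 0.067 (epoch 10)
held-out Fmax 0.998 at τ*=0.38, F1 0.994, AUPR 1.000, MCC 0.986
```

The loss trace shows the joint optimization converging; the four metrics
say the planted protein→function signal is recovered almost perfectly on
unseen proteins. `examples/03_ablation_study.py` runs the module
ablations on the default 500-protein cohort:

```
          full: AUPR 0.9686  Fmax 0.9000  F1 0.8877
 relation_only: AUPR 0.9424  Fmax 0.8718  F1 0.8633
     text_only: AUPR 0.9340  Fmax 0.8557  F1 0.8337
 taxonomy_only: AUPR 0.9088  Fmax 0.8236  F1 0.8079
          none: AUPR 0.9088  Fmax 0.8225  F1 0.8079
```

Every knowledge module helps, the relation graph most, taxonomy least —
`none` is the bare linear probe on mean sequence embeddings. The other
examples cover cohort simulation, the pruning-threshold sweep, the
packaged benchmark summaries and the protein-pair interaction matching
statistic.

A thin CLI mirrors the library:

```bash
gofuse simulate scratch/cohort --n-proteins 200 --gamma 15
gofuse train scratch/cohort scratch/run --aspect BP --threshold 0 --epochs 10
gofuse evaluate scratch/cohort scratch/run scratch/run/model_BP --threshold 0
```

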