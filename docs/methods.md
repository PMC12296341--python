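# Methods

## Problem setting

GO-term annotation is hierarchical multi-label classification: a protein
i is described by a binary vector Y_i ∈ {0,1}^γ over the retained terms
of one GO aspect (BP, MF or CC), and the model learns a map from a mixed
feature embedding X_mix to term scores. The package assumes frozen
upstream embeddings ("linear probing"): an external PLM supplies
per-residue sequence embeddings and an external biomedical language
model supplies per-token term-description embeddings; both enter through
the archive interface and are never computed here. One model is trained
per aspect, because the three subontologies are disjoint DAGs with
different sizes and statistics.

## Label space construction

The ontology is read from OBO (via `obonet`), keeping only non-obsolete
terms and `is_a`/`part_of` edges; `regulates` and other relations are
out of scope. Terms are ordered lexicographically by GO id, which fixes
the column order of every matrix and makes runs reproducible.

Pruning removes terms with fewer annotations than a frequency threshold
(default 21; `--auto-threshold` recomputes 0.015 % of the actual cohort
size). A pruned node is *contracted*, not just deleted: its parents are
connected directly to its children, so ancestor reachability among
retained terms is exactly the original reachability restricted to
retained endpoints. This matters because the prediction head consumes
graph structure; an induced subgraph would fragment the DAG and starve
the graph convolution. Annotations to pruned terms are dropped (not
remapped to ancestors).

The graph enters the head as Â = D^{-1/2}(A+I)D^{-1/2}, built on the
undirected union of the kept edge types with self-loops; this symmetric
normalization is the standard graph-convolution convention, keeps the
spectrum in [-1, 1] and is enforced exactly symmetric in floating point.

True-path ancestor propagation of annotations is available
(`--propagate`) but off by default: CAFA-style label files are
conventionally pre-propagated, and double propagation would distort
term frequencies.

## Fusion modules

**Relevance filter.** Candidate texts are all retained terms'
descriptions. Each text is projected d′→d and scored by the mean
per-position cosine against the sequence, summing over
K = min(l, l′) positions — the only well-defined range when the two
lengths differ. Zero-norm positions contribute cosine 0. Texts with
score > 0 are kept, sorted descending (ties broken by GO id) and capped
at `top_k_texts` = 5; an unbounded concatenation would make attention
cost quadratic in the number of relevant texts. Because the projection
is trained jointly, the selection is recomputed at every forward pass.

**Attention fusion.** Sinusoidal positional encodings are added to the
sequence and each projected text; the blocks are concatenated along
positions and packed into fragments of ≤ 512 positions (a text block is
never split across a fragment boundary unless it alone exceeds the cap,
but may share a fragment with preceding positions). Attention is
deliberately parameter-free — the concatenation serves as query, key and
value, softmax(XXᵀ/√d_h) X per head — with 8 heads realized as
contiguous d/8 row slices; the learnable capacity sits in the text
projection and the position-wise FFN (hidden width 2d, ReLU, residual
connection). A config switch adds learned per-head Q/K/V projections for
comparison. Dropout 0.3 is applied to the attention output during
training only.

**Taxonomy encoding.** Pooling is the arithmetic mean over all sequence
and text positions. The species enters as X_mix = LE(s)·w_tax + X_pro
with a learned (n_species+1)×d table; row 0 is the reserved
unknown-species code, and out-of-vocabulary ids fall back to it rather
than erroring, since new species at inference time are expected. Only
the leaf rank (species) is encoded — no taxonomy-tree traversal. w_tax
is fixed at 0.1 (an optional learnable-scalar mode exists); the table is
initialized N(0, 0.02²) so the taxonomy contribution starts small
relative to pooled embeddings. Setting w_tax = 0 reproduces the
no-taxonomy ablation bitwise.

## Prediction head and training

The head is a two-layer perceptron (hidden width 2d) into γ logits,
followed by one graph-convolution step: logits H (b×γ) are
right-multiplied by Â — so the smoothing acts on the label axis — and
then by a dense γ×γ output map W_A, with a final sigmoid. b₂ is added
before the smoothing, following the printed composition of the model.
The convolution is applied once, not stacked. W₁/W₂ use Kaiming
initialization; W_A starts at identity plus N(0, 0.01²) noise so early
training approximates the plain MLP probe. A diagonal-W_A memory-guard
option exists for very large γ. With Â = I and W_A = I the head is
exactly the MLP linear probe, which is also the `none` ablation.

Training minimizes mean element-wise BCE (computed on logits for
numerical stability) with Adam (β₁ 0.9, β₂ 0.999, ε 1e-9), initial
learning rate 2e-4 decayed ×0.6 every 5 epochs (variant: 4e-5, ×0.5),
batch size 16, 30 epochs by default. All modules — text projection, FFN,
species table, head — are optimized jointly end-to-end; gradients come
from the package's reverse-mode autodiff engine (`gofuse.autodiff`), a
tape-based tensor wrapper over numpy sufficient for these small dense
models. Given a seed and a fixed thread count, training is deterministic
to 1e-6 in the loss trace.

Train/test splitting is seeded and enforces that every retained term has
at least one positive training example: after the random split, each
uncovered term's lowest-indexed carrier protein is moved to the train
side. The default test fraction is 0.1.

## Evaluation

Fmax follows the CAFA protein-centric convention: on the grid
τ = 0.01…1.00 (step 0.01), precision is averaged over proteins with at
least one prediction at τ, recall over all proteins with at least one
true term; Fmax is the maximum harmonic mean, ties resolved toward the
smaller τ, and 0 when no threshold yields predictions. Example-based F1
and MCC are evaluated at τ = 0.5; a protein with neither predictions nor
true terms contributes F1 = 1 (configurable, recorded in the report).
AUPR is micro-averaged over all n·γ protein-term pairs using step
integration — robust under the extreme label sparsity of GO spaces.

The pair-matching statistic keeps proteins whose per-protein precision
at τ = 0.5 is ≥ 0.75, pairs those whose positive predicted term sets
have Jaccard similarity ≥ 0.70 (similarity on positives only, because
the label space is sparse), and counts pairs whose score in a local
interaction-confidence table (0–99.9) is ≥ 70. The operating threshold
for the precision floor is recorded in the output, as the convention is
not universal. The confidence table is always a local file — no network
calls.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline exploits, and
nothing more:

- a rooted random DAG per aspect (each non-root has 1–2 parents drawn
  from earlier nodes, ~20 % `part_of`), acyclic by construction;
- labels drawn at leaf terms (per-leaf rate 0.12, at least one leaf per
  protein) and propagated to ancestors, so generated labels are
  true-path-consistent — the hierarchical coherence the graph head
  presupposes;
- sequence embeddings: a label-driven mean shift signal·(G y_i) — G a
  fixed random d×γ mixing matrix — broadcast over l ~ U{20..60} residues
  plus N(0, noise²) noise, so the pooled embedding is linearly
  predictive of function, as PLM embeddings empirically are;
- term texts tied to the *same* mixing matrix (column j projected to d′,
  tiled over l′ ~ U{5..15} tokens, scaled by `text_relevance`), so the
  cosine filter has genuine signal to find;
- species ids (10 by default) modulating the prevalence of 20 % of leaf
  terms (×2 for preferred species, ×0.4 otherwise), a weak but real
  taxonomic cue.

Defaults: n = 500 proteins, γ = 30 per aspect, d = 64, d′ = 48,
signal 5, noise 1, seed 0 — sized so a full train-and-evaluate cycle
runs in well under a minute on one CPU. The ablation experiment
(`run_ablations`, also used by `scripts/acceptance.py`) trains each
variant for 10 epochs on this cohort; by then the loss has plateaued at
this scale and the five variants separate cleanly.

What passing these tests shows: the wiring is correct — each module
recovers the kind of signal it was designed for, and removing it costs
measurable held-out AUPR. What it does not show: performance on real
embeddings, whose geometry (anisotropy, length effects, amino-acid
statistics) and whose GO topology (tens of thousands of terms, heavy
tails) the generator deliberately does not imitate.

## Known limitations

- No PLM/LM inference and no adapter fine-tuning of the upstream model;
  config keys for the latter are reserved but unimplemented, as it
  requires the real PLM.
- Dense W_A is γ×γ: at CAFA-scale label spaces (γ ≈ 7,600 for BP) this
  is memory-heavy; the diagonal option trades capacity for memory.
- The candidate text set is the full retained label space; no shortlist
  index is built, so text scoring is O(γ) per protein per step.
- Training is single-threaded CPU numpy; it is sized for desk-scale
  cohorts, not for 10⁵-protein corpora.
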