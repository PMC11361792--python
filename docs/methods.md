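# Methods

## The prediction problem

An mRNA transcript can occupy several subcellular compartments at once;
experimentally curated localization data for human mRNAs therefore forms a
multi-label problem over six compartments: nucleus, exosome, cytosol,
ribosome, membrane and endoplasmic reticulum (ER). `rnaloc` predicts a
probability for each compartment from two views of a transcript:

* **the primary sequence**, summarized by two fixed-length composition
  vectors — k-mer frequencies for k = 1..5 (4 + 16 + 64 + 256 + 1024 = 1364
  dimensions) and CKSNAP, the composition of k-spaced nucleotide pairs for
  gaps 0..5 (16 × 6 = 96 dimensions); and
* **the secondary structure**, represented as a graph with one node per base,
  backbone (`adjacent`) edges between consecutive bases and `base_pair`
  edges from the stack-matched brackets of a dot-bracket string. Each node
  carries a 10-dimensional feature vector: one-hot over (A, C, G, U, N), the
  NCP chemical-property triple, the EIIP pseudopotential scalar, and ANF,
  the accumulated frequency of the base within its prefix.

The motivation for the structure view is biological: localization is often
directed by cis-acting elements — frequently stem-loops — bound by RNA-binding
proteins, so the shape of the molecule carries signal the composition vectors
cannot.

## Model

Four parallel extractors each emit a 128-dimensional embedding:

* two sequence branches (one per composition vector): an MLP maps the vector
  to `attn_tokens × attn_dim` values (default 16 × 32) viewed as a token
  sequence, multi-head scaled-dot-product self-attention
  (softmax(QKᵀ/√d_k)V per head, concatenated through an output projection)
  mixes the tokens, and the mean-pooled result is projected to 128. The
  tokenization is a design choice: self-attention needs a token axis and a
  flat composition vector has none, so the MLP's output is reshaped into
  tokens. Heads default to 4.
* two graph branches (one per structure source): a stack of GIN layers,
  h′_v = MLP((1+ε)·h_v + Σ_{u∈N(v)} h_u), with a learnable ε per layer and
  batch normalization inside each update MLP (the canonical GIN
  construction), followed by a set2set readout (a recurrent attention query
  producing a 2d-dimensional, permutation-invariant graph vector over d=64
  node embeddings, 3 processing steps) and a projection to 128. GCN and GAT
  layers are selectable alternatives; GIN is the default.

The concatenated embeddings (512 for the full model) pass through a
two-layer head whose second layer applies a sigmoid, giving six independent
probabilities. Ablation flags disable any branch; a sequence-only model
concatenates 256 dimensions.

**GIN depth.** The default is 4 layers. The receptive field of a k-layer GIN
is a k-hop neighborhood, and the graph feature that distinguishes a folded
localization element is a long run of stacked pairs: planted stems produce
ladders of 20–40 stacked pairs while maximum-base-pairing folds of random
sequence rarely stack more than ~7. Two layers cannot see past a stack of
~2 and demonstrably fail to separate such graphs; four layers can, at about
twice the compute.

## Training

The objective is summed binary cross-entropy over the six labels (the
negative log-likelihood of six independent Bernoullis), averaged over the
mini-batch, with probabilities clamped to [1e-7, 1−1e-7]. Defaults follow
the published recipe: Adam at learning rate 3e-4, dropout 0.1, 200 epochs,
an 8:1:1 train/validation/test split (floor allocation, remainder to
training). There is no early stopping; the weights with the lowest
validation loss are additionally kept as a non-destructive best checkpoint.
Mini-batches of variable-size graphs are disjoint unions with a per-node
graph index; unmasked neighbor aggregation runs through a symmetric sparse
adjacency. Class imbalance is not reweighted by default (optional per-label
positive weights are exposed).

Models compute in float32 by default (`ModelConfig.dtype`); the engine
preserves float64 when given float64 parameters, which the oracle tests use
so that 1e-9 comparisons against reference implementations are meaningful.

## Structures

Structures arrive from a dot-bracket file, from an external folding tool
(RNAfold/LinearFold adapter: sequence on stdin, first dot-bracket line of
stdout, energy suffix stripped), or from the built-in folder — a Nussinov
maximum base-pairing dynamic program (AU, GC, GU pairs; hairpin loops ≥ 3;
deterministic traceback that leaves j unpaired when optimal, otherwise pairs
j with the smallest eligible k). The built-in folder maximizes pair count,
not free energy; it exists so the whole pipeline runs without external
software, and its folds are correspondingly denser and noisier than
thermodynamic predictions. Pseudoknot-layer brackets in input files are
treated as unpaired. The model consumes two structure sources; when only one
is present it feeds both graph branches (logged).

## Evaluation

Six multi-label metrics: example-based accuracy (mean per-sample Jaccard
index between true and thresholded label sets, 1 when both are empty),
hamming loss, one-error, coverage (max 1-based rank of a true label minus
one), ranking loss (wrongly ordered true/false pairs, ties ½) and average
precision (mean precision at each true label's rank). Ranks are by
descending probability with ties broken by ascending label index, so results
are deterministic. Samples with no true label are excluded from the four
ranking metrics and kept in Acc_exam/hamming. Per-label accuracy and MCC are
reported alongside; MCC is defined as 0 when a confusion marginal is zero.
The binarization threshold defaults to 0.5 (p ≥ t maps to 1) and is
config-exposed, scalar or per-label.

## Interpretation

Edge importance is a learned mask: one logit per undirected edge of a
record's structure graph (applied to both message directions), squashed by a
sigmoid and multiplied into that branch's messages. The mask is optimized
(Adam, 0.1; 100 steps by default) to keep the record's positive labels
predicted while an L1 term (weight 0.005) shrinks the mask and an entropy
term (weight 0.1) pushes it toward binary. Scores are the final mask values
in [0, 1], reported with edge type and 1-based positions. The top-k edges
(default 300) induce a subgraph whose connected components of ≥ 3 bases are
reported as substructures, written with `==` for base pairing and `<->` for
backbone neighbors; their per-compartment frequencies are emitted under both
a per-record and a per-edge normalization, since either reading of
"proportion" is defensible. Node-feature-group importance (one-hot, NCP,
EIIP, ANF) is measured by occlusion — zeroing a group's columns and
recording the mean absolute change in each compartment's probability —
which is deterministic.

## Synthetic benchmarks

The generator emulates a localization corpus at desk scale: i.i.d. random
sequences (default 220–320 nt; real transcripts reach tens of kilobases),
with labels driven by planted elements and marginals echoing the strong
compartment imbalance of curated data (exosome most frequent at 0.80 down to
ER at 0.15). Two element types:

* **motif rules** insert a fixed 6-mer (2 copies by default) into positive
  records and scrub chance occurrences from negatives — signal the
  composition vectors can decode;
* **hairpin rules** insert arm + loop + reverse-complement(arm) with a fresh
  random arm per record (stem 40, loop 4 by default); negatives receive a
  shuffled decoy of the same insert. Because the arm is re-drawn per record
  and the decoy preserves base composition, the sequence view carries no
  consistent signal for these labels — only the folded ladder does. This is
  the desk-scale analogue of structure-mediated localization elements.

Elements are placed without overlap by drawing positive labels first and
distributing the total slack randomly among the gaps, so placement always
succeeds when the elements fit; records too short for all elements drop the
widest (label forced to 0, logged). Labels are otherwise independent given
their elements — no label-correlation structure (a documented
simplification). The generator does not emulate evidence codes, redundancy
structure, length tails, or thermodynamic folding; passing tests on it shows
the pipeline recovers planted signal under these idealized conditions, not
that the paper-scale benchmark numbers are reproduced.

## Desk-scale experiments (`rnaloc.experiments`)

* **Overfit capacity**: 20 benchmark records, the standard 200-epoch recipe
  (batch 8). Reported is the final model's training-set loss in eval mode —
  the fit actually achieved, without dropout/batch-statistic noise (the
  running epoch loss is reported alongside). Typical value ≈ 0.008.
* **Multi-view comparison**: n = 200, full model vs sequence-only ablation,
  three training seeds on a fixed benchmark. Both models train a fixed 50
  epochs (batch 4, learning rate 1e-3 — an optimization setting for a corpus
  ~80× smaller than production scale) and the final models are compared on
  validation Acc_exam, mirroring the fixed-epoch protocol under which the
  ablation is meaningful. Checkpoint selection by validation loss is not
  used here: on this task validation loss does not track Acc_exam once the
  structure signal is learned.
* **Interpretation recovery**: a graph-only model trained on a single
  hairpin-driven label (stem 20, 90–130 nt records); the planted window's
  pair edges must out-score background edges under the learned mask for a
  majority of explained records, across three mask seeds.

Problem sizes were chosen so the full battery runs in minutes on one CPU.

## Known limitations

* The built-in folder is a pair-count maximizer; graph branches trained on
  its folds will not transfer to thermodynamic structures without refolding.
* Validation sets of 20 records quantize Acc_exam coarsely; seed-to-seed
  variation of a few samples is expected, which is why comparative claims
  are made over seed majorities.
* On the default benchmark the trained model typically reaches validation
  Acc_exam ≈ 0.6–0.78, limited by the minority labels (membrane, ER) and
  the small validation split; the generator's independence assumptions also
  make label correlations unlearnable by construction.
* Sequences containing long N runs degrade the composition blocks (windows
  with N are excluded from numerator and denominator; blocks with no
  countable window are zero with a warning).
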