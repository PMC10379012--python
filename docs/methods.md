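# Methods

## Overview

`promgraph` predicts whether a fixed-length DNA window centered on a
putative transcription start site (TSS) is a promoter. The model chains
four stages:

1. **Local encoding.** Each window of length *L* becomes a vector of
   7·*L* per-nucleotide features: the fused NCP-ND quadruples (4*L*), the
   EIIP energies (*L*), and the bi-profile Bayes lookups (2*L*).
2. **Similarity graph.** All *m* sample vectors (train and test together)
   are gathered into a nonnegative matrix X, and each row is reconstructed
   as a nonnegative weighted combination of its k nearest neighbors by
   minimising ½‖X − (C∗W)X‖²_F + (μ/2)‖(C∗W)e − e‖² over W ≥ 0 with
   support restricted to the kNN indicator C. The symmetrised support of W
   is the weighted sample graph; connectivity is enforced by a kNN
   backbone plus nearest-pair bridges.
3. **Multi-scale embeddings.** Three node embeddings of the graph are
   concatenated: biased-random-walk skip-gram vectors (node scale),
   leading eigenvectors of the weighted modularity matrix
   B = A − ddᵀ/(2W_tot) (community scale), and truncated-SVD factors of
   positive log-shifted k-step transition matrices Sᵗ, S = D⁻¹A (global
   scale).
4. **Classification.** Local and embedding features are concatenated and
   a gradient-boosted decision-tree ensemble (LightGBM) is fitted on the
   training rows only.

The protocol is deliberately transductive at the graph stage — the graph
and embeddings see every sample — while the bi-profile Bayes profiles and
the classifier are fitted strictly on the training split. Users who
consider the transductive graph a form of leakage can set
`transductive=False`, which builds the graph on training rows only and
attaches each test row to its nearest training samples; this changes the
protocol, never the mathematics.

## Local encodings

* **NCP** maps each base to three binary chemical-property indicators
  (ring structure, hydrogen-bond strength, functional group):
  A=(1,1,1), C=(0,0,1), G=(1,0,0), T=(0,1,0).
* **ND** at position *i* is the frequency of the position's base within
  the prefix 1..*i* — count/position, always in (0, 1].
* **EIIP** substitutes the electron–ion interaction pseudopotential
  energy per base: T=0.1335, A=0.1260, G=0.0806, C=0.1340.
* **BPB** fits, per window position and class, the relative frequency of
  each nucleotide over the *training* records (Laplace pseudocount 1 by
  default — the profiles are brittle at small sample sizes without
  smoothing). A window encodes as its positive-profile lookups followed
  by its negative-profile lookups ("all p⁺ then all p⁻"), so a flat BPB
  index ≥ L always denotes a negative-profile feature.

Feature names are bit-stable (`NCPND_k`, `EIIP_k`, `BPB_k`,
`GraphEmbeddings_k`, 0-based per block) so that ablation tables and
importance outputs are reproducible across runs.

## Graph construction

* `neighborhood_ratio` (default 0.1) sets k = max(1, round(ratio·(m−1)));
  ties in the Euclidean distances break toward the smaller index.
* The multiplicative update
  W ← W ⊙ (XXᵀ + μeeᵀ) / ((C∗W)XXᵀ + μ(C∗W)eeᵀ) runs from seeded
  uniform(0,1] entries on the neighbor support with an ε = 1e−12
  denominator floor; it provably keeps W ≥ 0 and, empirically on random
  problems, never increases the objective (tested to 1e−8 slack).
* μ defaults to 1.0. The row-sum constraint (C∗W)e = e is soft: the
  deviation of row sums from 1 scales like O(1/μ), so tests that verify
  the constraint use μ = 1000.
* Convergence: max-abs elementwise change below `tol` (default 1e−6),
  capped at `max_iter` (default 500). At m ≈ 400 the update typically
  hits the iteration cap with deltas ~1e−5; the resulting W is
  graph-quality converged even when the flag reports otherwise.
* Symmetrisation uses the elementwise max of W and Wᵀ, preserving strong
  one-directional similarities. Disconnected results are repaired by a
  mutual-kNN backbone (`backbone_c` = 3 nearest samples, at the smallest
  positive edge weight already present) plus nearest-pair bridging;
  backbone edges carry the provenance tag `connectivity_backbone`.

## Embeddings

Defaults: node scale — dim 64, p = q = 1, 10 walks per node of length 40,
window 5, 5 epochs, 5 negative samples; community scale — k = 16
eigenvectors; global scale — K = 4 steps × 16 dims. Edge weights are used
throughout (walk biasing, weighted degrees, weighted transitions).

The skip-gram trainer is a vectorised NumPy implementation of SGNS:
unigram^0.75 negative sampling, learning rate decaying linearly from
0.025 to 0.00025, mini-batches with duplicate-index gradient
accumulation. The batch size is capped at 8·m (minimum 256, maximum
4096): with a larger batch a node recurs so often within one
stale-parameter batch that the summed update overshoots and the
parameters diverge. Embedding matrices are deterministic given the seed;
eigenvector and singular-vector signs are fixed by making each column's
largest-magnitude entry positive.

The global scale follows the k-step factorisation recipe: for each step
t the matrix max(log(Sᵗ_ij / colsum_j) − log(1/m), 0) is factored by SVD
and the left factors are scaled by √singular values; rank-deficient steps
are zero-padded to the requested width.

## Classifier

LightGBM with 500 iterations, depth 6 (63 leaves), learning rate 0.05,
single-threaded deterministic mode, and inverse-frequency class weights
when `balance="auto"` — weighting rather than resampling, because the
ensemble stage is expected to carry the imbalanced-data robustness on its
own. The decision threshold is 0.5 with the ≥ convention. The fitted
model snapshots its feature names and refuses to score a differently
named table.

## Synthetic data generator

The generator exists to exercise the pipeline without any external
dataset. Positives are i.i.d. background at GC 0.55 with the TATA-box
consensus `TATAAA` planted (probability `tata_fraction`, default 1) at a
uniform offset 25–35 bp upstream of the TSS; the default 300-bp window
places the TSS at index 249, i.e. the [−249, +50] convention. Negatives
emulate exon/intron sequence as an order-1 Markov chain with stationary
GC 0.45 and persistence 0.25 (P(b|a) = (1−ρ)π_b + ρ·[b=a]) — enough
short-range dependence to be compositionally distinct without making the
task trivial. Every run emits a ground-truth manifest of planted motif
positions, so recovery tests never re-derive truth by scanning.

What the generator does **not** model: CpG islands, initiator or CAAT
elements, TATA-less promoter classes, genomic repeat structure, or
sequencing noise. Passing tests therefore demonstrate that the pipeline
recovers a planted compositional/motif signal at desk scale, not that it
reproduces performance on real promoter corpora.

## Problem sizes used by tests and the acceptance script

End-to-end recovery runs use the 300-bp window with 200 positives + 200
negatives (test fifth held out, stratified). The ablation harness runs
all seven local-encoding combinations and all seven embedding-scale
combinations at a reduced size (100-bp windows, 60+60 balanced and
24+120 imbalanced samples, smaller embedding dims and 150 boosting
rounds), chosen so the 14-combination × 2-condition grid completes in
minutes while preserving the harness semantics.

## Known limitations

* At a few hundred samples the boosted-tree stage cannot fully aggregate
  hundreds of individually weak positional features: a plain naive-Bayes
  log-likelihood readout of the BPB block can outrank the full model on
  the synthetic task. With the larger corpora the method targets, this
  gap closes; at desk scale the held-out AUC of the full pipeline
  plateaus around 0.92–0.95.
* The synthetic similarity graph is only weakly class-assortative
  (~60–78% same-class neighbors), so the embedding block adds little
  signal there and can slightly dilute the local block; on data with
  stronger neighborhood structure the embeddings are the point of the
  method.
* FLNSA cost is O(m²) memory and O(iter·m²·k) time; the implementation
  targets m up to a few thousand, not genome-scale corpora.
* Kappa is implemented in its multi-class form; its binary equivalence to
  2(TP·TN−FP·FN)/((TP+FP)(FP+TN)+(TP+FN)(FN+TN)) is a verified property,
  not an assumption.

## Degenerate inputs and numerical conventions

Metric denominators that vanish (empty margins) return 0 with a warning.
AUC uses midrank Mann–Whitney, exact under ties. The PR curve enumerates
distinct thresholds in descending order, anchored at (recall 0,
precision 1) and truncated once full recall is reached. Ambiguous bases
(N etc.) are dropped with a logged count by default, because every
encoder is defined only over {A, C, G, T}; records of the wrong window
length are always an error.
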