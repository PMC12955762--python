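# Methods

This note documents the models and procedures implemented in foldvec,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic test bed can show.

## TM-score oracle

For chains `q`, `t` with a residue correspondence `{(i, j)}` the score is

    TM = (1 / L_norm) · Σ 1 / (1 + (d_i / d0(L_norm))²)

with `d_i` the CA–CA distance of a corresponding pair after a rigid
superposition, `L_norm` the normalizing chain length, and

    d0(L) = 1.24 · (L − 15)^(1/3) − 1.8   (clamped below at 0.5 Å),

the standard length-dependent scale (the raw formula is negative for
L ≤ 15, hence the clamp).  Both normalizations are reported; `tm_max`,
the larger of the two, is the canonical similarity label used for
training and benchmarks.

**Superposition.**  Kabsch via SVD with the determinant correction, so
reflections are never returned; degenerate (collinear) point sets are
accepted.  Fewer than 3 pairs is an error.

**Maximization.**  The score is non-convex in the superposition, so the
search follows the established fragment-seed strategy: superpose on a
contiguous window of the correspondence, then iterate — keep the pairs
within a distance cutoff, re-superpose on them — until the kept set is
stable, sweeping cutoffs `d0 + {0.5, 1.5, 2.5, 3.5}` Å, and keep the
best full score seen at any visited superposition.  Seed windows are
lengths `{N, N/2, N/4}` (minimum 4) at stride `max(1, N/20)`; for
N ≤ 20 every contiguous window of length ≥ 3 is a seed, which makes the
search exhaustive over its candidate set at small sizes.  The all-pair
window is always among the seeds, so the result is never below the
global-Kabsch score.  The tests compare this search against an
independently written exhaustive maximizer (scipy superpositions, plain
loops) on hundreds of tiny pairs.

**Correspondence is an input, not inferred.**  Sequence-independent
alignment is out of scope; synthetic structures share indices by
construction, and equal-length homologs use the identity correspondence.
Assemblies are compared by concatenating chains under a mapping —
identity, or an exhaustive best permutation for ≤ 8 chains (filtered to
length-compatible permutations) — and scoring the concatenation with the
identity correspondence.

## Synthetic structure generator

The generator produces idealized CA traces, not physical proteins; it
exists so every downstream stage has inputs with known, tunable
ground-truth similarity.

* Helices follow the canonical CA spiral (rise 1.5 Å/residue, 100°
  turn/residue, radius 2.3 Å; consecutive CA ≈ 3.83 Å); strands are
  zig-zags with 3.4 Å rise; coils bridge elements on circular arcs with
  every step kept inside [3.2, 4.2] Å.  Element orientations are drawn
  from the packing seed and re-drawn (bounded) until each junction is
  within coil reach, keeping generation deterministic per seed.
* Hierarchy: folds differ in element lists and layouts; superfamilies
  within a fold share both but are repacked (new orientations, accepted
  when the TM to the fold base lands in 0.30–0.70); families differ by a
  hinge rotation plus light noise (band 0.45–0.85 to the superfamily
  parent); members add isotropic noise of 0.35 Å (band 0.75–0.995 to the
  family parent).  Bands are enforced by rejection-resampling against
  the TM-score oracle (25 draws; the closest candidate is kept if the
  band is never hit).  The defaults produce mean `tm_max` of roughly
  0.96 / 0.70 / 0.28 / 0.16 at the family / superfamily / fold /
  cross-fold levels on the default 48-structure set.
* Sequences are drawn per family with 5% per-member mutations, so family
  members share ≥ 90% identity and unrelated chains share background
  identity only.
* Homomeric assemblies place `n` rigid copies on a ring, either with the
  cyclic `C_n` rotation or as pure translations; placements with any
  inter-chain CA pair below 2.5 Å are rejected with a hint to enlarge
  the radius.  Rings of the same chain at sufficiently different radii
  have assembly TM < 0.5 — genuinely different quaternary structures
  built from identical subunits.

**What the generator does not emulate:** real side-chain packing,
sequence–structure coupling, domain insertions, non-homomeric complexes,
and the length/composition statistics of real folds.  Tests passing on
this bed show the machinery is correct and that training recovers a
known signal; they do not certify accuracy on natural structures.

## Embedding model

* **Geometric residue encoder** (default, frozen): per residue, windowed
  CA–CA distances to ±`window_radius` sequence neighbours (normalized by
  the expected separation 3.8·k), sin/cos of the pseudo bond angle and
  pseudo dihedral, and a one-hot residue type; a seed-generated linear
  map projects to `d_in`.  All features are internal distances/angles,
  so the encoding is exactly invariant to rigid motion.  Dihedrals over
  collinear stretches are ill-defined and reported as zero rather than
  numerical noise.  Only the aggregator is trained; the encoder plays
  the role of a frozen upstream representation, and the adapter contract
  (HDF5 dataset `embeddings` with attrs `chain_id`/`dim`, or headered
  TSV) lets an external protein language model supply residue embeddings
  instead.
* **Aggregator**: optional input projection (present only when
  `d_in ≠ d_model`), `n` transformer encoder layers (post-norm; head
  count `d_model/32`; feed-forward with ReLU), **no positional
  encoding**, summation pooling over residues, then residual blocks of
  two affine maps with ReLU and an identity skip.  Without positions the
  encoder stack is permutation-equivariant and the pooled vector
  permutation-invariant; summation (not averaging) is kept deliberately,
  so embeddings are length-sensitive.  Sequences are processed unpadded
  one structure at a time, so no attention masking is needed.
* Presets: reference 6 × 1536/3072 + 12 blocks (169.97 M parameters by
  the analytic count, never instantiated in tests) and mini
  2 × 64/128 + 3 blocks over `d_in = 32`, which trains on one CPU in
  minutes.
* **Similarity**: ranking always uses the raw cosine; the "predicted
  TM-score" display clamps it to [0, 1].  Since clamping is monotone on
  the ranking-relevant range, it cannot change any benchmark result.
* **Baseline**: the row-wise mean of residue embeddings, kept as the
  no-aggregator comparison point.

The whole network runs on a small in-repo reverse-mode autograd engine
over float64 NumPy arrays (broadcast-aware primitives, last-axis softmax
and layer-norm core, stacked matmul).  Single-threaded float64 makes
training runs bit-reproducible under a fixed master seed.  The forward
pass is verified against an independent straight-line NumPy
implementation, and every primitive against finite differences.

## Training

* Targets: `tm_max` rounded half-up to one decimal — bins
  {0.0, 0.1, …, 1.0}.  Eleven bins reconcile "round to the first
  decimal" with the count of attainable values on [0, 1]; a flag allows
  regressing the raw `tm_max` for ablation.
* Sampling: per batch, every non-empty bin receives an equal quota
  (remainder spread over randomly chosen bins), drawing within bins
  uniformly with replacement; bins absent from the pool are excluded and
  their share redistributed.  This counters the heavy skew of all-vs-all
  pair sets toward dissimilar pairs.
* Validation: a bin-stratified pair holdout (default 2%, at least one
  pair per non-empty bin, never emptying a bin's training side).  AUPRC
  with positives at TM ≥ 0.5 — the conventional same-fold threshold,
  matching the benchmark's FP convention — is computed each epoch and
  the best-epoch weights (earliest on ties) are returned.
* Schedule: Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) with linear warmup from 0
  over the first two epochs, then cosine decay from the peak (default
  3e-4 for the mini preset) to peak/100.
* Mini run sizes: 15 epochs × 1536 pairs in batches of 48 on the
  48-structure default benchmark; chosen so a full training run with
  oracle labelling completes in a few minutes on one CPU while leaving a
  clear margin on the recovery checks (held-out Spearman ≥ 0.6, trained
  AUPRC above the mean-pooling baseline).

## Benchmark statistics

* Labelling schemes: hierarchical classification (family: TP = same
  family, FP = different fold, else ignore; superfamily and fold levels
  analogous, each excluding the finer level), TM thresholds (TP at
  ≥ 0.6/0.7/0.8, FP below 0.5, the gap ignored), and topology
  combinations (TP = identical topology multisets, FP = disjoint
  architecture sets, architecture = the topology string truncated one
  level).  Self-pairs are never labelled; every non-self pair receives
  exactly one label.
* Sensitivity to the first FP is computed per query on descending
  ranked lists, both as a count and as a fraction of the query's TPs;
  the fraction is primary for curves.  Ignore pairs are removed before
  locating the first FP — they neither count nor block.  Queries
  without any TP are skipped (their fraction is undefined).  Score ties
  are broken by target id so the statistic is deterministic.
* Precision–recall pools all labelled unordered pairs; tied scores share
  a threshold and the area is the step sum Σ(Rᵢ − Rᵢ₋₁)·Pᵢ (verified
  against scikit-learn's average precision).
* Split construction: k-fold cross-validation partitions *families*
  (each test fold holds all structures of its families), and the
  superfamily holdout withdraws ⌈fraction·S⌉ whole superfamilies; both
  are deterministic per seed.

## Retrieval

Vectors are L2-normalized at insertion, so cosine is a dot product.
Exact search is a full scan with ties broken by id — a total order used
as the reference.  The HNSW index is built with M = 16 (2M on the base
layer), ef_construction = 200 and diversity-pruned neighbour selection
(a candidate is kept only if it is closer to the query point than to
every already-kept neighbour, padding with nearest skipped candidates);
level assignment uses the standard geometric distribution with
mL = 1/ln M.  Returned similarities are always exact; only the candidate
set is approximate.  On the 10 000-vector clustered test store, recall@10
against exact search is 1.0 at ef_search ∈ {32, 64, 128}.  Store and
index persist to a single HDF5/NPZ file with an embedded manifest.

## Known limitations

* The assembly embedding is invariant to the spatial arrangement of
  identical subunits: rings of the same chain at different radii embed
  identically while their assembly TM is < 0.5.  This degeneracy is
  inherent to chain-wise encoding followed by order-invariant
  aggregation and is surfaced explicitly in tests and examples.
* TM-score under a fixed correspondence can understate the similarity of
  multi-domain chains related by hinge motions; the oracle reports the
  rigid-superposition optimum by design.
* The geometric encoder is a stand-in representation: it carries local
  backbone geometry and residue identity but none of the evolutionary
  signal a protein language model provides, so absolute benchmark
  numbers on this test bed say nothing about performance with a PLM
  front end.
* Exhaustive chain-permutation matching for assemblies is factorial and
  capped at 8 chains.
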