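# Methods

## Model

The embedding network is a 1D residual convolutional trunk over amino-acid
tokens. Input residues are mapped through a learned token table of width
`d` (20 canonical amino acids plus one unknown token onto which X/B/Z/J/U/O
collapse; a single unknown token avoids inventing biochemical priors for
ambiguity codes). Each of `n_blocks` residual blocks computes
`x + Conv2(σ(Conv1(σ(x))))`; both convolutions have `d` input and output
channels and the same odd kernel, with symmetric zero padding of
`(kernel−1)/2` so the output always has one row per residue. The activation
σ is applied before the first convolution of every block, exactly as the
block formula reads. There is no output head and no normalization layer: the
last block's output is the embedding (training consumes raw dot products;
search normalizes explicitly).

Defaults: `d = 256`, 8 blocks, kernel 7, ELU — 7,349,504 learnable scalars
(trunk `8·2·(256²·7 + 256) = 7,344,128` plus the 21×256 token table), i.e.
~7M. The closed form is exact for any configuration and is tested against
enumeration.

Batched inference pads to the longest sequence and forces padded positions
to zero after the token lookup and after every convolution. Because σ(0) = 0
for ELU, the zeros seen past a sequence's end are then identical to the
zeros symmetric padding supplies when the sequence is embedded alone, so a
sequence's embedding is bit-identical inside or outside a batch. An edit
more than `n_blocks · (kernel − 1)` positions away from a residue cannot
reach its embedding (receptive-field locality); both properties are tested.

The forward and backward passes are written directly in numpy (im2col +
matmul convolutions, hand-derived gradients). At this model size that is
fast enough for desk-scale training, keeps the dependency surface minimal,
and the full network+loss gradient is verified against central finite
differences in float64.

## Loss

For an aligned pair (A, B) the target matrix `T` is binary with row and
column sums ≤ 1. The masked N-pair term is

    Σ_ij −R^a_i R^b_j T_ij log( e^{D_ij} / Σ_w e^{D_iw} )

with the softmax denominator running over **all** residues of B in row i
(computed via log-sum-exp with row-max subtraction). The loss is applied as
printed — row-asymmetric, softmax over B for each aligned residue of A; an
optional symmetrized variant (average of both directions) exists but is off
by default. Negatives come only from the partner sequence within the same
pair; no cross-pair batch negatives are used. The L2 term is
`(γ/n)(Σ R^a_i‖a_i‖² + Σ R^b_i‖b_i‖²)` with `n` the training crop length,
making the term scale-free in sequence length; in the standalone loss
function `n` defaults to |A|. Per-batch loss is the mean of per-pair losses.

Training examples are contiguous random crops of at most `crop_length`
residues per side. When the pair has aligned columns, one column is sampled
as an anchor and placed at the same random offset inside both windows
(clipped to the sequence ends), guaranteeing that at least one aligned
column survives the crop; surviving columns are re-indexed. Repeat masks are
computed on the cropped sequences before the loss.

Full-scale defaults follow the training recipe this architecture was
designed for: 24,000 AdamW steps, batch 512, crop 256, learning rate 1e-5,
weight decay 1e-2, γ = 5e-3, no gradient clipping. The package's built-in
discrimination benchmark (below) trains a ~200× smaller model on ~10²
pairs and uses batch 8, crop 128, learning rate 1e-3 — a step size
appropriate to that model scale; the full-scale defaults are left untouched
in `TrainConfig`.

## Masking

Masks (1 = keep, 0 = repetitive/biased) silence the loss during training and
exclude residues from both sides of the search. Two sources combine by
union:

* **Soft-masked FASTA** — lowercase letters, for masks produced by an
  external repeat masker; this is the fidelity path for users who want a
  specific masking tool's behavior.
* **Internal detector** — a deliberately simple, deterministic rule:
  a residue is masked if any 16-residue window covering it has composition
  entropy below 2.0 bits, or if it lies in a tandem repeat with period ≤ 5
  spanning at least two full periods and at least 6 residues. The 6-residue
  floor exists because chance doublets (period 1, two residues) occur at
  ~5% of positions in random sequence and are not credible repeats; with
  the floor, well under 5% of uniform-random residues are masked while
  homopolymers and short-motif tandems are masked completely. The detector
  is a pluggable stand-in, not a reimplementation of any probabilistic
  tandem-repeat model.

## Index and search

Vectors are L2-normalized on insertion and query, so inner-product retrieval
equals cosine retrieval. The `exact` backend stores the full matrix and is
the ground truth (tested against a brute-force oracle). The `ivf_pq` backend
clusters vectors into `n_lists` inverted lists (k-means) and
product-quantizes the residuals (32 segments by default, codebook size
min(256, N/4)); queries probe the `n_probe` nearest lists, score candidates
by asymmetric distance (coarse term + per-segment lookup), shortlist 4k of
them, and re-rank with the stored full-precision vectors. Returned
similarities are therefore exact cosines; only candidate retrieval is
approximate. `n_probe` is not prescribed anywhere upstream; the default of
32 is this package's choice and is exposed as configuration. When fewer
vectors than `n_lists` exist, the list count auto-shrinks to ⌈√N⌉ with a
warning — the full-scale defaults (5000 lists) presume millions of
residues.

k is a hard cap per probed residue (per query residue in the standard
orientation, per target residue in the reversed one). Match sets are
deduplicated per (query, target) pair before summation, ties in similarity
break by (seq_id, position) lexicographic order, and the hit list is sorted
by score descending with ties by id, so reruns are bit-identical. With the
exact backend and k at least the index size, standard and reversed
orientations return identical hit sets (tested).

The noise gate subtracts `δ/√d` from each cosine. For standard-normal
vectors the cosine is approximately N(0, 1/d) (the exact distribution has
cos² ~ Beta(1/2, (d−1)/2)); at δ = 3 the gate removes 99.87–99.90% of chance
similarities across d ∈ {64, 256, 1024}, and the sd·√d product is constant
within 5%. Both facts are verified by simulation in the tests.

## Simulator

`make_benchmark` emulates remote-homolog search at desk scale: ancestors are
drawn i.i.d. from the Robinson-Robinson amino-acid background, and each
family member evolves independently by per-position substitution
(probability `substitution_rate`, replacement drawn from the background
excluding the current residue) and indels (open probability `indel_rate` per
position, geometric lengths with mean `mean_indel_length`, insertions from
the background). Ground-truth alignment columns are the ancestor positions
surviving un-deleted in both descendants. Expected column identity has the
closed form `(1−r)² + r²·Σ_a π_a Σ_{x≠a} q_x(a)²` (the second term is
coincident double substitutions), which the Monte-Carlo tests reproduce.
Low-complexity contamination is injected by splicing short tandem segments
(motif length 1–3, total 12–24 residues) into descendants with probability
`lc_insert_prob`; decoys are exact residue permutations of the positive
targets. Families split 80/20 into train/eval by a hash of the family id, so
no family leaks across the split.

Defaults — 50 families of 3 sequences (one query, two targets), lengths
128–512, substitution rate 0.3, indel rate 0.02 (mean length 3),
lc_insert_prob 0.1 — are fixed study conditions, not tuning knobs.

What the simulator does **not** emulate: site-rate heterogeneity,
profile-specific substitution preferences, domain shuffling, and the
long-tail length distribution of real databases. Passing tests therefore
demonstrate that the pipeline learns and exploits local sequence context
under a known-truth homology process; they do not certify recall on real
remote homologs, where divergence is structured rather than i.i.d.

## Discrimination benchmark

`near.benchmarks.family_discrimination_auc` runs the whole system
end-to-end: 55 families (lengths 128–256, substitution rate 0.3) split by
family hash; a d = 32, 2-block model trained 2000 steps on the training-side
pairs; exact-backend search of held-out queries against held-out targets
plus their shuffled decoys; AUC of hit scores over positive vs decoy pairs
(absent pairs score 0). The problem sizes are chosen so a single run
completes in a few minutes on one CPU; at these settings the trained tiny
model reaches AUC ≥ 0.9 on every tested seed (an untrained model of the
same shape sits near 0.89, so the contrastive training, not just the
architecture's locality prior, provides the margin).

## Numerical choices and degenerate inputs

* Softmax always via log-sum-exp with row-max subtraction; loss math in
  float64 even when model weights are float32.
* Zero vectors are normalized with an ε = 1e-12 floor.
* Empty query/target sets and fully masked sequences yield empty results,
  never errors; an empty index returns empty neighbor lists.
* Non-finite dot matrices and non-binary masks raise immediately; training
  aborts with a diagnostic if the loss goes non-finite.
* All file coordinates are 0-based; intervals half-open. Output files carry
  a header with the tool version and a hash of the resolved configuration.

## Known limitations

* The numpy trainer is single-process and CPU-bound; it is meant for
  desk-scale experiments, not corpus-scale training.
* The IVF-PQ backend re-ranks with full-precision vectors kept in memory,
  trading the memory savings of pure PQ for exact scores; at the scales this
  package targets that is the right trade, but it would not survive
  billion-vector indexes.
* The internal low-complexity detector is intentionally minimal; for
  production masking, soft-mask the FASTA with a dedicated tool and rely on
  lowercase ingestion.
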