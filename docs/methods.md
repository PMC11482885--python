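# Methods

`rnaclr` implements contrastive representation learning for mature mRNA and
the evaluation machinery around it, sized so that the complete
pipeline — corpus construction, pre-training, probing, similarity
analytics — runs on a single CPU in minutes.  This note records the model, the
choices made where the design was open, and what the synthetic corpus does
and does not establish.

## The learning problem

A mature mRNA (spliced exons: 5'UTR + CDS + 3'UTR) determines properties such
as stability and translational efficiency through sequence elements that are
sparse relative to transcript length.  Reconstruction-style self-supervision
spends most of its capacity on uninformative positions; the approach here
instead uses *biological* positive pairs: two transcripts that evolution or
splicing tells us are functionally related should lie close in the latent
space, and unrelated transcripts should not.

Positive-pair sources, per reference transcript x:

* **splicing** — other isoforms of x's gene;
* **orthology** — orthologous transcripts from other species.  Ortholog
  annotations typically cover only the CDS, so a sampled ortholog is passed
  through the *UTR-combination transform*: x's own UTRs are spliced around
  the ortholog's CDS.  Without this, every orthology pair would differ in its
  UTRs and the objective would learn that UTRs are uninformative;
* **naive orthology** — transcripts of identically named genes in other
  species (exact, case-sensitive match; homonym collisions are accepted);
* **masking fallback** — a transcript with no relatives is paired with a copy
  of itself whose nucleotide channels are zeroed at 30% of positions.  This
  also makes the "no augmentations" ablation expressible as "all sets empty".

Sampling is uniform over the union of available sources (per-source
probabilities were left open by the design; uniform is the default and the
weights are exposed in configuration).  A reference is never paired with
itself while its set is non-empty.  Draws are keyed by
`(seed, epoch, reference id)` so each epoch re-samples partners
deterministically with no stored state.

## Input encoding

Each transcript is an L×6 binary matrix: four one-hot nucleotide channels
(DNA alphabet, upper-cased; `N` leaves all four at zero), a splice-junction
channel, and a codon-start channel.  Conventions:

* Genomic coordinates are 0-based half-open (the native genePred/BED
  convention); mature coordinates are 0-based.
* The junction channel marks the **first base of each exon after the first**
  (the acceptor side, in mature coordinates).  The donor-side alternative is
  a one-line change; the acceptor convention was chosen because it is
  expressible without lookahead in a causal model.
* The codon-start channel marks the first base of every codon; the stop
  codon counts as part of the CDS.
* Transcripts longer than `max_len` are truncated from the 3' end
  (deterministic, preserves the 5'UTR and CDS start).  The full-scale default
  is 12,288 nt; the desk-scale (micro) default is 448 nt, which accommodates
  every transcript the default synthetic corpus generates, so truncation
  never removes the 3'UTR signal there.
* Non-coding transcripts use `utr5_len = cds_len = 0`, `utr3_len = L`.

## Encoder

The encoder is a stack of selective state-space blocks.  The continuous
dynamics `h'(t) = A h(t) + B x(t)`, `y(t) = C h(t)` are discretized with a
learned per-channel, per-position step Δ — zero-order hold for the transition
(`A_bar = exp(Δ·A)`) and Euler for the input (`B_bar = Δ·B`).  Selectivity
makes Δ, B and C affine functions of the input, which is what lets the model
gate informative tokens into its state and ignore the rest; with the
input-independent (linear time-invariant) variant as a controlled ablation.
`A` is diagonal with negative-real parameterization `A = −exp(A_log)`,
initialized per state dimension to −1…−N, so `|A_bar| ≤ 1` for any Δ ≥ 0 and
the recurrence is unconditionally stable.  These parameterization details are
the standard choices for this model family; the source material defers them
to its architectural reference.

One block computes: depthwise causal convolution (kernel 4) → SiLU →
selective scan → residual skip (`d_skip`) → multiplicative gate
(`SiLU(W_g u)`) → output projection, added residually to the block input.
The short convolution supplies local k-mer composition (motifs are a few
bases long); the scan integrates it over arbitrary distances.

The scan itself is implemented twice with identical semantics: a sequential
reference recurrence, and a log-depth associative (Hillis–Steele) scan used
for training, whose adjoint is the same scan run on time-reversed inputs
(`λ_t = g_t + a_{t+1} λ_{t+1}`).  The two agree to ~1e-5 and are
cross-checked in the test suite.

All neural components run on a compact NumPy reverse-mode autodiff core
(`rnaclr._autodiff`): a tape of ~20 operations plus the fused scan
primitives.  Parameters and activations are float32; the loss-oracle and
scan-reference computations are float64.

Pooling is a masked mean over valid positions (max-pooling available via
config).  The pooled output is the embedding used downstream; the 2-layer MLP
projection head (hidden width d_model, output 128, unit-normalized) exists
only for the contrastive loss and is discarded afterwards.

Presets: `micro` (2 layers, d_model 64, d_state 4) is the desk-scale
configuration used throughout the tests; `small` (≈1.3M parameters) and
`base` (≈10.1M) are produced by a width search at 6 layers against the target
counts, since per-preset layer/width settings were not available.

Baselines with the same `encode` contract: a dilated CNN (geometric receptive
-field growth) and a CNN→RNN hybrid (convolution, strided pooling, small
recurrent layer).

## Objectives

**Decoupled contrastive loss.**  For unit-norm projections of a batch of N
pairs, each anchor z_i^l contributes

    log Σ_{k≠i, l'∈{1,2}} exp(⟨z_i^l, z_k^{l'}⟩/τ) − w_i ⟨z_i^1, z_i^2⟩/τ

with τ = 0.1.  Both views of sample i are excluded from the negative sum
(the "decoupling"), and the loss is averaged over all 2N anchors — the
per-anchor definition is written for one view; averaging over both gives
symmetric gradient flow.  The anchor-vs-pair averaging convention only
rescales the loss by a constant and does not change the optimization
direction.  w_i = 0.8 for orthology-sourced pairs and 1.0 otherwise,
configurable.  The implementation is log-sum-exp stabilized and is verified
against a brute-force per-anchor double loop to 1e-6.

**Masked language modeling.**  15% of valid positions are corrupted by
zeroing the nucleotide channels (structural channels untouched — masking
destroys base identity, not transcript structure).  A linear head on the
shared encoder predicts the 4-way base distribution; the loss is mean
cross-entropy over the masked set only, with a 1e-12 probability floor before
the log (degenerate predictions are clamped and logged rather than producing
−∞).  Positions that were `N` in the original sequence carry no target and
are excluded.

**Joint objective.**  `L = (1−α)·L_CL + α·L_MLM` with α = 0.95,
compensating the MLM term's smaller numerical scale.  When both objectives
are active, the contrastive views are encoded clean and the MLM pass uses the
corrupted input, all through the same encoder.

## Training loop

Adam (β = 0.9/0.999), learning rate 1e-3 with cosine decay, optional
decoupled weight decay.  These settings are package defaults, not sourced
values — the original optimizer settings were not available.  Batching is
seeded per `(seed, epoch)`; *gene-exclusive* batching (default on) places at
most one transcript per gene in a batch so that an anchor's sibling isoforms
never appear among its negatives; turning it off reproduces the plain
random-batch description.  Runs are exactly reproducible and resumable from
epoch checkpoints (parameters + Adam state are serialized; all randomness is
re-derived from `(seed, epoch, step, id)` keys rather than stored generator
state).  Note that the cosine schedule depends on the configured total epoch
count, so a shorter run is only a prefix of a longer one at constant
learning rate.

## Synthetic corpus

The generator builds gene families with the statistical structure the method
assumes, deterministic per seed:

* each family is one ancestral gene on its own chromosome: 4–7 exons,
  introns of 50–150 nt, a 10–30 nt 5'UTR, a 70–120 nt 3'UTR, and a
  frame-consistent CDS.  Internal exon lengths are multiples of 3, so exon
  skipping preserves frame.  Half the genes are on the minus strand.
* isoforms (2–4 per gene) are exon subsets retaining both terminal exons.
* orthologs (2 species) are CDS-only single-exon transcripts derived from the
  canonical isoform by per-site substitution at rate 0.1 — except inside
  planted motifs, which are copied verbatim.  Conserved functional islands in
  a sea of drifting sequence is precisely the signal the contrastive
  objective is hypothesized to exploit, and it gives the exon-deletion
  analysis its ground truth.
* the property label is `y = Σ_m β_m·count_m(3'UTR) + 0.5·ln(cds_len) + ε`,
  with five 6-mer motifs at β = 1, 0–2 planted copies each, and ε ~ N(0, 0.5²).
  An ordinary least-squares fit on the *true* motif counts recovers the β
  within error and R² ≥ 0.8 at n ≈ 2,000 — the generator's own oracle,
  independent of any encoder.
* functional classes (10) group families that share a conserved, domain-like
  sequence block (45 nt, truncated to the carrying exon's length) planted into
  1–2 internal exons' CDS — GO-sharing genes share domain-scale sequence, so
  the class signal is sized like a small protein domain rather than a short
  motif.  Those exons also carry protein-domain annotations, creating the
  correlation structure between domain overlap and embedding similarity that
  the similarity analytics measure.  The same exons are the "motif-bearing"
  set for exon-deletion contrasts.

What the corpus does **not** emulate: realistic phylogenies (orthologs are
independent draws, not a tree), indels or splice-site sequence signals, GC
or codon-usage structure, overlapping genes, and any coupling between the
label and cellular context.  Passing the end-to-end tests therefore shows
that the machinery — pair construction, objective, encoder, probes,
statistics — behaves as designed on data with the assumed structure; it is
not evidence about performance on real transcriptomes.

A limitation observed consistently at this scale: the contrastive objective
assigns embedding salience to *gene-unique discriminative* sequence, so
deleting a neutral exon (unique content) can move a transcript's embedding
at least as much as deleting an exon carrying the class-shared conserved
block.  The exon-deletion contrast that favors conserved functional exons
appears to require either far broader evolutionary variation than a
two-species, 200-family corpus provides, or an objective component that
rewards conserved content directly; the corresponding end-to-end check is
expected to fail at desk scale and is retained as an honest negative
result.

## Evaluation machinery

* **Homology-aware splits**: whole families are assigned to train/val/test
  (greedy largest-deficit assignment of shuffled families), so probe scores
  measure generalization to unseen genes, not sequence memorization.
* **Linear probes**: ridge regression / logistic regression on frozen,
  standardized embeddings; 7 log-spaced regularization strengths (1e-3…1e3)
  selected on validation.  Metrics: Pearson's R (regression), macro-averaged
  auPRC (classification).
* **Few-shot**: training subsets of n ∈ {30, 100, 300}, uniform without
  replacement, validation/test untouched.
* **Ablation Z-scores**: per task, scores from all configurations × seeds are
  pooled (regression scores Fisher-transformed, arctanh); each score is
  standardized by the pool's μ, σ; per-config task Z is the seed mean and the
  aggregate Z the unweighted task mean.  Significance against a reference
  configuration uses a one-sided Welch t-test (Satterthwaite df), top tier
  meaning p > 0.05; a seed-paired t-test is available behind a flag for the
  variant description that pairs runs by seed.
* **Similarity analytics**: embedding similarity `1 − ln‖e1−e2‖₂` (natural
  log; distance floored at 1e-8 so identical embeddings score finitely),
  Jaccard indices over protein-domain sets and over base-pair interval sets
  (two empty sets score 1 — identical annotations), pair groups
  intragene / intergene / same-functional-class with non-homologous =
  different family, two-sided Mann-Whitney between groups, per-gene
  correlations of domain overlap against embedding similarity and against
  length- and sequence-overlap baselines.
* **Isoform clustering**: pairwise similarity, min-max normalized per gene
  (the normalization scheme was unspecified; per-gene min-max makes heatmaps
  comparable across genes), average-linkage clustering on
  `distance = 1 − normalized similarity`, deterministic leaf order, newick
  serialization.
* **Exon-deletion delta**: re-splice without one exon, recompute the CDS
  (frame-breaking deletions are flagged and the CDS truncated to whole
  codons), re-encode, and report the L2 embedding displacement.  Deleting
  nothing returns exactly 0.

## Numerical and degenerate-input policy

Value errors on: empty sequences, Δ < 0, non-unit projection rows, batches
with fewer than two pairs (no negatives), empty masked sets, α or fractions
out of range, σ = 0 reference pools, |r| ≥ 1 in the Fisher transform,
constant training labels, single-isoform clustering, deleting a transcript's
only exon.  Warnings (with the offending item skipped or clamped): unknown
ortholog ids, missing embeddings for a sampled pair, interval Jaccard across
chromosomes (scored 0), near-zero probabilities in the MLM loss.

## Problem sizes

The standard study corpus is 200 families (~600 reference transcripts,
~400 orthologs); the micro encoder trains on it with batch 32 for 10 epochs
(~190 steps) in a few minutes on one CPU, which is sufficient for the
latent-space structure the integration tests measure.  The selective-copying
benchmark uses sequences of length 64 with 4 content tokens over a 4-symbol
vocabulary, 500 training steps, and a parameter-matched linear
time-invariant control (the control is widened to d_model 80 to offset the
parameters that selectivity adds).  These sizes are the package's standard
desk-scale configuration; all of them scale up through configuration without
code changes.
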