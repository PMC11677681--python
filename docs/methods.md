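# Methods

`psspkit` implements a desk-scale framework for per-residue protein
secondary structure prediction (PSSP): a segment-masking autoencoder
that produces a narrow per-residue sequence encoding, a multi-task
predictor that couples the 8-state (or 3-state) structure task with a
buried/exposed auxiliary task through a mixture-of-experts sharing
layer, the standard residue- and segment-level evaluation metrics, and
the data analyses that motivate the design.  This note records the
models, their assumptions, the tunable parameters, and the choices made
where the design was genuinely open.

## Labels and features

Residues use the 21-letter alphabet (20 standard amino acids + `X` for
everything non-standard: B, J, O, U, Z and unknown letters all map to
`X`).  Secondary structure uses the DSSP 8 states H, G, I, E, B, T, S,
L, reduced to 3 states as H/G/I→helix, E/B→strand, T/S/L→coil.  All
internal coordinates are 0-based half-open; reports are 1-based.

Per-residue feature channels (each individually toggleable in the
predictor):

| channel | width | source |
|---|---|---|
| one-hot | 21 | sequence |
| PSSM | 20 | PSI-BLAST ASCII profile (reader only; optional sigmoid squashing) |
| HMM | 30 | HH-suite `.hhm` (reader only; optional `2^(-x/1000)` de-quantization, `*`→0) |
| physicochemical | 7 | packaged literature table (sheet/helix propensity, pI, hydrophobicity, van der Waals volume, polarizability, graph shape index) |
| embedding | D (default 1280) | any per-residue matrix from a protein language model; treated as a pluggable numeric channel |
| autoencoder encoding | 4 | the encoder below |

The paper-derived profile transforms are off by default (raw values);
whether profiles are rescaled is left configurable because no single
convention dominates.  The physicochemical and max-ASA tables are data
files and can be replaced by any file of the same layout; tests rely on
the lookup contract, not the specific values.

## Segment-masking autoencoder (`psspkit.hta`)

The encoder is a chain of `A` residual dynamic-convolution blocks
(default `A = 2`, the smallest depth that exercises chaining).  Each
block:

1. masked global average pooling of the input over valid positions;
2. a 1×1 convolution (a linear map on the pooled vector) to `B` logits,
   softmax → per-sample attention weights over a bank of `B` candidate
   filters (default `B = 3`);
3. convolution with the attention-weighted *combined* filter (one
   effective filter per sample), batch-normalized;
4. plus a batch-normalized 1×1-projected residual, LeakyReLU (slope
   0.01).  The 1×1 projection is applied even when input and output
   widths agree, matching the block's definition literally.

The final block outputs 4 channels per residue — deliberately narrow so
the code is dense in task-relevant information.  The decoder is a
BiLSTM (default 2 layers, 20 hidden units per direction; the reference
description is ambiguous about which number is layers and which hidden
units, so both are exposed) followed by a position-wise linear layer to
21 classes.

Training masks one maximal single-category secondary-structure segment
per sequence, chosen uniformly at random afresh each epoch, by zeroing
its one-hot rows (no mask token exists in the alphabet; a dedicated
22nd mask channel is available via `mask_mode="token"`).  The
reconstruction loss is cross-entropy against the true residue
identities over all valid positions by default (`loss_scope="masked"`
restricts it).  Masking never touches label tracks.  At encoding time
inputs are not masked, so no residue is ignored.

**Pre-training protocol.** The autoencoder trains with AdamW (weight
decay 0.05) at a *constant* learning rate 2e-3
(`default_hta_train_config`).  The halving schedule used for the
predictor (below) is unsuitable here: at desk scale an epoch is only a
handful of updates, and geometrically decaying the rate caps the total
parameter movement before the reconstruction escapes the marginal
residue distribution — a failure we observed directly as a model unable
to fit even a 20-sequence corpus.

## Multi-task predictor (`psspkit.mtl`)

Pipeline: enabled channels (except the embedding) are stacked and pass
a multi-scale residual convolution — per scale `s ∈ {1, 5, 9}` a
same-padded convolution plus a 1×1-projected residual, LeakyReLU, then
channel-wise concatenation (default 32 channels per scale).  Scales 1,
5, 9 reflect the empirical segment-length pattern (most segments are
1–11 residues).  An embedding channel, if enabled, bypasses the
convolution and joins at the concatenation: language-model embeddings
already encode inter-residue context, so re-convolving them adds little.

The shared layer is a multi-gate mixture of experts: `E = 3` expert
networks (each β = 2 Conv1d+BatchNorm pairs, 64 channels, LeakyReLU
between pairs) are combined per task by a task-specific gating network
(1×1 conv → BN → LeakyReLU → softmax across experts, independently at
each sequence position); expert outputs are weighted by the gate,
summed, added to a task-specific batch-normalized 1×1 residual and
passed through LeakyReLU.  Gate weights broadcast down the channel
rows.  The soft sharing is motivated by the moderate association
(Cramér's V ≈ 0.23) between structural category and burial: related
enough to share, not related enough for fully shared parameters.

Each task tower is a temporal convolutional network — `M = 3` residual
blocks, two causal dilated convolutions per block, dilation `2^(i-1)`,
kernel 3 — followed by a BiGRU (1 layer, 32 hidden per direction) and a
1×1 convolution head with per-position softmax.  Tower parameters are
per-task.  The structure head has 8 (or 3) classes; the auxiliary head
classifies burial as RSA ≤ 0.15 (buried) vs > 0.15 (exposed) — binary
because the association analysis that justifies the auxiliary task is
binary at that threshold.

Unstated widths/depths (β, CH, M, kernel, per-scale channels, BiGRU
shape) are package defaults chosen to be the smallest values that
exercise every mechanism; all are configurable.

## Optimization protocol (`psspkit.train`)

AdamW, weight decay 0.05; batch size 32 with per-batch padding to the
longest sequence; initial learning rate 5e-4 halved every 5 epochs
(predictor); early stopping with patience 3 on validation structure
accuracy (higher-better) when a validation split is given, otherwise on
training loss; loss = 0.8·CE(structure) + 0.2·CE(burial), cross-entropies
averaged over valid positions only; seed 42.

Padding hygiene: padded positions are excluded from batch-norm
statistics and losses, recurrent state updates are gated by the
validity mask, and activations are re-zeroed at padded positions after
every block so convolutions near a sequence tail see the same context
whether or not the batch is padded.  In evaluation mode a record's
outputs are therefore identical alone or inside a padded batch
(verified to 1e-8).

## Evaluation metrics (`psspkit.metrics`)

* **Q** — percentage of residues whose predicted category matches the
  observed one; multi-sequence values pool counts, never average
  per-sequence scores.
* **SOV** — segment overlap.  For each category, observed/predicted
  segment pairs that overlap contribute `(minov + δ)/maxov · l(s1)`
  where `minov`/`maxov` are intersection/union lengths,
  `δ = min(maxov − minov, minov, ⌊l(s1)/2⌋, ⌊l(s2)/2⌋)` (integer
  division, following the classical segment-overlap definition), and
  `l(s1)` is the observed segment's length; the normalizer sums
  observed-segment lengths over overlapping pairs plus unmatched
  observed segments.  Categories absent from the observed labeling
  contribute nothing.  The implementation is verified against an
  independent brute-force transcription, exhaustively for all label
  pairs up to length 8 over two categories.
* **Boundary accuracy** — Q restricted to boundary residues: sequence
  ends (Type 1), interior residues whose two flanks disagree (Type 2),
  or whose flanks agree but differ from the residue's own category
  (Type 3).  Types 2/3 require both flanks to exist; in a length-2
  sequence both residues are Type 1.
* **Confusion matrices** — observed × predicted counts, row-normalized
  on request (zero rows stay zero).

## Association analysis (`psspkit.analysis`)

RSA = ASA / max-ASA of the residue type (clipped to [0, 1]; the
packaged max-ASA table uses theoretical maxima, configurable).
Burial is binarized at RSA ≤ 0.15.  Cramér's V of the 2×8
burial-by-category contingency table uses expected counts
`E_ij = sum_i · sum_j / sum` and
`V = sqrt(Σ (O−E)²/E / (sum · min(m−1, n−1)))`; margins are always
recomputed from cells, and zero-margin rows/columns are dropped with a
warning before the χ² sum.  The package ships a published ~6.03-million
residue reference tally on which V = 0.2264.

## Synthetic data (`psspkit.synth`)

The generator emulates the statistical structure the framework relies
on: a first-order category chain with zero self-transitions (segments
are maximal by construction), per-category truncated-geometric segment
lengths with mass concentrated on 1–11 residues (helix longest, bridge
shortest), per-category residue emissions (a biased-but-noisy default,
and a deterministic one-letter-per-category preset for learnability
tests), and a per-category exposure probability.  Continuous RSA values
are placed uniformly within the correct side of the 0.15 threshold —
sufficient because every downstream computation binarizes there.

`calibrate_association(target_v)` scales the spread of the per-category
exposure probabilities around their residue-weighted mean using the
closed form `V = sqrt(Σ_c p_c (q_c − q̄)² / (q̄(1−q̄)))` for a 2×n
table, so a generated corpus hits a target Cramér's V in expectation;
at ~10⁶ residues the measured value lands within ±0.02.

What the generator does *not* emulate: real sequence–structure
energetics, long-range residue interactions, homology structure, or
class imbalance as extreme as real π-helix scarcity.  Passing learning
checks on these corpora demonstrates that the architectures train and
that information flows end to end — not benchmark-level accuracy on
real proteins.

## Numerical substrate

The neural components run on a small reverse-mode automatic
differentiation engine over NumPy (`psspkit.nn`): elementwise ops,
matmul, reductions, slicing, concatenation, activations, and a 1-D
convolution supporting dilation, causal padding and per-sample filter
banks.  Gradients of every primitive and composite layer are verified
against central finite differences (tolerance 1e-4 relative).
Float64 throughout; batch-norm ε = 1e-5, momentum 0.1; softmax and
log-softmax are max-shifted for stability.  Fixed seeds give
bit-identical training histories.

## Problem sizes

Desk-scale runs use synthetic corpora of 150–500 sequences of 30–60
residues; the learning checks use 16 channels per scale, 32 expert
channels and 16 BiGRU hidden units (the library defaults are 32/64/32).
The association check generates ~10⁶ residues.  These sizes were chosen
so every end-to-end check trains a real model from scratch on one CPU
in minutes.

## Known limitations

* The autoencoder's masked-position reconstruction is bounded by the
  conditional predictability of a hidden segment from its flanks; on
  synthetic corpora the Bayes ceiling is ≈ 0.5 with ≈ 0.36 frequency
  baseline, so margins are modest by construction.
* Batch norm in training mode makes outputs depend on batch
  composition; all invariance guarantees hold in evaluation mode.
* The CLI predicts from label files (id + sequence [+ tracks]); plain
  FASTA prediction requires the library API.
* No gradient clipping (off by default, available via config); no
  ensembling or multi-seed averaging.
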