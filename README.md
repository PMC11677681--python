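# psspkit

A desk-scale toolkit for **protein secondary structure prediction
(PSSP)**: per-residue classification of a protein chain into the DSSP
8-state categories (H, G, I, E, B, T, S, L) or their 3-state reduction
(helix / strand / coil).  It is aimed at method developers who want the
full training-and-evaluation machinery of a modern PSSP framework —
sequence encoding, multi-task learning, segment-level scoring — in a
form that trains end to end on one CPU in minutes, on synthetic or
user-supplied data.

The package implements:

* **A segment-masking autoencoder** ("highly targeted" sequence
  encoder): a dynamic-convolution encoder whose per-sample attention
  combines `B` candidate filters into one effective filter, compressing
  the one-hot sequence `L×21` to a narrow `L×4` encoding; a BiLSTM
  decoder reconstructs residue identities.  Training masks one maximal
  single-category secondary-structure segment per sequence per epoch,
  tying the code to segment context.  Unlike profile features, the
  encoding needs no multiple-sequence alignment and is independent of
  how many homologs a protein has.
* **A multi-task predictor**: multi-scale residual convolution (scales
  1/5/9, chosen because real secondary-structure segments are mostly
  1–11 residues), a multi-gate mixture-of-experts (MMoE) sharing layer
  in which task-specific gates softly combine `E` shared experts at
  every sequence position, and per-task towers of causal dilated
  temporal convolutions (TCN) followed by a BiGRU.  The main task
  predicts the structural category; the auxiliary task predicts burial
  (relative solvent accessibility ≤ 0.15), whose association with
  structure (Cramér's V ≈ 0.23) motivates the soft sharing.
* **Evaluation**: residue accuracy `Q = Σ_i T_i / N × 100`, the
  segment-overlap score
  `SOV = 100/N · Σ pairs (minov + δ)/maxov · l(s1)` with
  `δ = min(maxov−minov, minov, ⌊l(s1)/2⌋, ⌊l(s2)/2⌋)`,
  per-category recall, confusion matrices, and accuracy restricted to
  boundary residues (sequence ends and category switch points).
* **Association analysis**: RSA computation and binarization,
  burial-by-category contingency tables, Cramér's V
  `V = sqrt(χ² / (N·min(m−1, n−1)))`, segment-length histograms.
* **A synthetic corpus generator** with a tunable
  structure–burial association, used by the tests and examples.

The neural layers run on a small NumPy autograd engine included in the
package (`psspkit.nn`), verified against finite differences.

## Worked example

```python
import numpy as np
import psspkit as pk
from psspkit.mtl import MTLConfig, majority_class_q

# a corpus whose residue identities determine the structural category
gen = pk.GeneratorConfig(n_sequences=200, min_length=30, max_length=50,
                         emissions=pk.deterministic_emissions(), seed=6)
records, _ = pk.generate_corpus(gen)

cfg = MTLConfig(features=("one_hot",), channels_per_scale=16,
                expert_channels=32, bigru_hidden=16)
feats = pk.assemble_features(
    [pk.build_bundle(r, with_physchem=False) for r in records], cfg)
model, history = pk.train_mtl(records, feats, cfg,
                              pk.TrainConfig(seed=42), n_epochs=10)
outs = pk.predict(model, feats)
q8 = np.mean([pk.q_accuracy(o.ss_string, r.ss8)
              for o, r in zip(outs, records)])
print(q8, majority_class_q(records, cfg))
```

Running this (it is `examples/05_train_multitask.py`) prints:

```
multi-task loss: 1.650 -> 0.660
train-set Q8 = 95.0%  SOV8 = 92.2%  (majority-class baseline 38.1%)
```

i.e. after ten epochs the model recovers 95% of the per-residue labels
on a corpus whose majority class would give 38% — the whole pipeline
(features → multi-scale convolution → MMoE → TCN/BiGRU towers → heads)
learns.  The association analysis (`examples/01_association_analysis.py`)
prints, for the packaged ~6.03-million-residue reference tally:

```
Cramér's V = 0.2264  (0 = independent, 1 = deterministic)
synthetic corpus calibrated to V=0.2264: measured V = 0.2287 on 89919 residues
```

Each script in `examples/` demonstrates one capability (association
analysis, metrics, corpus synthesis, autoencoder training, multi-task
training) and prints what the numbers mean.  The same pipeline is
available from the shell:

```bash
psspkit synthesize --out corpus --n 200 --seed 7
psspkit train-hta --labels corpus/corpus.labels --out hta.pkl --epochs 30
psspkit encode    --model hta.pkl --labels corpus/corpus.labels --out encs
psspkit train     --labels corpus/corpus.labels --encodings encs --out mtl.pkl
psspkit predict   --model mtl.pkl --labels corpus/corpus.labels \
                  --encodings encs --out preds
psspkit evaluate  --pred preds/predictions.tsv --obs corpus/corpus.labels
psspkit analyze   --labels corpus/corpus.labels
```

File formats: FASTA, a plain-text label table (`id sequence ss8
[per-residue RSA...]`), PSI-BLAST ASCII PSSM, HH-suite `.hhm`, and
whitespace-delimited numeric matrices for embeddings/encodings.

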