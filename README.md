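# tcrhla

Peptide-agnostic prediction of which Class I HLA allele (loci A and B) a
T-cell receptor binds, from the receptor's β-chain alone.

## The problem

T cells that reach the periphery were positively selected on one of their
host's MHC molecules, so a bulk-sequenced repertoire should be enriched for
TCRs that bind *some* host HLA allele — but nobody knows which one.  The
CDR1/CDR2 loops that contact the MHC α-helices are fully determined by the
Vβ gene, and the hypervariable CDR3 also touches the MHC, so both carry
signal about the restricting allele.  This package is for immunoinformatics
researchers who want to (a) quantify the Vβ–HLA association in paired
TCR–HLA tables, (b) train a neural TCR–HLA binding predictor, and (c) train
and evaluate through the label ambiguity of bulk repertoires, where each TCR
comes only with its donor's 4 candidate alleles (2 A + 2 B).

## Models

**Naive Bayes Vβ baseline.** From positive pairs, estimate P(h), P(v),
P(v|h) and score a pair by Bayes' rule:

    s_ij = P(h_i | v_j) = P(h_i) P(v_j | h_i) / P(v_j)

which with no smoothing equals count(h_i, v_j)/count(v_j).

**Neural binding predictor.** A TCR encoding E_t (CDR3β compressed by a
pretrained sequence autoencoder, fine-tuned downstream, plus 50-dim learned
V/J gene embeddings) and an HLA encoding E_h (14-dim character embedding of
the allele name through a 2-layer CNN to 100 dims) are concatenated into
E_th and passed through an MLP with one hidden layer of half the input
dimension (Leaky ReLU, dropout 0.1) and a sigmoid output.  Negatives are
sampled to match the positives' TCR and HLA marginals; splits are
donor-aware; early stopping monitors internal-validation AUC.

**Two-stage training for bulk repertoires.** Stage 1 treats every
(TCR, candidate-allele) pair as positive.  Stage 2 relabels: only the
candidate scored highest by the stage-1 model stays positive, the rest
become negatives, and the model is retrained.

**Ambiguity-aware evaluation.** With m candidate labels of which one is
true, even a perfect scorer is capped at AUC = (m+1)/(2m) — 0.625 at m=4 —
so the package adds **Group Accuracy** (GA): the fraction of TCRs whose
top-ranked allele over the whole universe lies in their candidate set,
compared against a scrambled-label null curve.  A donor co-occurrence
cross-check calls TCR–HLA associations from donor sharing patterns and
tests the model's recall on them by chi-squared.

A CD4/CD8 classifier (same TCR encoding, one hidden layer) filters unsorted
repertoires down to the CD8-like TCRs for which Class I prediction applies.

All neural components run on a small numpy layer library included in the
package (`tcrhla.nn`); no GPU or deep-learning framework is required.

## Worked example

Generate a paired table with a planted Vβ–HLA association (each of 16
alleles prefers one of 16 V genes with probability 0.9), then fit both
models:

```python
import numpy as np
import tcrhla as t
from tcrhla import synthetic_data as sd

spec = sd.GeneratorSpec(
    n_tcrs=4000,
    hla_pool=sd.default_hla_pool(8, 8),        # 8 A + 8 B alleles
    v_pool=sd.default_v_pool(16),
    association=sd.planted_association(16, 16, strength=0.9),
    seed=7,
)
pairs = sd.generate_pth(spec)

nb = t.VGeneNaiveBayes(pairs).fit(smoothing_alpha=0.5)
print(nb.summary())

negatives = t.sample_negatives(pairs, ratio=1.0, seed=0)
scores = np.concatenate([nb.score_pairs(pairs), nb.score_pairs(negatives)])
labels = [1] * len(pairs) + [0] * len(negatives)
print(f"Naive Bayes AUC vs matched negatives: {t.roc_auc(scores, labels):.3f}")

cfg = t.BindingModelConfig(max_epochs=30, patience=8, ae_epochs=20, seed=0)
results = t.BindingModel(pairs, negatives, config=cfg).fit()
print(results.summary())
print(f"ambiguity AUC ceiling at m=4: {t.max_auc_bound(4):.3f}")
```

This prints:

```
V-gene Naive Bayes association model
  training pairs : 4000
  HLA alleles    : 16
  V genes        : 16
  smoothing alpha: 0.5
  most frequent HLAs: B*05:01 (273), A*07:01 (269), B*06:01 (268)
Naive Bayes AUC vs matched negatives: 0.966
TCR-HLA binding predictor
  positives / negatives : 4000 / 4000
  HLA universe          : 16 alleles
  E_t dim / E_h dim     : 130 / 100
  epochs run (best)     : 28 (19)
  validation AUC        : 0.9292
  lr / weight decay     : 0.007 / 0.001
ambiguity AUC ceiling at m=4: 0.625
```

The Naive Bayes AUC of 0.966 says the planted V-gene association is almost
fully recoverable from gene usage alone; the neural model reaches a 0.93
internal-validation AUC on the same data (it must also learn the allele
encoding from scratch).  The 0.625 figure is the hard ceiling any scorer
faces once each TCR's true allele hides among 4 candidates — which is why
downstream repertoire results are read through Group Accuracy rather than
AUC alone.

For the ambiguous-label pipeline see `tcrhla.two_stage.run_two_stage`, and
`tcrhla/cli.py` (`tcrhla --help`) for the command-line wrappers
(`preprocess`, `simulate`, `nb`, `train`, `cd4cd8`).

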