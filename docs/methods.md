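# Methods

## Scope and data model

The package predicts TCR–HLA (Class I, loci A and B) binding from the TCR
β chain: the CDR3β amino-acid sequence, the Vβ gene (two-field label,
`V05-01`) and the Jβ family (`J02`).  α-chain fields are carried through and
can be encoded when present, but no module requires them.  The peptide is
deliberately ignored everywhere: the target of inference is the restriction
between receptor and MHC molecule, not antigen specificity.  HLA alleles are
two-field labels (`A*02:01`); C-locus alleles are accepted in typing input
but discarded with a logged count, since typing and pairing information for
C is too sparse to model and every prediction on it would be unverifiable.

Two data regimes are supported. *Paired tables* give each TCR one
experimentally observed allele. *Bulk repertoires* give each TCR only the
donor's candidate set — normally 4 alleles (2 A + 2 B; fewer for homozygous
donors, since candidate sets have set semantics).  The assumption linking
the two is that every peripheral TCR was positively selected on at least one
host allele.

## Normalization rules

Curated tables mix HLA dialects (`HLA-A*02:01`, `A*02:01`, `HLA-A*02`,
serological `A2`) and V-gene dialects (`TRBV5-1`, `V05-01/3/4`,
`V01-02:01`).  Normalization maps all of them to the canonical forms above:
allele suffixes are stripped, slash-separated multi-gene options collapse to
the first option, and group-only inputs (two-digit HLA, single-field V) are
completed to the most frequent full label of that group in a reference table
(a `FrequencyCatalog`, by default built from the table being loaded,
overridable with an external reference; ties break lexicographically so the
completion is deterministic).  Both normalizers are idempotent, which the
suite checks property-style.  Row filtering for paired tables drops
non-human rows, rows with missing or multiple HLA entries, and rows without
a CDR3β, then deduplicates exact (TCR, HLA) repeats; every drop is counted
in an audit log and kept + dropped always equals the input row count.

## Naive Bayes Vβ model

From positive pairs the model estimates P(h), P(v) and P(v|h) and scores
with Bayes' rule, s_ij = P(h_i)P(v_j|h_i)/P(v_j), which unsmoothed reduces
to count(h,v)/count(v).  An optional Laplace pseudo-count `alpha`
(default 0, i.e. plain frequencies) keeps scores finite for (h, v)
combinations unseen in training — without it, cross-dataset transfer crashes
on any new gene.  P(v) is computed by marginalizing P(h)P(v|h), so posterior
columns sum to 1 for any alpha.  The association heatmap is
log(s_ij + 1e-5); leaf orders for rows and columns come from single-link
hierarchical clustering with Euclidean distance on the log rows/columns.

## Neural architecture

All networks run on `tcrhla.nn`, a small numpy layer library (dense,
embedding, 1-D convolution, max-pooling, dropout, Adam with L2 weight decay)
written for this package; the models are small enough that single-CPU numpy
is adequate, and gradient correctness is finite-difference-checked in the
test suite.

* **CDR3 autoencoder** — input is a (max_len, 21) one-hot matrix (20 amino
  acids + a stop symbol terminating the sequence, zero padding after it).
  Encoder: flatten → dense(300) → ReLU → dense(30); mirrored decoder emits
  per-position logits trained with cross-entropy.  Padding positions are
  trained toward the stop class so decoding is well defined at every
  position; decoding reads argmaxes up to the first stop.  Pretraining sees
  sequences only — no HLA information — for 300 epochs by default.  The
  pretrained encoder *initializes* the downstream classifiers and is
  fine-tuned with them: with the encoder frozen, its high-variance CDR3
  features act as a memorization channel that the binding objective overfits
  instead of learning the gene–allele signal (we observed validation AUC
  collapse), while fine-tuning lets weight decay shrink the unhelpful
  directions.
* **TCR encoding** E_t = [AE(cdr3β) | Emb_V(v) | Emb_J(j)], with 50-dim gene
  embeddings (one reserved unknown row per table for genes unseen in
  training) and α-chain analogues appended when configured; 130 dims in the
  β-only default.
* **HLA encoding** E_h embeds the *characters of the canonical allele name*
  (14 dims) and applies two conv→ReLU→max-pool blocks and two dense layers
  with dropout 0.1, giving 100 dims.  Treating the allele label as a short
  character string lets structurally related names (same locus, same allele
  group) share features without any molecular input; the encoder interface
  is pluggable so an encoder over HLA protein pseudo-sequences can be
  swapped in.
* **Binding head**: E_th = [E_t | E_h] → dense(|E_th|/2) → Leaky ReLU →
  dropout 0.1 → dense(1) → sigmoid.  Loss is binary cross-entropy, the
  natural choice for a 0/1 target.  Optimizer Adam, lr 0.007, weight decay
  0.001 by default.
* **CD4/CD8 head**: E_t → dense(|E_t|/2) → ReLU → dropout 0.1 → dense(1) →
  sigmoid; Adam lr 0.0005, weight decay 0.0005.

## Training protocol

Negative pairs are sampled so the features match the positives': the TCR
multiset is reused as-is and HLAs are drawn from the positives' empirical
allele distribution, rejecting pairs present in the positive set.  Splits
are donor-aware whenever donor provenance exists — a donor's pairs are never
on both sides — with 80/20 train/test and a further 10% of the training side
as internal validation (the validation fraction is ours; only "internal
validation" is specified).  Early stopping halts when validation AUC fails
to improve for `patience` epochs (default 20) and restores the best-epoch
weights, so the restored epoch always attains max(history).

Two-stage training for bulk repertoires: stage 1 uses all (TCR, candidate)
pairs as positives and non-candidate negatives sampled to the configured
ratio; stage 2 keeps, per TCR, only the argmax-scored candidate as positive
(ties broken by canonical allele-name order and counted), turns the losing
candidates into negatives, and tops the negatives up with non-candidates to
preserve the stage-1 class ratio, keeping class balance comparable across
stages.
Round 2 retrains from round-1 weights (warm start, configurable off); more
rounds repeat the relabeling.  GA is always computed against the *original*
candidate sets, the only ground truth available.  With singleton candidate
sets the whole procedure reduces exactly to ordinary supervised training.

## Evaluation

ROC AUC delegates to scikit-learn (tests cross-check it against an
exhaustive pairwise Mann–Whitney oracle).  With m candidate labels of which
exactly one is true, a perfect scorer still labels m−1 "positives" with
noise scores, capping AUC at 1/m + (m−1)/m · 1/2 = (m+1)/(2m) in the
large-universe limit — 0.625 at m=4, 1 at m=1.  This closed form is
validated against a Monte-Carlo perfect-oracle simulation
(`simulate_ambiguity_auc`), which is also what `scripts/acceptance.py`
recomputes.  Group Accuracy (argmax over the full allele universe of the
dataset, ties broken by canonical name order) is compared against a
scrambled null that permutes candidate sets across TCRs (preserving set
sizes) over R = 10 realizations per sample-size fraction, reported as mean ±
standard error.  The donor co-occurrence cross-check considers TCRs shared
by ≥ T1 donors, divides each allele's carrier fraction by its population
frequency (default: empirical frequency over the input donors), renormalizes
to sum 1, and calls an association when the maximum exceeds r1 (two
practical operating points, T1=15/r1=0.5 for large cohorts and T1=5/r1=0.25
for small ones, are exercised in the tests); model recall on called associations is compared with the 1/|U|
random rate by a continuity-corrected 2×2 chi-squared test with significance
stars at 0.05/0.01/0.001.

## Synthetic data

The generator plants known structure so every pipeline has a recoverable
ground truth: an (HLA × V-gene) row-stochastic association matrix (default
planted strength 0.9 on one preferred V gene per allele), CDR3 letters i.i.d.
uniform over the 20 amino acids with lengths 8–20 peaked near 14, optional
HLA-specific CDR3 k-mer motifs, and a CD8 motif present in a configurable
fraction of CD8 cells (0.7 in the planted-recovery checks, which puts the
Bayes-optimal CD4/CD8 AUC near 0.7·1 + 0.3·0.5 = 0.85).  Bulk donors draw
2 A + 2 B alleles from population frequencies, and each TCR's true allele is
uniform over its donor's set; the truth map is returned for recovery tests
only.  `make_noisy_pth` degrades a labelled table into the ambiguous form by
attaching k extra alleles per TCR sampled from the table's empirical allele
distribution, excluding the truth so candidate sets have exactly k+1
members.  What the generator does *not* model: VDJ recombination statistics,
realistic joint CDR3-length/gene-usage distributions, thymic-selection
biology, or cross-donor sharing of public clones.  Passing recovery tests
therefore demonstrates that the estimators and training loops work, not that
real repertoires carry this much signal.

## Problem sizes and numerical choices

Planted-recovery runs use 200 donors × 100 TCRs (20 000 TCRs, 64-allele
universe, m=4) for the two-stage check and 20 000 TCRs for the CD4/CD8
check, with reduced network sizes chosen for single-CPU runs: autoencoder
hidden width 128 (default 300), max_len 21 (covers generated lengths ≤ 20
plus stop; default 25), pretraining 6–10 epochs on a corpus capped at 8 000
sequences, and 12–15 training epochs.  The two-stage runs use learning rate
0.001 rather than the 0.007 default: with noisy stage-1 labels over a 64×64
gene–allele grid the higher rate collapses the head to constant output,
while 0.001 trains stably (0.007 remains the default, appropriate for clean
paired tables).  Small-sample caveat observed
while validating: with few donors, donor-aware held-out AUC on bulk data can
dip *below* 0.5 because a held-out donor's alleles were rare among training
positives, depressing their baseline scores; GA, being a within-TCR ranking,
is robust to this, which is an additional argument for reading repertoire
performance through GA.

Other numerical details: argmax tie-breaks are lexicographic on the
canonical allele string everywhere a ranking is produced; negative-pair
rejection sampling raises after 1000·n attempts rather than looping forever
on dense pair spaces; `filter_top_cd8` keeps exactly ⌈fraction·n⌉ TCRs with
a stable, input-order tie-break, and the kept fraction is a required
argument with no default: sensible choices span orders of magnitude (a few
percent of a pre-sorted repertoire down to 0.01% of a huge mixed cohort),
so the caller must choose.

## Known limitations

Only A/B Class I alleles are modelled; Class II labels are storable but get
no dedicated logic.  The HLA encoder sees allele names, not molecular
structure, so it cannot generalize to alleles absent from training beyond
name similarity.  The train/test split fraction is configurable (default
80/20).  Hard-argmax relabeling (no EM-style soft responsibilities) is
implemented by design.
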