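# tispred — translation initiation site prediction from mRNA

Finding the translation initiation site (TIS) — the ATG at which the ribosome
actually starts translating — is a classification problem between one true
start per mRNA molecule and the many other ATG codons it carries.  The problem
is heavily imbalanced (typically one positive for every 20–130 negatives), and
naive training yields classifiers with excellent specificity and useless
sensitivity.  `tispred` is a toolkit for researchers studying start-codon
selection and class-imbalance handling in sequence classification.  It
implements:

- **Frame-aware candidate extraction.**  Every ATG occurrence is enumerated
  5'→3' and classified by region (upstream / TIS / downstream of the annotated
  start) and reading frame (in or out of frame with it: in frame ⇔
  `(pos − tis) mod 3 = 0`).  Fixed windows of U upstream and D downstream
  nucleotides are cut around each candidate (the ATG occupies +1..+3; a
  `-10+30` window is 40 nt); candidates the molecule cannot cover are dropped,
  never padded.
- **One-hot encoding plus biological feature flags.**  Windows are encoded
  4 bits per nucleotide (A=1000, C=0100, G=0010, T=0001).  Optional binary
  flags append: an upstream in-frame ATG, an in-frame stop codon within
  100 nt (a true start that close to a stop would encode ≤ 33 residues), and
  in-frame CTG/GAC/GAG/GCC codons in the downstream window.
- **Cluster-based undersampling.**  Three strategies shrink the negative
  class before training: uniform *random* undersampling; *SBC*, which
  clusters both classes with k-means and draws majority samples per cluster
  in proportion to the cluster's majority/minority ratio,

      SSize_MA_i = (m · Size_MI) · (Size_MA_i / Size_MI_i) / Σ_j (Size_MA_j / Size_MI_j),

  apportioned to integers by largest remainder; and *M-Clus*, which clusters
  the majority class alone into k = ⌈Size_MI / s⌉ clusters and selects from
  each the s members nearest its centroid.
- **A fixed SVM.**  Degree-4 polynomial kernel `(x·x' + 1)^4` with
  error/margin trade-off C = 1; no hyperparameter search.
- **InAKnow — inclusion of acquired knowledge.**  Under the ribosome scanning
  model downstream ATGs are never evaluated, so their negative label is an
  assumption.  The three-level procedure trains on positives vs upstream
  out-of-frame negatives (Level 1), labels every downstream candidate with
  that model (Level 2), then re-balances the pooled relabeled data and
  retrains (Level 3).  This recovers downstream candidates in genuine start
  context, reduces the class imbalance, and sharply improves precision.
- **Evaluation.**  Accuracy, precision, sensitivity, specificity and adjusted
  accuracy `Adj = (Se + Sp)/2` from the confusion matrix, 10-fold
  cross-validation that splits by molecule and balances training folds only,
  and ROC points from a threshold sweep.
- **A synthetic-mRNA generator** with 5'UTR / Kozak-context TIS / open
  reading frame / 3'UTR anatomy and plantable decoy ATGs, so the whole
  pipeline is testable without any database download.

## Worked example

Simulate 60 annotated molecules and cross-validate the default configuration
(window `-10+30`, features `ATG+STOP+GAG`, M-Clus balancing, InAKnow on,
degree-4 polynomial SVM):

```bash
$ tispred simulate --n-molecules 60 --seed 4 --out-dir sim
INFO simulated 60 molecules (785 ATG occurrences) into sim
$ tispred evaluate sim/molecules.fasta sim/annotations.tsv \
      --balancer mclus --n-folds 10 --seed 4 --out-dir cv
INFO cross-validation means: Ac=98.03  Pr=96.93  Se=89.05  Sp=99.47  Adj=94.26
```

The means are over the ten held-out folds, each evaluated with its natural
imbalance: 89% of true starts are recovered (Se) while 99.5% of decoy ATGs
are rejected (Sp); the adjusted accuracy 94.26 is their average and the
headline number for imbalanced data.  Per-fold confusion counts and metrics
land in `cv/cv_folds.tsv`, the full report in `cv/cv_report.json`, ROC points
in `cv/cv_roc.tsv`, and the resolved configuration next to them:

```
fold  TP  FP  TN  FN  Ac      Pr      Se      Sp      Adj
0     6   0   37  0   100.00  100.00  100.00  100.00  100.00
1     9   2   56  0   97.01   81.82   100.00  96.55   98.28
...
```

The other subcommands are `extract` (audit TSV of candidate windows),
`train` (serialized model + InAKnow sidecar counts) and `predict`
(per-candidate labels and decision values).  Every command accepts the same
flags or a YAML config, in the conventional notation (`--window -10+30`,
`--combo ATG+STOP+GAG`).

## Layout

```
src/tispred/
  seqmodel.py    records, candidate enumeration, windows, 4-bit encoding
  features.py    biological feature flags and sample assembly
  balancing.py   random / SBC / M-Clus undersampling
  classifier.py  fixed polynomial-kernel SVM wrapper
  inaknow.py     three-level acquired-knowledge procedure
  evaluation.py  metrics, cross-validation, ROC
  simdata.py     synthetic mRNA generator
  io.py, cli.py  formats and command-line interface
```

See `docs/methods.md` for the model, its assumptions, and the design
decisions.
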