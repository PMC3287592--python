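# Methods

## Problem and model

A eukaryotic mRNA carries one translation initiation site (TIS) and many
other ATG codons.  Discriminating the true start is a binary classification
over candidate ATGs, governed biologically by the ribosome scanning model:
the 40S subunit binds the 5' cap and scans 5'→3', initiating at the first
ATG in adequate context.  The strongest context determinants are a purine at
−3 and a G at +4 (the critical positions of the Kozak consensus
`gcc[a/g]ccATGg`); a start is also expected to open a reading frame, i.e. to
have no nearby in-frame stop codon.

`tispred` classifies candidates from a fixed sequence window plus a few
binary flags, with an SVM, after undersampling the overwhelming negative
class, optionally refining the labels of downstream candidates with the
model's own predictions (InAKnow).

## Coordinates and extraction

Biological coordinates are 1-based with the candidate ATG at +1..+3 and no
position 0; internally everything is 0-based half-open.  A window `-U+D`
covers positions −U..−1 and +1..+D, so it is U+D nucleotides long and D
counts from the A inclusive (some prior work instead centres windows on the
ATG — this package does not).  The default is `-10+30`, the configuration
that balances sensitivity (driven by near-context positions) against
specificity (helped by downstream coding content).

Rules, applied in this order:

- Records whose annotated start is not an ATG, or containing characters
  outside {A,C,G,T} (ambiguity codes included), are rejected at load and
  counted per reason; no imputation.
- Molecules with fewer than U nucleotides before the TIS, or ending before
  +D, are discarded with counted reasons.  (The source literature states the
  upstream filter ambiguously as a CDS-length condition; the operative rule
  implemented is "≥ U nucleotides upstream of the annotated TIS".)
- Candidate windows that the molecule cannot cover are dropped, never
  padded; the same rule symmetric on both sides.
- Non-TIS candidates in frame with the TIS are excluded from training and
  evaluation by default (out-of-frame negatives only, matching how the
  negative sets are tabulated in the source study); a switch includes them.
- mRNA is single-stranded; there is no reverse-complement scanning.

## Features

All flags are computed relative to the candidate under scoring — at
prediction time the true TIS is unknown, so "in frame with the TIS" is
operationalised as in frame with the candidate:

- `UP_ATG`: an ATG at p < candidate with (candidate − p) ≡ 0 mod 3, searched
  over the molecule's whole upstream (a 10-nt window would make the flag
  nearly vacuous).
- `STOP100`: an in-frame stop (TAA/TAG/TGA) starting within 100 nt after the
  candidate A; the scan stops at the 3' end.  Raising the horizon can only
  flip 0→1.
- `CTG`, `GAC`, `GAG`, `GCC`: the codon at an in-frame offset wholly inside
  the window's downstream region +4..+D (configurable to the 100-nt horizon
  instead; the window region is the default).

Flags are appended to the one-hot bits as raw {0,1} values, matching the bit
range.  The default combination is `ATG+STOP+GAG`, the top-ranked set for
both reference organisms in the source study.

## Balancing

All methods return an exact subset of the majority class (no synthesis, no
duplication) of size `min(|majority|, m·|minority|)`, with m = 1 by default.
k-means is standard Lloyd iteration (scikit-learn, `n_init=10`, seeded); any
k-means reaching a local minimum of within-cluster sum of squares satisfies
the contract.

- **random**: uniform draw without replacement.
- **SBC** (k = 4 clusters over both classes): per-cluster quotas
  proportional to the cluster's majority/minority ratio; a cluster with no
  minority members uses Size_MI_i = 1 (the method authors' convention);
  real-valued quotas are apportioned by largest remainder so they sum to
  m·Size_MI, capped at each cluster's majority count with shortfall
  redistributed by the same rule.  Within-cluster selection is a uniform
  draw (a nearest-to-centroid variant is available).
- **M-Clus** (k = ⌈Size_MI/s⌉ clusters over the majority only, s ∈ {1,2,3},
  default s = 1 so k = Size_MI): each cluster contributes its s members
  nearest the final centroid (ties broken by input order).  Undersized
  clusters are backfilled — and any surplus trimmed — by global
  nearest-to-own-centroid rank so the output size is exact.  The "removed"
  sequences in the method's original wording are the ones *selected into*
  the balanced training set.  Distances are unweighted Euclidean on the same
  encoded vectors (bits + flags) used for classification.

## Classifier

A C-SVM with kernel `(x·x' + 1)^4` and C = 1.  The polynomial degree and
trade-off define the method; the remaining kernel constants differ between
libraries, so they are pinned to gamma = 1 and coef0 = 1 and documented.
The decision threshold is 0, with a 0 decision value mapped to −1.  Trained
models embed a layout fingerprint (window, feature combination, dimension)
and refuse vectors produced under any other layout.

## InAKnow

Level 1 trains on positives vs upstream out-of-frame negatives, balanced.
Level 2 assigns every downstream candidate its hard Level-1 prediction — no
confidence filtering, threshold 0.  Level 3 pools positives with
relabeled-positive downstream candidates against upstream negatives with
relabeled-negative ones, re-balances with the same balancer specification,
and trains the final model.  Whichever class is larger after pooling is
treated as the majority for balancing.  With an empty downstream set the
procedure degenerates to plain training and the relabel fraction is reported
as 0 of 0.

In cross-validation the three levels run entirely inside the training folds.
Held-out downstream candidates are never relabeled *into training*; their
*evaluation* labels, however, are assigned by the training fold's Level-1
model rather than assumed negative, because under the scanning model
downstream candidates have no observed class — they join the data only
through that classification.  Plain-mode evaluation labels every non-TIS
candidate negative.  This distinction is what makes the procedure's
precision gain measurable: relabeled downstream candidates the final model
accepts are counted as true rather than false positives.

## Evaluation

Ac = (TP+TN)/total, Pr = TP/(TP+FP), Se = TP/(TP+FN), Sp = TN/(TN+FP),
Adj = (Se+Sp)/2, reported as percentages.  A metric with a zero denominator
is undefined and rendered as a dash; full precision is kept internally and
display rounds half-up to two decimals.  Cross-validation partitions
*molecules* (so one mRNA's positive and negatives can never straddle
train/test), stratified on positive-window extractability so every fold
holds positives; fold sizes differ by at most one.  Training folds are
balanced (and InAKnow applied) per fold; the held-out fold keeps its natural
imbalance.  A leakage audit inside the loop asserts that no held-out
molecule contributes a training sample.  ROC points come from a standard
threshold sweep over the decision values.

## Synthetic data

Each molecule is assembled as 5'UTR + CDS + 3'UTR from a position-independent
base composition (uniform by default): the CDS starts with ATG, ends with a
stop codon, contains no internal in-frame stop, and its length (including
both) is a multiple of 3 drawn from 90–600 nt.  With probability
`kozak_strength` (default 0.9) the TIS receives the full Kozak consensus
template — GCC(A/G)CC upstream, G at +4 — the −3 purine and +4 G mandatory
and the flanking positions best-effort under the constraint checks below.
The template is the consensus itself rather than only its two critical
positions: with just the −3/+4 determinants among 160 one-hot bits, the
pinned polynomial kernel has too sparse a signal to learn the
context/open-frame conjunction at realistic training sizes, and no
classifier could meet the recovery targets below under that design.

Decoy ATGs are planted in the UTRs and at out-of-frame CDS positions at
`decoy_rate` expected decoys per 100 nt (default 1.0), each forced into weak
context (pyrimidine at −3, non-G at +4).  Chance ATGs additionally arise
from the base composition at ≈ 1/64 per position and keep whatever context
they fall in.  Every mutation is constraint-checked: writes never touch the
start codon, terminal stop, or previously fixed context positions, and never
create a stop codon in the CDS frame (a C is the universal safe repair
nucleotide — no stop codon and no ATG contains one).

`context_positive_downstream_frac` upgrades a Bernoulli share of all
downstream out-of-frame ATGs — planted and chance alike, so the ground-truth
strong fraction among the candidates InAKnow scores equals the knob — to the
full template with their reading frame cleared of stops for 100 nt where the
molecule permits.  These are the candidates the acquired-knowledge step
should recover; they are recorded in the truth table and never labelled
positive for supervised training.

Default 5'UTR lengths are uniform 10–150 nt, a typical mammalian range,
which at U = 10 reproduces the upstream-negative:positive ratio (~1.2:1)
tabulated for the source study's reference organism; 3'UTRs are 20–200 nt.
The generator does not model organism-specific codon usage or GC content,
introns/splicing, or non-ATG starts — so passing tests demonstrate the
pipeline's mechanics and its response to context signal, not performance on
real transcriptomes, where context determinants are weaker and composition
is structured.

## Problem sizes and numerical choices

The acceptance script and end-to-end tests run the default configuration on
120 simulated molecules (≈ 1000 candidate windows) for cross-validation, 80
molecules (≈ 500 downstream candidates) for the relabel-recovery experiment,
and 20 paired 90-molecule replicates for the plain-vs-InAKnow precision
comparison — sizes comparable to the smaller organism databases in the
source study and sufficient for the stated tolerances (3 binomial standard
errors for the recovery fraction; a one-sided sign test at α = 0.05 for the
precision direction).  k-means uses 10 seeded restarts and scikit-learn's
default tolerance; quota rounding is largest-remainder with ties broken by
input order; all randomness flows from explicit integer seeds, and every
balancer, trainer and generator is byte-reproducible given its seed.

## Known limitations

- The paper-derived bookkeeping of relabeled counts in the source study is
  internally inconsistent and is not reproduced; the package reports its own
  relabel counts.
- No probability calibration, alternative kernels, oversampling, or non-ATG
  start handling.
- First-ATG-style baselines and external predictors are out of scope; their
  printed contingency counts are used only to verify the metric arithmetic.
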