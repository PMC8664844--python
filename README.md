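# thermoscm

Scoring-card prediction and characterization of thermophilic proteins from
primary sequence.

Thermophilic proteins (TPPs) keep a stable fold at 80–100 °C, which makes
them valuable in industrial catalysis and protein engineering — and makes
fast sequence-based screening of candidate TPPs useful long before any
structure is available. `thermoscm` implements the **scoring card method
(SCM)**: an interpretable classifier that, unlike an SVM, reduces to a
single weighted sum and one threshold, and whose weights — dipeptide
*propensity scores* — can be read directly as biology.

## The method

A protein `P` is encoded by its *g*-gap dipeptide composition: the
400-vector of fractions `f_d` of ordered residue pairs separated by `g`
intervening residues (`g = 0` is classic dipeptide composition). A scoring
card assigns each dipeptide `d` a propensity score `PS_d ∈ [0, 1000]`, and
the protein's score is the convex combination

```
S(P) = Σ_d  f_d · PS_d ,        predict thermophilic  ⇔  S(P) ≥ threshold.
```

Card construction has two stages:

1. **Statistical estimation** — each dipeptide's propensity is the
   difference of its class-mean compositions (thermophilic minus
   non-thermophilic), min–max rescaled onto [0, 1000].
2. **Genetic-algorithm refinement** — the 400 scores are optimized under
   the composite fitness `Fit = 0.9·AUC_cv + 0.1·R`, where `AUC_cv` is the
   mean held-out-fold AUC over a seeded stratified 10-fold plan and `R` is
   the Pearson correlation with the initial card (a regularizer against
   overfitting). The GA is run several times and the card with the highest
   cross-validated MCC is kept; the decision threshold is the
   training-accuracy-maximizing midpoint between consecutive scores.

Performance is reported as ACC, sensitivity, specificity, MCC and ROC AUC.
For interpretation, per-residue propensities (the mean of the 40 dipeptide
scores containing a residue) can be correlated against AAindex
physicochemical scales, and dipeptides ranked by score.

A synthetic benchmark generator ships with the package: negatives are drawn
i.i.d. from a background amino-acid composition, positives from a
first-order Markov chain with planted dipeptide enrichment of controllable
strength, so every pipeline stage is testable without downloads and against
an analytic ground truth.

## Worked example

Simulate a planted-signal benchmark (300 sequences per class; every residue
is 3× more likely to be followed by Glu or Lys in the positive class),
train a card, and predict on a fresh draw:

```
$ thermoscm simulate --out-pos train_pos.fasta --out-neg train_neg.fasta --config sim.json
wrote 300 positives and 300 negatives
$ thermoscm train --pos train_pos.fasta --neg train_neg.fasta --g 0 --seed 7 \
      --pop 20 --generations 20 --runs 3 --out model.json
trained card: g=0 threshold=209.06 cv_mcc=0.971 -> model.json
$ thermoscm predict --model model.json --fasta test_pos.fasta --out pred.csv
$ head -3 pred.csv
id,score,label
pos00000,247.4746,positive
pos00001,219.5107,positive
```

On the held-out draw this card reaches ACC 0.962, Sn 0.973, Sp 0.950,
MCC 0.924 and AUC 0.996. Characterization recovers the planted biology:

```
$ thermoscm characterize --model model.json --aaindex aaindex.txt \
      --fasta test_pos.fasta --fasta test_neg.fasta --out reports
scores: positives 243.48 +/- 19.08, negatives 185.11 +/- 11.70
$ head -3 reports/top_dipeptides.csv
rank,highest,score_high,lowest,score_low
1,KE,1000.00,GL,0.00
2,EK,961.79,LL,13.36
```

The top-scoring dipeptides are the planted Glu/Lys pairs, the top residues
are Lys (326) and Glu (310), and the card's residue propensities correlate
most strongly (R = 0.73) with the AAindex scale for surface composition of
amino acids in thermophile intracellular proteins — the charged-residue
signature the generator planted.

Other subcommands: `score-table` dumps the 400 propensity scores as CSV,
`sweep` runs a cross-validation sweep over gap sizes `g = 0…9` (with
optional independent test) and prints per-gap rows with mean/SD summary
lines. Real datasets are supplied as a positive and a negative FASTA file;
records with non-standard residues (B, U, X, Z, …) are dropped, and
`thermoscm.io.split_balanced` produces class-balanced train/test partitions.

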