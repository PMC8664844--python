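# Methods

## Model

The scoring card method (SCM) is a linear, interpretable two-class
classifier over g-gap dipeptide composition. A sequence of length `L`
contributes `L − g − 1` ordered pairs `(seq[p], seq[p+g+1])`; `g` counts
the residues skipped between the pair members, so `g = 0` means adjacent
residues and reproduces classic dipeptide composition. Sequences shorter
than `g + 2` are rejected rather than zero-filled: a zero vector would
break the sum-to-one invariant of the composition and silently score 0.

The protein score is `S(P) = Σ_d w_d · PS_d`. The weights `w_d` are the
normalized composition fractions, making `S(P)` a convex combination of
the 400 scores, bounded by the card's score range and independent of
sequence length — which is what makes scores of proteins of different
lengths comparable against a single threshold. A `mode="count"` switch on
the scoring functions preserves the alternative reading in which raw pair
counts are used as weights; it is not used anywhere else in the package.

### Initial estimation

For each dipeptide the raw propensity is
`diff(d) = mean_pos f_d − mean_neg f_d`, the difference of class means of
per-sequence fractions. Averaging per-sequence fractions (rather than
pooling counts) weights every sequence equally regardless of length,
matching the per-sequence definition of the composition itself. The 400
differences are min–max rescaled onto [0, 1000], so the estimated card
always attains exactly 0 and 1000 at its most class-biased dipeptides.
If every difference is identical (e.g. the two classes are the same
sample), all scores are set to 500, the scale midpoint — the symmetric,
information-free card. Swapping the classes maps every score `s` to
`1000 − s`.

### Genetic-algorithm refinement

The GA treats the 400 scores as a real-valued genome with composite
fitness `w1·AUC_cv + w2·R` (defaults 0.9/0.1). `AUC_cv` is the mean
held-out-fold rank AUC of the candidate's protein scores over a stratified
fold plan fixed once per run; because a candidate card is a fixed scorer
(nothing is re-fit per fold), fold-averaging is an honest use of
cross-validation inside the fitness. `R` is the Pearson correlation with
the initial card and acts as a shrinkage term toward the statistical
estimate; a zero-variance candidate is assigned `R = 0` so fitness is
always defined.

GA internals (a genuinely open design choice, fixed as follows): seed
population = the initial card plus Gaussian-perturbed copies
(σ = `mutation_step`, default 50 score units); size-2 tournament
selection; uniform per-gene crossover at rate 0.8; per-gene Gaussian
mutation at rate 0.05; scores clipped to [0, 1000] after every operation;
2 elites carried unchanged, which makes best-so-far fitness monotone.
Defaults are population 50 × 100 generations; the test-suite and
benchmark experiments use a desk-scale configuration (population 20,
20 generations, 3 runs) under which the whole suite completes in seconds —
on the default synthetic benchmark the search is nearly converged after a
handful of generations, so larger budgets buy little.

The decision threshold is *not* a 401st gene: the AUC fitness is
threshold-free, so the threshold is chosen after optimization as the
smallest training-accuracy-maximizing midpoint between consecutive
distinct scores. Equality at the threshold classifies as positive.
Repeated runs use seeds `seed, seed+1, …`; the returned card is the one
with the highest cross-validated MCC (threshold re-chosen per fold on the
in-fold scores), ties going to the earlier run. Every run is bit-exactly
reproducible from its inputs and seed.

## Evaluation

ACC, Sn, Sp and MCC follow the standard 2×2 definitions with positive =
thermophilic. Conventions for degenerate tables: any zero factor in the
MCC denominator gives MCC = 0, and an empty truth class gives Sn (or
Sp) = 0, so every fold yields a complete report. AUC is the rank-based
probability that a random positive outscores a random negative with ties
credited 0.5 (identical to trapezoidal ROC area); the implementation
delegates to scikit-learn and is cross-checked in the tests against
explicit pairwise enumeration. `cross_validate` re-estimates *and*
re-optimizes the card inside every fold — leak-free, unlike evaluating one
global card on its own folds — and reports fold means with sample (n−1)
standard deviations, the same SD convention used by the `aggregate`
summary rows. Fold plans are seeded stratified K-fold partitions
(class balance within ±1 per fold).

## Characterization

Per-residue propensities average the 40 dipeptide scores containing the
residue — 20 with it first, 20 with it second — so the homodipeptide is
counted twice. (Only 39 *distinct* dipeptides contain a residue; the
40-term convention keeps the two positional sums symmetric.) Residue
propensities are correlated (Pearson) against AAindex1 per-residue scales;
`NA` entries are handled by pairwise deletion, correlations over fewer
than 3 shared residues or with zero variance are reported as undefined and
excluded from rankings. Rankings use signed R, so "top" and "bottom" lists
answer different questions (properties tracking vs. opposing the
propensity). The AAindex1 flat-format parser is written in-package
(two-row, ten-column `I` block; records delimited by `//`).

## Synthetic benchmark

The generator emulates the statistical structure the scoring card actually
models — a dipeptide-composition difference between two classes — without
pretending to be a real proteome.

* **Negatives**: i.i.d. draws from a background amino-acid composition,
  by default the Swiss-Prot average frequencies. A uniform background is
  deliberately *not* the default: under uniform frequencies all
  non-enriched dipeptides have identical expected composition differences,
  and those exact ties make the planted 400-dipeptide ranking
  unrecoverable in principle, defeating the generator's purpose as a
  parameter-recovery benchmark.
* **Positives**: a first-order Markov chain whose transition weights are
  background products multiplied by per-dipeptide enrichment factors and
  renormalized per preceding residue. A first-order chain (rather than
  residue reshuffling) plants genuine pair signal partly independent of
  single-residue composition. With `g_signal > 0` the chain conditions on
  the residue `g_signal + 1` positions back, planting the signal at that
  gap.
* **Default signal**: every residue is 3× more likely to be followed by
  Glu (even alphabetical rank) or Lys (odd rank) in the positive class —
  20 enriched dipeptides, multiplier 3. This caricatures the
  charged-residue (salt-bridge) dipeptide enrichment of thermophilic
  proteomes, and putting one enriched pair in every transition row makes
  the renormalization touch all 400 dipeptides, so the analytic truth
  ranking is informative everywhere.
* **Sizes**: 300 sequences per class, lengths uniform on [100, 300] —
  large enough that the statistical card recovers the planted ranking
  (Spearman ≥ 0.8) and the end-to-end pipeline exceeds 0.9 held-out AUC,
  small enough that the full benchmark runs in about a second.
* **Determinism**: every sequence has its own RNG substream keyed by
  `(seed, class, index)`, so datasets are identical regardless of
  generation order or batching.

`planted_truth` returns the exact expected per-sequence pair-fraction
difference between the generators at the planted gap, computed from the
chain's step-wise marginals and averaged over the uniform length draw; the
tests verify it against a 5000-sequence Monte-Carlo estimate.

What the generator does **not** emulate: real thermophile/mesophile
residue usage, homology-induced redundancy (no CD-HIT-like structure),
domain architecture, or length–composition dependence. Passing the
synthetic benchmarks therefore demonstrates that the pipeline estimates,
optimizes, thresholds and evaluates correctly — not that any particular
accuracy will transfer to curated thermophile datasets, which users must
supply themselves as FASTA.

## Numerical conventions and edge cases

* Dipeptides are ordered alphabetically row-major internally; all
  serialized artifacts key by two-letter dipeptide strings, so the
  internal order is unobservable.
* Model files are JSON (scores keyed by dipeptide, plus gap, threshold,
  provenance, metadata) — human-inspectable and order-independent.
* Any residue outside the 20 standard letters disqualifies a record (the
  conservative generalization of dropping B/U/X/Z-containing sequences);
  lower-case and whitespace are normalized away at read time; duplicate
  FASTA ids are an error because reports key on id.
* Balanced splitting partitions positives exactly
  (`floor(fraction · n_pos)` to train) and samples negatives without
  replacement to match; it requires at least as many negatives as
  positives.
* Ties: classification at threshold → positive; protein rankings and
  dipeptide rankings break score ties alphabetically; equal-fitness GA
  individuals keep the earlier index; equal-MCC runs keep the earlier run.

## Known limitations

* The scoring card sees only (gapped) pair composition; signals requiring
  longer context, position specificity or structure are invisible to it.
* Threshold selection maximizes training accuracy and can overfit very
  small datasets; the GA's fitness guards the ranking, not the cutoff.
* The GA is a stochastic search: different seeds give different (equally
  valid) cards, and only the selection-by-CV-MCC protocol, not any
  particular score table, is reproducible science.
* `aggregate` treats metrics as independent columns; it does not pool
  confusion counts across folds.
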