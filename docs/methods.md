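# Methods

## Model

`triplexpot` classifies nucleotide sequences as triplex-forming or not
from composition alone. One pipeline serves two roles: a **lncRNA model**
(is this transcript among the lncRNAs most likely to form DNA:RNA
triplexes in practice?) and a **DNA-site model** (is this DNA region a
likely triplex host?). Both consume FASTA; RNA input is handled by
mapping U to T, since every feature is alphabet-based.

### Featurization

A sequence of length n yields a 90-dim vector:

1. **k-mer frequencies**, k = 1, 2, 3 (84 features). Overlapping windows,
   denominator n − k + 1, lexicographic order over (A, C, G, T) within
   each k block. Each block sums to 1 for n ≥ k.
2. **kmerscore**, k = 1…6 (6 features): the mean over windows of
   log(M_neg(hᵢ)/M_pos(hᵢ)), where M_pos/M_neg are the class-mean k-mer
   profiles of the *training* data. Natural log; the base only rescales
   the feature but is fixed for reproducibility. Because every window of
   the same word contributes identically, the implementation computes the
   equivalent frequency-weighted dot product; the test suite checks this
   against the explicit per-window sum.

Class-mean profiles are smoothed by adding a pseudocount (default 1e−6)
to every entry and renormalizing. This is a mathematical necessity, not a
tuning knob: for k = 6 there are 4096 words and small training sets are
certain to miss some in one class, making the log-ratio undefined. The
pseudocount is exposed in the API and serialized with the profile.

Profiles are fitted on the raw training-fold positives and negatives,
*before* bagging or down-sampling, so bootstrap duplicates cannot tilt
the class means toward the weak subtype. They are stored inside every
saved model, so prediction on new data always reuses training-time means
and test information can never leak into the features. Sequences shorter
than 6 nt (the largest kmerscore k) are rejected rather than padded.

### Classifier

The 90-dim vector is treated as a length-90 single-channel 1-D signal:

    conv(32 filters, kernel 7, same padding) → ReLU → maxpool(3)   90 → 30
    conv(32 filters, kernel 6, same padding) → ReLU → maxpool(2)   30 → 15
    flatten → dense(32) → dropout(0.3) → sigmoid

The final conv stage emits feature maps of length 15 per filter; the
configuration validator recomputes the stage lengths and rejects any
architecture that does not reach the declared output length. Same-padded
convolutions are used because a valid-convolution chain with integer
pooling cannot produce a length-15 map from a 90-long input with these
kernels. Training minimizes binary cross-entropy with Adam (lr 1e−3,
batch 32) for 50 epochs by default — enough for convergence at the
training-set sizes this package targets (a few hundred rows after
balancing). All of this is configurable through `CNNConfig`.

The network is implemented directly in numpy (float64, explicit
backpropagation, first-maximum tie-break in pooling). Backprop is
verified against finite differences in the test suite. With a fixed seed,
initialization, batch shuffling and dropout masks are all drawn from one
seeded generator, so training is bit-reproducible run to run on the same
platform. Probabilities ≥ the decision threshold (default 0.5) map to the
positive class.

### Imbalance handling

* **Down-sampling**: training negatives are drawn uniformly without
  replacement down to the (augmented) positive training count, with a
  fresh draw per CV fold / repetition. If fewer negatives than that are
  available, all are used and a warning is raised.
* **Weighted bagging** (lncRNA role): the positive training set is
  enlarged to multiplier × N (default 3×) by bootstrap;
  round((1 − weak_fraction)·3N) draws come from all positives and the
  remaining draws from the weak-subtype pool only (defaults give the
  2N + N split). "Weak" marks the minority positive subtype — in the
  motivating data, the experimentally reported triplex lncRNAs, whose
  AT-rich composition resembles the negatives; without over-weighting,
  the model fixates on the CG-rich majority subtype. Draws in the
  all-positives share may also hit weak records (bootstrap from the full
  pool). The DNA-site role has no subtype structure and skips bagging.

### Evaluation protocols

Metrics: Acc, Sn, Sp, their harmonic mean Hm, F1 (with precision), plus
AUROC (trapezoidal, ties handled as blocks) and AUPRC (step-wise
precision-at-recall summation, the standard PR convention — linear
interpolation is biased for PR curves). Metrics with zero denominators
are reported as absent with a warning, never coerced to 0. AUROC is
cross-checked in the tests against the rank-statistic (concordance)
formulation, and the closed-form metrics against an independent tally.

* **Stratified five-fold CV**: per-class round-robin assignment after a
  seeded shuffle (fold sizes within ±1 per class). Each fold retrains
  everything from scratch — profile, bagging, down-sample, network — on
  the four training folds; the test fold is evaluated untouched, at its
  natural imbalance. AUPRC is therefore measured against the full
  imbalance; a balanced-test variant can be had by down-sampling inputs
  beforehand.
* **Leave-gene-out**: all transcript variants of one gene are held out as
  positive test data, the remaining positives train the model, and the
  run is repeated (default 5×) with fresh negative down-samples;
  negative test data come from the held-out side of a fold split over
  the negatives. This controls for within-gene redundancy: variants of
  one gene are near-duplicates, so ordinary CV can score a gene's
  variants by memorizing its siblings in the training folds.
* **Redundancy filter**: an approximate, deterministic stand-in for
  alignment-based clustering — greedy incremental clustering on
  4-mer-count cosine similarity, visiting records by decreasing length —
  so removed-redundancy experiments can be run at desk scale. It is not
  bit-compatible with CD-HIT; identity thresholds (0.9/0.8) map directly
  onto the cosine cutoff.

## Synthetic data

The generator reproduces the compositional structure the method
exploits, not triplex biophysics. Defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| strong-subtype base probs | (0.15, 0.35, 0.35, 0.15) | CG-rich majority positive subtype |
| negative base probs | (0.35, 0.15, 0.15, 0.35) | AT-rich background |
| weak subtype | negative + δ·(strong − negative), δ = 0.3 | minority subtype that resembles negatives |
| subtype counts (lncRNA) | 50 strong : 20 weak | ≈2.5:1 subtype ratio |
| imbalance | 1:68 (lncRNA), 1:5 (DNA-site) | the two roles' class ratios |
| lengths | 200–2000 nt (lncRNA), 60–400 nt (DNA-site) | plausible scales; features are length-normalized, so length mainly affects variance |
| gene blocks | 1–5 variants/gene, point-mutation rate 0.02 | within-gene redundancy for leave-gene-out and filtering tests |

Sequences are i.i.d. draws from the base probabilities (optionally with a
planted motif, off by default since the feature set is composition-based).
What passing tests on this generator show is that the pipeline recovers
compositional class structure, behaves at chance when there is none, and
that leave-gene-out demotes genes whose variants do not resemble the
positive class. What they do not show: performance on real lncRNA data,
which has positional structure, shared repeats, splice-variant families
and annotation noise that i.i.d. composition draws cannot emulate.

## Numerical and design choices

* Seeds: every stochastic stage (generation, shuffling, down-sampling,
  bagging, weight init, dropout) takes an explicit seed; orchestration
  derives per-fold sub-seeds from the run seed via `SeedSequence`.
  Record order is canonicalized by id before any seeded draw, and class
  means use id-sorted summation, so results are independent of input
  order.
* Ties: pooling takes the first maximum; ROC ties are handled as blocks
  (inherited from the trapezoidal implementation); redundancy filtering
  breaks length ties by id.
* Degenerate inputs: empty classes, single-class labels, non-finite
  features, sequences shorter than the largest k, and unknown genes are
  errors that name the offender; ambiguity codes other than N are always
  rejected, N-containing records are dropped (and logged) only on
  request.
* Problem sizes in the shipped experiments (e.g. 100 positives / 500
  negatives for the composition-gap runs, 30-epoch training for the
  gap experiments) are desk-scale choices that keep the full protocol —
  including 15 network trainings for a 3-seed × 5-fold run — comfortable
  on a single CPU core while leaving the conclusions unchanged.

## Known limitations

* Composition features cannot see position: two sequences with permuted
  windows are identical to the model.
* The original hyperparameters of the motivating architecture (filter
  counts, kernel sizes, optimizer schedule) are not published in full;
  the defaults here are reasonable choices exposed in `CNNConfig`, not a
  claim of equivalence.
* The redundancy filter approximates clustering by composition, so it can
  merge compositionally similar but unrelated sequences that an
  alignment-based tool would keep apart.
* Bit-reproducibility is guaranteed within one platform/BLAS build, not
  across different numpy builds.
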