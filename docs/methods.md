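# Methods

## Overview

`dbnscreen` implements an unsupervised reweighting scheme for molecular
fingerprints: per descriptor, a stack of Bernoulli RBMs is pretrained
greedily, unrolled into an autoencoder and fine-tuned by backpropagation;
reconstruction errors drive both the removal of outlier features and the
selection of the most re-constructible ("important") features; selections
from several descriptors are fused into one combined descriptor that is
then searched with the Tanimoto coefficient and evaluated with the
recall@n% / Kendall-W protocol.

## RBM and DBN training

* **Units and conditionals.** Visible and hidden units are Bernoulli;
  conditionals are factorized logistic functions of the weighted input.
  Count fingerprints (ECFC-style) are binarized with threshold 0 (entry > 0
  → 1) before training, since the energy model is defined over {0,1} units.
* **Contrastive divergence.** The positive phase uses hidden
  *probabilities* given the data; the negative phase runs a k-step Gibbs
  chain from each data vector, sampling binary states along the chain and
  taking probabilities at the final step. This is the standard
  variance-reduction choice; k (`gibbs_steps`) is configurable.
* **Initialization.** Weights start uniform on [0, 1) by default with a
  `gaussian` (sd 0.01) alternative, biases at zero. The uniform start is
  atypical for RBMs (all-positive weights) and can converge more slowly;
  both options are exposed and seeded.
* **Hyperparameter defaults.** `TrainConfig` defaults to the full-scale
  protocol: learning rate 0.05, 70 epochs, batch size 128, 50 Gibbs steps,
  with architecture 1024→2000→1800→1300→800→300 appropriate for a ~10⁵
  molecule corpus. Desk-scale runs (tests, the demo pipeline, the
  acceptance script) use 64→32→16, CD-1, 8 pretraining epochs and 25
  fine-tuning epochs — sizes chosen so a complete run with ground-truth
  checks executes in seconds while the planted structure is still
  recovered reliably.
* **Fine-tuning.** The stack is unrolled encoder→decoder with the decoder
  initialized to the transposed weights and visible biases; weights are
  untied from the first update. The objective is the per-molecule mean
  squared reconstruction error; optimization is plain minibatch gradient
  descent (one seeded shuffle per epoch). No labels are used anywhere.
  Gradients are exact backpropagation, verified against central finite
  differences to a relative error below 1e-4.
* **Reconstruction.** Deterministic mean-field pass to the deepest layer
  and back — no sampling — so reconstruction is a pure function of the
  model. Per-entry error `E = |X − Y|`; per-molecule error is the L2 norm
  of an E row (L1 switch available); per-feature score is the column mean
  of E.

## Iterative outlier removal

Each round re-initializes a DBN with a seed derived from (root seed, round
index), trains, reconstructs, and removes the `ceil(fraction × M_current)`
features with the largest mean column error; the loop stops when the mean
per-molecule error changes by at most the convergence tolerance between
rounds, when the round budget (`max_rounds`) is reached, or immediately
after one round if the fraction is zero. Design choices worth noting:

* Re-initializing per round (rather than continuing training) makes each
  round's error comparable and the whole loop reproducible; the derived
  seeds keep rounds independent.
* Features are never removed after the final reconstruction, so the
  returned error matrix always describes exactly the surviving columns.
* The pipeline default is `max_rounds=2` — one removal pass — because each
  pass removes a fixed fraction of the *current* features and additional
  passes eat into genuine signal once the planted/true outliers are gone.
  The library default (10) simply guarantees termination.
* Removed indices are reported in original-matrix coordinates.

## Error PCA and feature selection

The N×M error matrix is transposed (features as rows), each feature's row
is centered across molecules, and the covariance is taken as `C = DDᵀ`
without a 1/(N−1) factor — normalization changes neither eigenvectors nor
the relative distances used for ranking. Components are the top-k (k = 3)
eigenvectors of C, sign-fixed so each component's largest-magnitude entry
is positive. Feature coordinates are the projections of the rows of D onto
the principal directions of D's row space, which by the SVD identity
`C = US²Uᵀ` equal `U_k·diag(s_k)`; the selection score is the Euclidean
distance of those coordinates from the origin. Features are kept in
ascending distance order (ties broken by ascending index) subject to an
optional distance threshold (default 3.0 in coordinate units — data-scale
dependent, so the top-k cap, default 300, is the primary selector).

Two screening representations of the combined descriptor are supported,
since either reading is defensible: continuous Tanimoto over the
reconstructed feature weights at the selected columns (default), or binary
Tanimoto over the original bits at those columns.

## Similarity search and evaluation

* The reference structure is excluded from its own ranked list (keeping it
  would inflate every recall uniformly); a switch restores it.
* Cutoff counts use `ceil(fraction × (N−1))`.
* Ranking ties are broken by ascending molecule id, making retrieval
  invariant to database row order.
* Recall uses the class size minus one as denominator, consistent with
  query exclusion.
* Kendall W assigns rank n to the highest recall within each judge
  (activity class), with mid-ranks on ties; significance uses the
  chi-square approximation χ² = m(n−1)W on n−1 degrees of freedom.
* Published-table summaries (`gains`) are computed from the
  table-precision column means — exact decimal means of the 2-decimal cell
  values, rounded half-up — because that is the arithmetic a printed
  summary row implies; full-precision means are also exposed
  (`RecallTable.column_means`).

## Synthetic data: what it emulates and what it does not

The generator plants the statistical structure the method exploits:
several activity classes of configurable sizes; per class a disjoint block
of signal bits on with probability `p_signal_on` (default 0.9) inside the
class and at the background rate elsewhere; background bits on with
`p_background_on` (default 0.15); and outlier features flipped on with
probability 0.5 irrespective of class — maximally non-reconstructible
noise. Descriptors share molecules and labels but draw independent signal
positions, mimicking complementary fingerprint types.

The background rate matters: folded 1024-bit fingerprints typically have
bit densities in the 5–20% range, and noise bits must genuinely vary for
"re-constructibility" to discriminate feature classes — at near-zero
density a background bit is almost constant and trivially reconstructible,
which would make low-error selection favor empty bits over chemistry. The
default 0.15 sits mid-range of that realistic band.

Not emulated: real substructure correlations (rings, scaffolds), folding
collisions, heavy-tailed bit frequencies, inter-class structural overlap.
Passing the recovery tests therefore shows the machinery identifies
planted reconstructability structure under controlled conditions; it does
not certify retrieval gains on real corpora, which the published MDDR
tables (embedded as fixtures) summarize instead.

At desk scale (2 classes × 100 molecules) recall at a 1%/5% cutoff is
bounded by the cutoff itself (e.g. at 5%: 10 retrieved of 99 same-class
actives = 10.1%), so saturated equal columns mean "everything retrieved",
and method differences show up only on harder or larger configurations.

## Numerical choices and degenerate inputs

* All randomness flows through explicit `numpy` Generators; pipeline
  stages derive independent seeds from the root seed with counter-based
  `SeedSequence` keys (all below 2³¹).
* The logistic function is scipy's `expit` (saturates without overflow).
* Enumeration of the joint Boltzmann distribution (the test oracle and
  `exact_moments`) is limited to V+H ≤ 20 states and log-sum-shifted for
  stability.
* A constant error matrix yields zero deviations, zero covariance and
  all-zero distances (no error); an empty selection is returned, not
  raised, when no feature passes the threshold.
* Tanimoto of two all-zero vectors is 0 by convention.
* Classes smaller than the requested number of reference structures fall
  back to using every member, with a warning.

## Known limitations

* Plain SGD fine-tuning (no momentum/adaptive rates); adequate at the
  scales exercised here, slow for the full 1024→…→300 architecture.
* Persistent CD is not implemented.
* No GPU path; everything is numpy on one CPU.
* The distance threshold's natural scale depends on the dataset; treat the
  top-k cap as the primary selector.
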