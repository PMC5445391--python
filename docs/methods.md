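# Methods

`saeppi` predicts whether two proteins interact using nothing but their
amino-acid sequences. The model is a stacked autoencoder (SAE) over
fixed-length pair encodings; this note records the model, the choices
behind the defaults, and what the synthetic benchmark does and does not
demonstrate.

## Sequence encodings

**Autocovariance (AC).** Each residue is mapped to seven physicochemical
descriptors — hydrophobicity, hydrophilicity, net charge index of side
chains, polarity, polarizability, solvent-accessible surface area, and
side-chain volume. Each descriptor row is standardized to zero mean and
unit variance *across the 20 residues* (population SD, tolerance 1e-9)
before use. For descriptor j and lag `lag` the feature is

    AC(lag, j) = 1/(n - lag) * sum_{i=1}^{n-lag} (X[i,j] - mean_j) (X[i+lag,j] - mean_j)

where `mean_j` is the mean of descriptor j over the whole sequence of
length n. The centring term is the *sequence mean*: this is the standard
autocovariance definition, it makes the encoding vanish identically on
homopolymers, and it makes the vector invariant under sequence reversal.
With `lag_max = 30` (the conventional choice for this encoding lineage;
configurable) a protein of any length ≥ 31 becomes a 210-vector, ordered
descriptor-major: (j=1, lag=1..30), (j=2, ...), ...

The descriptor values ship as a packaged TSV and can be overridden; the
tests anchor dimensional and analytic properties (standardization,
rank preservation, the homopolymer and reversal identities, agreement
with a brute-force double loop) rather than specific numeric entries.

**Conjoint triad (CT).** The 20 residues are collapsed into 7 groups by
dipole moment and side-chain volume — {A,G,V}, {I,L,F,P}, {Y,M,T,S},
{H,N,Q,W}, {R,K}, {D,E}, {C} — and a width-3 window slides along the
grouped sequence one position at a time. The feature vector is the raw
count of each of the 7³ = 343 triads, indexed first-position-fastest:
triad (a,b,c) maps to `a + 7(b-1) + 49(c-1)`. Counts are left
unnormalized at the per-protein level (the example sequence MREIVHIQAG
then shows exactly eight triads with count 1); all scaling is deferred
to the pair scaler below, which keeps that worked-example pattern exact.

**Pair assembly.** A pair is encoded by min-max scaling each member's
vector per feature to [0,1] and concatenating, giving 420 (AC) or 686
(CT) inputs. The scaler is fitted on the training split only and test
values are clipped to [0,1]; sigmoid units want bounded inputs, and
fitting per training fold keeps the protocol leakage-free. Pairs are
encoded in the order given in the pair file; the classifier is not
symmetrized (both-orientation augmentation can be done at the data
level if desired).

## Stacked autoencoder

Architecture: input → sigmoid hidden layer(s) → 2-unit softmax head.
Defaults are a single hidden layer of 400 units for AC input and 700
for CT — one medium hidden layer is enough at this input scale, and
capacity ordering is exercised in the tests.

* **Pretraining** trains each hidden layer in turn as an autoencoder on
  the activations of the layer below, minimizing mean squared
  reconstruction error through a sigmoid decoder. Decoder weights are
  *untied* from the encoder and discarded after pretraining (kept on the
  layer object for inspection).
* **Fine-tuning** minimizes softmax cross-entropy end to end through all
  encoder layers and the head.

Both phases use mini-batch gradient descent with momentum
(`v ← μv − η∇`, `θ ← θ + v`). Defaults: pretraining rate 0.5,
fine-tuning rate 0.1, momentum 0.5, batch size 100, 20 pretraining and
50 fine-tuning epochs — stable, conventional settings for sigmoid SAEs
at a few hundred input dimensions, all exposed in `TrainConfig`. No
denoising, sparsity, or weight decay is applied; the epoch budget is the
only regularizer.

Numerical choices: sigmoid computed in a two-branch form that never
exponentiates a positive argument; softmax shifted by the row maximum;
cross-entropy clamped with eps = 1e-12. Hidden weights initialize
uniform on ±4·sqrt(6/(fan_in+fan_out)) (the sigmoid variant of the
Glorot bound), biases zero; the softmax head starts at exactly zero so
an untrained model outputs (0.5, 0.5). An exact probability tie predicts
the negative class. All randomness descends from explicit integer seeds,
so training and prediction are bitwise reproducible; the analytic
gradients of both objectives are verified against central finite
differences (< 1e-6 relative) in the suite.

## Dataset construction

* **Filtering:** sequences shorter than 50 residues, with non-standard
  residues, or without a unique compartment annotation are removed, with
  a per-rule rejection log.
* **Negatives:** presumed non-interacting pairs are unique unordered
  pairs of proteins from *different* compartments, drawn uniformly;
  self-pairs and any supplied positive pairs are excluded. Sampling is
  by seeded rejection with an exact-enumeration fallback, so small
  exhaustive cases and large sparse cases are both handled.
* **Hold-out split:** uniform random, exact sizes, disjoint.
* **Redundancy (NR) filter:** a hold-out pair is removed when *either*
  member aligns at ≥ 25% identity to *any* training protein — the
  conservative reading, since one conserved member is enough to leak
  homology. Identity = identical aligned residues / alignment length
  including gap columns, from a global Needleman–Wunsch alignment
  (BLOSUM62, gap open 10, extend 0.5; all configurable). The alignment
  engine is Biopython's `PairwiseAligner`; an independent Gotoh dynamic
  program in the test suite checks the optimal scores. Scores are
  compared rather than identities because co-optimal alignments make
  identity-by-traceback ambiguous at equal score.
* **Folds:** stratified k-fold (default 10) via per-class shuffling and
  round-robin dealing with a carried counter, so fold sizes differ by at
  most one overall *and* within each class. Stratification stabilizes
  per-fold metrics on balanced data.

## Evaluation

Accuracy, sensitivity, specificity and precision from the confusion
counts, with class 1 (interaction) positive. A zero-denominator metric
is reported as `None`/`NA`, never silently 0 — degenerate folds must be
visible in sweeps. `cross_validate` refits the scaler and the network on
the k−1 training folds for every fold; `architecture_sweep` selects the
candidate with the highest mean CV accuracy, ties going to the smaller
parameter count.

## Synthetic benchmark

The generator emulates the *shape* of a curated PPI benchmark: random
i.i.d. sequences (natural residue frequencies by default, lengths
uniform on 50–200) with uniformly assigned compartments, and a balanced
pair list (default 1000 positive + 1000 negative over 3000 proteins).
Interaction is planted as motif co-insertion: with probability
`signal_strength` a positive pair receives the complementary motifs
`KWKWKWKWKWKWKWKWKWKW` / `DCDCDCDCDCDCDCDCDCDC` at random positions in
its two members. Periodic, compositionally extreme motifs were chosen
because they light up both encodings at once — strong short-lag
autocovariance in the hydrophobicity/charge descriptors and large spikes
in a handful of triad counts. Each positive protein appears in exactly
one positive pair; negatives are cross-compartment pairs of the
remaining proteins, so compartment structure is present (as in the
benchmark construction) but uncorrelated with sequence content.

At `signal_strength = 0` the classes are exchangeable and the pipeline
sits at chance; at 1.0 the default AC pipeline recovers the signal
essentially perfectly. The acceptance suite runs both ends on 2,000
pairs with 10-fold CV. These sizes keep a full run to a couple of
minutes on one core while leaving per-fold training sets (1,800 pairs)
large relative to the network.

What passing does **not** show: real interactomes carry homology
structure, compositional biases correlated with localization, hub
proteins appearing in many pairs, and interaction signals far subtler
than a planted 20-mer. Accuracy on the synthetic benchmark certifies the
pipeline's plumbing and learning dynamics, not biological performance;
published benchmark accuracies require the corresponding curated
datasets, which this package deliberately does not download.

## Known limitations

* CPU-only, dense NumPy; architectures beyond a few hidden layers of a
  few thousand units are out of scope.
* The redundancy filter is O(test proteins × training proteins) global
  alignments; for large benchmarks a pre-clustering step would be needed.
* Only binary classification with a 2-unit head is supported.
* The CT encoding discards triad position; the AC encoding discards
  everything beyond lag-30 covariance. Both are as blunt as they sound —
  that bluntness is the method.
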