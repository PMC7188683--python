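# Methods

## CKSAAP descriptor

For gap *j*, a sequence of length *L* contains *N_j* = *L* − (*j*+1)
ordered residue pairs (s[i], s[i+j+1]), i = 1…*N_j*. Block *j* of the
descriptor holds the 400 pair frequencies count(a,b)/*N_j* over the
alphabet A,C,D,…,Y in lexicographic pair order; the column of pair (a,b)
in block *j* is 400·*j* + 20·rank(a) + rank(b). Blocks *j* = 0…*k*
concatenate to a vector of length 400·(*k*+1) that sums to *k*+1. The
default *k* = 8 (3600 descriptors) follows the incremental-selection result
that gap 8 discriminates AFPs best; frequencies are used as-is, with no
further scaling, since they already live in [0, 1].

Two deliberate extensions beyond the bare definition:

* **Non-standard residues.** Validation is `strict` by default (fail with
  record id and position). The `mask` policy replaces B/J/O/U/X/Z/\*/- with
  `?`, which matches no pair but still occupies its position, so *N_j* (and
  hence the normalization) still reflects the true sequence length.
* **Short sequences** (*L* < *k*+2) make some *N_j* non-positive; that is a
  hard error by default, and `pad_policy="zero"` emits all-zero blocks for
  the unsatisfiable gaps (logged) for users who must encode fragments.

## Joint model

The encoder (input → 50 → 25 → 25 → 10 → LV), mirrored decoder, and
classifier head (LV → 10 → 10 → 10 → softmax over 2 classes) share the
latent layer and are trained *simultaneously* on

w_recon · MSE(X, X̂) + w_class · CE(y, ŷ) + λ · mean(|z|),

MSE taken over all matrix entries and CE the cross-entropy of the one-hot
2-class targets (identical to binary cross-entropy in the 2-class case).
Defaults: w_recon = w_class = 1 (the plainest reading of "trained
simultaneously"; both exposed), λ = 1e-4 as an L1 activity penalty on the
latent layer (the penalty form is a design choice — an absolute-value
activity penalty is the simplest sparsity regularizer and the latent is
non-negative under ReLU, so the penalty is differentiable almost
everywhere). Optimizer: RMSprop (ρ = 0.9, ε = 1e-8), learning rate 1e-3,
batch size 32 — conventional defaults for this optimizer family, both
configurable. Training runs up to 1000 epochs with early stopping
(patience 50) on the *combined* validation loss over a stratified 90:10
split (stratification prevents a degenerate single-class validation set at
the small class sizes typical here); the best-validation weights are
restored. All randomness (split, shuffling, initialization, dropout)
derives from one integer seed, and identical inputs give bit-identical
histories and predictions.

Placement choices the architecture sketch leaves open:

* Dropout (30 %) follows each *hidden* encoder and decoder layer, not the
  latent layer and not the reconstruction output: noise injected directly
  into the latent coordinates would corrupt the single representation both
  the decoder and the classifier consume and would fight the sparsity
  penalty. The classifier head carries no dropout.
* The latent layer and the decoder output use ReLU like every other
  autoencoder layer (the inputs are non-negative frequencies, so a
  rectified reconstruction is natural); `linear_decoder_output=True`
  switches the output layer to linear.
* `use_batchnorm=True` inserts batch normalization (batch statistics in
  training, running averages at inference) before each hidden autoencoder
  activation. Its gradients are exercised by the finite-difference check,
  but the flag is experimental: at the small batch/dataset sizes used
  here it tends to collapse the classifier to the majority class, and it
  is off by default.

The network is implemented directly on numpy with hand-written
backpropagation. A finite-difference gradient check over every parameter
(weights, biases, batch-norm scale/shift) guards the derivatives; the check
perturbs biases off their zero initialization first, because exactly-zero
pre-activations sit on the rectifier kink where the two-sided difference
quotient and the subgradient legitimately disagree.

Numerical conventions: softmax rows are clipped at 1e-12 inside the
cross-entropy; reconstruction quality is reported as 10·log₁₀(MSE) dB
(an exact zero maps to −inf with a warning); probability ties at exactly
0.5 resolve to the non-AFP class and are logged; a non-finite loss raises
immediately with the epoch at which it occurred.

## Metrics

All eight threshold-dependent quantities derive from the TP/FP/TN/FN
tallies with AFP positive. Zero-denominator conventions (each occurrence
logged): MCC → 0 when a factor under the root is zero, precision → 0 when
TP+FP = 0, F1 → 0 when precision+recall = 0. Balanced accuracy and
Youden's index satisfy youden = 2·BA − 1 identically.
`metrics_from_rates` reconstructs integer tallies from printed
sensitivity/specificity and class sizes (TP = round(sens·n_pos)) for the
count-based metrics, while computing BA and Youden directly from the rates
— this is how published comparison tables can be audited for internal
consistency without the underlying predictions. Display rounding follows
the field's tables (percentages to 1 d.p., indices to 2 d.p.); full
precision is kept internally.

## Synthetic data generator

Negatives are i.i.d. residues from a background distribution (uniform over
the 20 amino acids by default — uniform maximizes the clarity of
planted-signal tests; a natural-frequency background is available).
Positives are drawn from the same background, then `enrichment` plantings
(default 10) each overwrite two positions with a motif pair (a, b) at its
stated gap. Planting overwrites rather than inserts, so the two classes
have identical length distributions (uniform on [50, 300] residues by
default) and length cannot act as a confounder. The default motif is the
single ordered pair A…C at gap 3: a single pair concentrates the planted
signal in one descriptor column, and the gap is the largest for which the
default enrichment fits the shortest default sequence
(enrichment × (gap+2) ≤ L_min).

What the generator emulates: a minority class distinguished by enrichment
of specific k-spaced residue pairs at a controllable effect size, under
class imbalance, with exactly reproducible draws. What it does not
emulate: real amino-acid composition (unless the natural background is
selected), homology structure, intra-class heterogeneity of real AFP
sub-types, or genuinely nonlinear class boundaries — the planted signal is
*linear* in descriptor space. Passing recovery tests therefore shows the
pipeline can learn a known signal end to end, not that it matches
published performance on real benchmarks.

`ratio_split` builds training sets of one positive to *r* negatives
(n_pos_train positives plus r·n_pos_train negatives, sampled without
replacement); every remaining sequence becomes the test set, mirroring the
published protocol in which everything outside the training subset is
evaluation data.

## Experiment drivers and problem sizes

`run_ablation` evaluates every (ratio, LV) cell with R independent runs;
run *i* uses seed base+*i*+1, which drives both a fresh split and a fresh
initialization (the stronger reading of published mean ± std values;
mean uses the arithmetic mean, std the sample standard deviation with
ddof = 1, reported only for R ≥ 2). A failed run is logged with its seed
and excluded. The grid is bit-for-bit reproducible from the base seed.

`project_2d` compares the 2-latent-variable embedding with the top-2
principal components, both fit on training rows only and applied unchanged
to test rows. Separability in each plane is summarized as the balanced
accuracy of a nearest-centroid rule on per-dimension standardized
coordinates (standardization is required for a fair comparison: Euclidean
centroids are not scale-invariant and the two coordinate systems carry
arbitrary, different units). This is an operationalization of a visual
claim, not a published statistic — and on planted (linear) synthetic
signal the principal components are themselves discriminative, so the
latent space's advantage there is smaller than on real data.

The test suite and the acceptance script run at desk scale: 500 + 500
generated sequences with a 300/300 training split and 200/200 held out,
up to 300 epochs (early stopping typically fires near epoch 60–170), a
reduced ablation grid (LV ∈ {2, 4} × ratios {1:1, 1:3}, R = 3, 40
epochs), and a five-shuffle permutation control. The permutation control
averages several label shuffles because a single shuffle retains chance
label–truth correlation of order 1/√n that a flexible model amplifies
along the planted direction; the mean over shuffles is the meaningful
null summary. Library defaults remain at the full scale (1000 epochs,
patience 50).

## Known limitations

* No real AFP data ships with the package, and no attempt is made to
  reproduce published benchmark figures that require the external dataset;
  published tables enter only through rate-identity checks.
* The classifier is a point estimate; no calibration, no uncertainty.
* The permutation-control band (±0.05 around chance) is a property of the
  desk-scale study sizes; at other sizes the appropriate band scales with
  1/√n.
* Only the 20-letter protein alphabet is supported; nucleotide sequences,
  alignments and annotation formats are out of scope.
* Transfer learning and descriptor families other than CKSAAP are out of
  scope.
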