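# Methods

`tab2pix` converts a 1-D numeric clinical record into a 2-D image so
that a convolutional network can classify it, and packages the full
experimental protocol around that idea: loading, normalization, three
encodings, covariance-driven field ordering, a small VGG-style CNN, and
diagnostic evaluation. This note records the models, the defaults and
the design choices made where the design was genuinely open.

## Data model and preparation

A dataset is an N x d matrix of continuous (or ordinal) measurements
with a binary label. The label convention is fixed package-wide:
**0 = malignant (negative), 1 = benign (positive)**, so TN counts
correctly identified malignant cases and sensitivity refers to benign
recall. Two UCI breast-cancer layouts are supported natively (the
Original layout with nine integer features, `?` missing markers and a
2/4 class code; the Diagnostic layout with an M/B diagnosis and thirty
real features) plus a generic headered CSV. ID columns are dropped;
only predictive features are encoded.

Missing cells default to **row dropping** rather than imputation: the
published test-partition sizes for the Original dataset are consistent
with removing the sixteen affected rows before splitting, and dropping
avoids inventing values in a diagnostic context. Mean imputation is
available as an explicit alternative.

Min–max normalization maps each feature to [0, 1] using that column's
observed extremes; a constant column maps to 0, which keeps its bar
empty rather than drawing an uninformative half-height bar. By default
statistics come from the full dataset before splitting — the encodings
are defined on wrangled data and the repeated-attempt protocol
re-splits on every attempt — but `minmax_normalize(ds, stats=...)`
accepts train-only statistics for leakage-free use (values outside the
training range are clipped into [0, 1]).

Splitting takes `floor(0.20 * N)` rows for test, then
`floor(0.20 * remaining)` for validation, stratified by label. The
floor convention is fixed by the published test-set sizes
(e.g. 113 = floor(0.2 * 569)).

## Encodings

**Equidistant bar graph.** With bar width psi (default 1 px) and gap
gamma (default 2 px), the canvas side is `psi*d + gamma*(d+1)`; for
psi=1, gamma=2 this is 3d+2, approximately 3d. Bar k starts at column
`gamma + k*(psi+gamma)` and is drawn bottom-up over
`round(x_k * side)` rows at intensity 1 (rounding is half-away-from-
zero; bottom-up growth with rounding is the conventional way to draw a
bar chart, and we fix it as the package's convention). The
height equals the width by construction — no separate rescale pass.
The px2/px4 variants set psi to 2/4 with gamma fixed at 2.

**Normalized distance matrix.** `M[i,j] = |x_i - x_j|` (the Euclidean
distance between two scalar features), divided by its maximum entry so
the image attains 1 whenever the vector is non-constant; an all-zero
matrix is left as zeros rather than raising. Upscaling replicates each
pixel into an r x r block (default r=3, giving 3d x 3d) — exact
replication, no interpolation, so no new intensities appear.

**Combined.** Three aligned 3d x 3d channels in listing order:
(1) the distance matrix upscaled x3; (2) the bar graph — its native
3d+2 canvas is center-cropped by one pixel per side (our convention
for reconciling the two sizes; other psi values are resampled
nearest-neighbour);
(3) a row-wise copy of the vector, rows 3i..3i+2 constant at x_i.

PNG output quantizes to 8 bits (`round(v*255)`); the in-memory
contract stays real-valued in [0, 1].

## Field ordering

The sample covariance of the features is converted to a rank matrix:
within each row, the off-diagonal entry with the largest covariance
*magnitude* gets rank 1 (strong negative covariance is also
relatedness), ties breaking toward the lower column index so the result
is deterministic. An ordering's cost sums the symmetrized rank
`(ranks[i,j] + ranks[j,i]) / 2` over consecutive pairs of an **open**
path (bars form a line, not a ring); the rank matrix is not symmetric
row-wise, and averaging the two directions is our choice.

Minimizing this cost is a path-TSP. Two solvers:

* `brute_force_order` — exhaustive over all d! permutations (refused
  above d=10), lexicographically smallest order on ties. This is the
  ground truth for verification.
* `ga_order` — permutation GA: tournament selection (size 3), order
  crossover (OX1), **segment-inversion mutation** at rate 0.5,
  elitism 1, population 50, 50 generations. Inversion (a 2-opt move)
  is the canonical mutation for path problems; plain element swap is
  available via `GAConfig(mutation="swap")` but recovers the exhaustive
  optimum far less reliably on small instances. The identity ordering
  is seeded into the initial population, so with elitism the returned
  cost can never exceed the identity ordering's cost. Fully
  deterministic for a fixed seed.

On random instances with 3 <= d <= 8 the GA matches the exhaustive
optimum in roughly 97–100 of 100 seeded runs.

## Network and training

The classifier is a 4-block VGG-style CNN built from the image size
alone. Block L holds `floor(0.5 * L * floor(sqrt(P)))` filters, where P
is the input's pixel count — for a square image `floor(sqrt(P))` is the
side length (so a 92 x 92 input gives 46/92/138/184 filters). Each
block is one 3x3 same-padding convolution, ReLU, and 2x2 max pooling
with stride 2 (odd trailing rows are dropped); inputs below 16 px per
side cannot be pooled four times and are rejected with a hint to
upscale the encoding. The head — flatten, dense(64), ReLU, dense(2)
with softmax — is our choice; only the convolutional trunk is
prescribed by the rule above.

Training is plain SGD with momentum 0.88, L2 penalty 9.4e-7, batch
size 8, and up to 1000 mini-batch update steps ("iterations" are read
as update steps, not epochs) at a constant learning rate of 0.02 (the
rate was originally searched on a log scale; no schedule is applied).
No optimizer beyond momentum SGD is implied by those hyperparameters.
The engine is a compact numpy implementation (im2col + BLAS matmul,
float32, He initialization) and is deterministic given the seed;
`tests/` include a float64 finite-difference check of every layer's
gradients.

An *attempt* is one full cycle: re-split with an attempt-specific seed
(`seed + attempt_index`), encode, build, train, evaluate. Re-splitting
per attempt (rather than only re-initializing weights) is the more
conservative reading of the protocol. The experiment report keeps
per-attempt validation/test accuracies and test-set diagnostic metrics,
aggregated as best (max) and average (arithmetic mean).

## Evaluation

Confusion counts follow the malignant-negative convention above.
Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), precision =
tp/(tp+fp), F1 = harmonic mean of precision and sensitivity, accuracy =
(tp+tn)/total. A zero denominator raises an explicit error instead of
silently reporting 0. All arithmetic is exact on integer counts;
rounding to two decimals (or percent) happens only at presentation.
"Best" summaries take the per-metric maximum over attempts.

## Synthetic data

The generator draws features class-conditionally from multivariate
normals with a block-diagonal equicorrelated covariance (unit
variances; blocks of equal size up to remainder). Informative features
(the first `ceil(informative_fraction * d)`) have class means at
+/- separation/2, so the standardized between-class difference per
informative feature is exactly `separation` and the Bayes error is
known in closed form. Labels are Bernoulli(class_ratio) with benign =
1; missing cells are knocked out uniformly at `missing_rate` and write
as `?` in CSV form. A single `numpy` Generator seeded from `SimSpec.seed`
drives all randomness; there is no global state.

Defaults — n=400, d=10, separation=3, informative_fraction=0.5,
block_correlation=0.3, two blocks, balanced classes, no missing cells —
describe a strongly separable ten-feature problem: five informative
features at separation 3 give a Mahalanobis distance of several sigma
and a Bayes error well under 1%, so a working pipeline should recover
>= 95% test accuracy, while `separation=0` yields labels independent of
features and any accuracy above the majority rate indicates leakage.

What the generator does *not* emulate: the integer/ordinal marginals,
skew and heteroscedasticity of real cytology measurements, label noise,
or structured missingness (real missing cells cluster in one feature).
Passing tests therefore demonstrate that the machinery — encoding,
ordering, training, evaluation — behaves correctly on data with known
structure, not that the published real-data accuracies transfer.

## Problem sizes and numerical choices

The test suite and the reproduction script run the pipeline at the
generator's default size (400 rows, ten features, 30 x 30 x 3 combined
images, 1000 update steps per attempt, five attempts; three attempts
for the null check) — small enough to finish in minutes on one CPU
while leaving the training protocol itself unreduced. The
ordering-equivalence experiment uses 100 random instances with
3 <= d <= 8, where exhaustive search is exact.

Ties and degenerate inputs are handled deterministically throughout:
covariance ties by column index, exhaustive-search ties
lexicographically, constant columns normalize to 0, constant vectors
encode as all-zero distance matrices, and an all-missing feature or a
single-class training set raises instead of proceeding.

## Known limitations

* The real UCI files are not bundled; loaders are exercised on
  format-faithful synthetic files, and reproduction on the real data
  requires pointing the CLI at locally downloaded copies.
* The CNN engine is CPU-only and sized for desk-scale images; it is not
  a general deep-learning framework (no padding options, strides, or
  other activations than ReLU).
* Published real-data accuracies are stochastic outcomes of training on
  external data; the package reproduces the protocol and the metric
  arithmetic exactly, but equals those accuracies only up to training
  stochasticity.
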