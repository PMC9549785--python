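# Methods

## The deconvolution model

A spot profile is modelled as the depth-normalized average of the
expression profiles of the D cells it captures (its *cell density*). The
estimation target is the composition vector q ∈ Δ^(K−1), q_i = x_i / D,
where x_i is the number of captured cells of type i. The model is
discriminative: a feed-forward network is trained on simulated
(profile, composition) pairs whose generative process mirrors this mixing
assumption, then applied to real spot profiles normalized the same way
(sum 1 over the marker genes).

Assumptions worth stating explicitly:

* A spot's expression is a *mean* of single-cell profiles — no
  spot-specific capture efficiency, lateral transcript diffusion, or
  platform noise beyond what resampling real cells provides.
* The single-cell reference covers the cell types present in the tissue,
  and its expression is comparable to the spatial platform's after
  depth normalization.
* Cell density is user-specified as an inclusive range (technology- and
  tissue-dependent; roughly 1–10 for Visium, 10–40 for Slide-seq-class
  data) and the training range should bracket the truth.

## Pseudo-spot sampler

For each spot: draw temp uniformly from the integers {0, …, steps}
(default steps = 10); form unnormalized weights w_i = base^(i·temp/steps)
for i = 0..K−1 (default base = 10), normalize, and shuffle; draw
x ~ Multinomial(D, p); draw x_i cells per type uniformly *with
replacement*; average all D cell profiles and rescale to sum 1.

Design notes:

* Exponents run 0..K−1 so exactly K weights are produced; at temp = steps
  the max/min weight ratio is base^(K−1), which at base 10 makes
  single-type spots reachable, and at temp = 0 the weights are exactly
  uniform. The shuffle removes positional bias, so every type's marginal
  expected proportion is 1/K.
* `base` is a free constant by default; `temperature_weights` accepts any
  base > 1, and the density itself can be passed as the base (making skew
  grow with spot size) — a variant reading exposed but not default.
* temp is drawn uniformly because no distribution is canonical; uniform
  gives even coverage of the mixed-to-pure spectrum, which is the point of
  the temperature family.
* Sampling with replacement keeps rare types usable at high densities.
* Mean-then-normalize equals sum-then-normalize; the mean is implemented.

The stratified splitter allocates each type's cells to train/validation/
test by largest remainder, forcing at least one cell into every split with
positive fraction, so simulated sets never share cells.

## Marker selection

Counts are depth-normalized to sum 1 per cell, scaled by 1e4 and log1p
transformed before ranking. The Welch t statistic (one type vs the rest,
per gene) is the default ranking score; an unpenalized one-vs-rest
logistic fit over all genes (lbfgs, 500-iteration cap, fixed tolerance) is
the alternative — preferable for small gene sets, slower at large K.
Ranking ties break lexicographically by gene id so output is
deterministic. The top-X union (duplicates collapsed, first-occurrence
order) becomes the model's input space. The verification gate — an
XGBoost classifier (200 trees, depth 6, configurable) on a stratified
90/10 split — is a sanity check that the reduced gene set still separates
the types (≥90% held-out accuracy), not a tuned model.

## Network and training

Input G marker genes, output K types. Hidden widths 512, 512, 256, 256,
128, 128, 64: three pairs plus one unpaired layer. Each pair layer is
linear → batch-norm → ReLU; the unpaired 64 layer is linear → ReLU; the
output layer is linear → leaky ReLU (negative slope 0.1). The loss is the
mean absolute error of this post-activation, *pre-scaling* output against
the true composition: scaling-before-loss admits degenerate near-zero-sum
outputs at large K, while the leaky slope keeps a gradient on negative
outputs so they are pushed back toward [0, 1]. At inference the output is
divided by its sum; a non-positive sum (never observed after successful
training) falls back to uniform with a warning. Reported proportions clamp
negatives to 0 and renormalize, so downstream tables are always valid
compositions.

Training: Adam (lr 1e-3), batch size 1024, up to 500 epochs by default —
all configurable. An epoch's validation loss is the same pre-scaling L1
criterion (the divergence is reserved for reporting). Strict improvement
checkpoints the weights; `patience` epochs without improvement trigger a
warm restart (best weights reloaded, counter reset) while restarts remain,
otherwise training stops, and the best checkpoint is restored either way.
Consequently a run without restarts ends exactly at best_epoch + patience,
and the returned model always attains the minimum recorded validation
loss. The whole stack is NumPy on CPU: identical seed and configuration
reproduce the training history bit for bit.

Batch-norm backpropagation uses the exact batch statistics; running
estimates (momentum 0.1, unbiased variance) are frozen at inference.
Initialization is fan-in uniform, U(±1/√fan_in), per layer from the build
seed.

## Metric conventions

`jensen_shannon_divergence` is the base-2 divergence:
½KL(P‖M) + ½KL(Q‖M), M = ½(P+Q), with 0·log 0 = 0; range [0, 1], value 1
iff supports are disjoint. All internal scoring (training-time evaluation,
the parameter-recovery tests) uses this form.

`jensen_shannon_distance` is √(ln 2 · divergence₂) — the square-rooted
natural-log form that `scipy.spatial.distance.jensenshannon` returns by
default and under which "JSD" percentages are most often printed in the
spot-deconvolution benchmarking literature; range [0, √ln 2 ≈ 0.8326].
`scripts/acceptance.py` reports the uniform-baseline benchmark in this
convention: on the 42,000-composition comparison set (K = 11, densities
10–30) the two conventions give materially different means (≈50% for the
divergence vs ≈57% for the distance), and the distance is the convention
consistent with published baseline values near 60%. The two functions are
linked algebraically, so they cannot drift apart.

## Synthetic reference fixtures

`FixtureSpec` defaults: K = 5 types × 200 cells, 500 genes, disjoint
20-gene marker blocks at fold change 10 over a background mean of 2,
negative-binomial counts with shared dispersion 2 (variance μ + μ²/2 —
moderate overdispersion, in the range typical of UMI counts). Disjoint
blocks make planted-marker recovery exactly assertable; fold change is the
single difficulty dial. What passing tests on these fixtures demonstrates
is that the pipeline recovers compositions when its generative assumptions
hold; they say nothing about reference/platform mismatch, doublets,
ambient RNA or batch effects, none of which are simulated.

## Problem sizes and defaults used in the shipped checks

The end-to-end parameter-recovery check runs the default fixture with
10,002 training spots (1,667 per density, densities 5–10), 1,200
validation and 3,000 test spots, a reduced-width network (128, 128, 64,
32), batch size 512, patience 10 — compact enough to run on one CPU in
well under a minute while leaving a wide margin to its acceptance bar
(mean divergence < 0.15; observed ≈ 0.004). The baseline benchmark
regeneration uses the full 42,000 compositions, which needs no reference
and runs in seconds. Full-scale runs (10⁵–10⁶ spots, G ≈ 1,400, K ≈ 11–42)
use the same code paths with larger arguments; memory is the main cost, as
profiles are dense float64.

## Known limitations

* No uncertainty estimates on predicted proportions.
* Dense in-memory arrays throughout; a 2-million-spot simulation at
  G = 1,389 needs ~20 GB unless generated in chunks.
* The NumPy trainer is single-threaded per BLAS call; at paper scale a
  GPU implementation of the same architecture would be substantially
  faster, though results are identical in expectation.
* Real-data workflows (HDF5/10x-h5 readers, spatial visualization,
  cross-tool statistical comparisons) are out of scope; inputs must be
  dense text or MatrixMarket triplets.
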