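# spotdecon

Spot-based spatial transcriptomics (10x Visium, Slide-seq) measures mixed
RNA profiles: each capture spot collects transcripts from several cells of
possibly different types. **spotdecon** estimates the cell-type composition
of every spot — a proportion vector over K types — by training a
feed-forward network on *synthetic* spots built from an annotated
single-cell RNA reference, where the ground-truth composition is known by
construction. It is aimed at computational biologists with a scRNA-seq
reference from a tissue comparable to their spatial sections.

## Method

1. **Marker genes.** Genes are ranked one-vs-rest per cell type (Welch
   t statistic, or an unpenalized one-vs-rest logistic fit) on
   depth-normalized log counts; the union of each type's top-X genes is the
   model's feature space. A gradient-boosted-trees classifier on a held-out
   10% of cells must reach ≥90% accuracy for the set to pass.
2. **Pseudo-spot simulation.** For a spot of cell density D, a composition
   x ~ Multinomial(D, p) is drawn, with p from a temperature family
   w_i ∝ base^(i·temp/steps), i = 0..K−1, normalized and shuffled per spot:
   temp = 0 gives fully mixed spots, temp = steps nearly pure ones, so
   training covers both regimes and class imbalance in the reference never
   enters. The spot profile is the mean of the x_i cells drawn per type,
   rescaled to sum 1; the target is x/D.
3. **Regression.** An MLP (default hidden widths 512, 512, 256, 256, 128,
   128, 64; batch-norm on the paired layers; leaky-ReLU output with slope
   0.1) is trained with Adam on the mean absolute error of the
   *pre-scaling* output; at inference the output X is reported as X_i / S,
   S = Σ X_i, so predictions sum to 1. Validation-loss checkpointing with
   patience and optional warm restarts (best weights reloaded) controls
   overfitting.
4. **Evaluation.** Predictions are scored against ground truth with the
   Jensen–Shannon divergence, JSD(P,Q) = ½KL(P‖M) + ½KL(Q‖M), M = ½(P+Q),
   base-2 logs (range [0,1]); the natural-log Jensen–Shannon *distance*
   (√ of the nat-log divergence) is also exposed, since published
   benchmarks frequently report that convention. The floor to beat is the
   uniform predictor 1/K.

## Worked example

Run the whole pipeline on a built-in synthetic reference (5 cell types,
200 cells each, 20 marker genes per type at 10-fold elevation over a
negative-binomial background; 10,002 training spots at densities 5–10):

```python
from spotdecon import FixtureSpec, end_to_end_smoke

result = end_to_end_smoke(FixtureSpec(K=5, fold_change=10.0, seed=0), seed=0)
print(f"marker verification accuracy: {result.marker_accuracy:.4f}")
print(f"epochs run: {result.history.n_epochs}, best epoch: {result.history.best_epoch}")
print(f"best validation L1 loss: {result.history.best_val_loss:.4f}")
print(f"trained model: {result.jsd}")
print(f"uniform baseline: {result.baseline_jsd}")
```

prints

```
marker verification accuracy: 1.0000
epochs run: 38, best epoch: 28
best validation L1 loss: 0.0162
trained model: mean JSD 0.36% (SD: 0.46%)
uniform baseline: mean JSD 35.28% (SD: 16.53%)
```

The marker set separates the five types perfectly (accuracy 1.0); training
stops 10 epochs after the best validation loss (patience); on held-out
synthetic spots the trained model's mean divergence from the true
compositions is 0.36%, against 35.28% for guessing equal proportions —
the compositions are essentially recovered.

The same flow is available from the shell:

```bash
spotdecon fixture  --out ref/ --seed 1
spotdecon markers  --counts ref/counts.csv --annotation ref/annotation.csv \
                   --top-x 20 --out markers/
spotdecon simulate --counts ref/counts.csv --annotation ref/annotation.csv \
                   --markers markers/markers.json --densities 5:10 \
                   --n-per-density 1667 --out spots/
spotdecon train    --train spots/train --val spots/validation \
                   --out model.npz
spotdecon deconvolute --model model.npz --spots my_visium_counts.csv \
                   --out proportions.csv
```

Input matrices can be dense CSV/TSV (observations × genes, header row of
gene ids) or a 10x-style MatrixMarket triplet (`matrix.mtx` +
`genes.tsv`/`barcodes.tsv`); orientation is resolved automatically.

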