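"""Fully synthetic annotated single-cell references.

Counts follow a negative-binomial model, the standard overdispersed choice
for RNA-seq: gene g in a cell of type t has mean ``baseline_mean *
fold_change`` if g lies in t's marker block and ``baseline_mean``
otherwise, with a shared dispersion (size) parameter.  Marker blocks are
disjoint across types, so ground-truth marker recovery is exactly
assertable, and ``fold_change`` dials the difficulty of every downstream
stage from trivially separable to hopeless.

What this emulates: per-type elevated marker expression over a noisy
background with realistic count overdispersion.  What it does not: doublets,
ambient RNA, batch effects, library-size gradients or dropout beyond what
the negative binomial produces — conclusions from these fixtures are about
pipeline mechanics, not about any real tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import JSDSummary, baseline_uniform, jsd_against_reference
from .io import CellTypeAnnotation, GeneCountMatrix
from .markers import find_markers
from .network import NetworkConfig, build_network
from .sampler import generate_dataset, stratified_split
from .training import TrainingConfig, evaluate, train


@dataclass
class FixtureSpec:
    """Parameters of the synthetic reference generator."""

    K: int = 5
    cells_per_type: int = 200
    n_genes: int = 500
    markers_per_type: int = 20
    fold_change: float = 10.0
    dispersion: float = 2.0
    baseline_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.markers_per_type * self.K > self.n_genes:
            raise ValueError("marker blocks exceed the gene count")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    # numpy parameterizes NB by (n, p) with mean = n (1-p)/p  =>  p = n/(n+mu)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_reference(
    spec: FixtureSpec,
) -> tuple[GeneCountMatrix, CellTypeAnnotation]:
    """Draw an annotated cells x genes count matrix from the fixture model.

    Cell ids are ``<type>_<i>``; type t's marker block occupies genes
    ``g{t*markers_per_type} .. g{(t+1)*markers_per_type - 1}``.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.K * spec.cells_per_type
    means = np.full((n_cells, spec.n_genes), spec.baseline_mean)
    labels: list[str] = []
    cell_ids: list[str] = []
    label_order = [f"type{t}" for t in range(spec.K)]
    for t in range(spec.K):
        rows = slice(t * spec.cells_per_type, (t + 1) * spec.cells_per_type)
        block = slice(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        means[rows, block] *= spec.fold_change
        labels += [label_order[t]] * spec.cells_per_type
        cell_ids += [f"type{t}_{i}" for i in range(spec.cells_per_type)]
    counts = _nb_sample(rng, means, spec.dispersion).astype(float)
    gene_ids = [f"g{j}" for j in range(spec.n_genes)]
    matrix = GeneCountMatrix(counts, cell_ids, gene_ids)
    annotation = CellTypeAnnotation(dict(zip(cell_ids, labels)), label_order)
    return matrix, annotation


def true_marker_blocks(spec: FixtureSpec) -> dict[str, list[str]]:
    """The planted marker genes of each type, for oracle comparisons."""
    return {
        f"type{t}": [
            f"g{j}"
            for j in range(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        ]
        for t in range(spec.K)
    }


@dataclass
class SmokeResult:
    jsd: JSDSummary
    baseline_jsd: JSDSummary
    marker_accuracy: float
    history: object
    label_order: list[str]


def end_to_end_smoke(
    spec: FixtureSpec | None = None,
    *,
    top_x: int = 20,
    density_range: tuple[int, int] = (5, 10),
    n_train_per_density: int = 1667,
    n_val_per_density: int = 200,
    n_test_per_density: int = 500,
    hidden_layout: tuple[int, ...] = (128, 128, 64, 32),
    max_epochs: int = 60,
    patience: int = 10,
    warm_restarts: int = 0,
    learning_rate: float = 1e-3,
    batch_size: int = 512,
    steps: int = 10,
    base: float = 10.0,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> SmokeResult:
    """Run the whole pipeline on a synthetic reference and score it.

    markers -> stratified split -> pseudo-spot simulation -> training ->
    test-set JSD, plus the uniform-baseline JSD on the same test set.
    ``shuffle_labels`` permutes the cell-type annotation before anything
    else runs — the negative control under which the model cannot beat the
    baseline by more than noise.
    """
    spec = spec or FixtureSpec()
    matrix, annotation = generate_reference(spec)
    rng = np.random.default_rng(seed + 1)
    if shuffle_labels:
        labs = list(annotation.mapping.values())
        rng.shuffle(labs)
        annotation = CellTypeAnnotation(
            dict(zip(annotation.mapping.keys(), labs)), annotation.label_order
        )

    marker_set = find_markers(
        matrix, annotation, top_x=top_x, method="t-test", seed=seed
    )
    restricted = matrix.subset_genes(marker_set.selected_genes)
    tr, va, te = stratified_split(restricted, annotation, (0.8, 0.1, 0.1), seed=seed)

    train_set = generate_dataset(
        tr, density_range, n_train_per_density, steps, base, seed=seed, role="train"
    )
    val_set = generate_dataset(
        va, density_range, n_val_per_density, steps, base, seed=seed + 1,
        role="validation",
    )
    test_set = generate_dataset(
        te, density_range, n_test_per_density, steps, base, seed=seed + 2, role="test"
    )

    model = build_network(
        NetworkConfig(
            input_dim=len(marker_set.selected_genes),
            output_dim=annotation.n_types,
            hidden_layout=hidden_layout,
        ),
        seed=seed,
        gene_ids=marker_set.selected_genes,
        label_order=annotation.label_order,
    )
    model, history = train(
        model,
        train_set,
        val_set,
        TrainingConfig(
            learning_rate=learning_rate,
            batch_size=batch_size,
            max_epochs=max_epochs,
            patience=patience,
            warm_restarts=warm_restarts,
            seed=seed,
        ),
    )
    _, summary = evaluate(model, test_set)
    baseline = jsd_against_reference(
        baseline_uniform(annotation.n_types), test_set.proportions
    )
    return SmokeResult(
        jsd=summary,
        baseline_jsd=baseline,
        marker_accuracy=marker_set.verification_accuracy,
        history=history,
        label_order=annotation.label_order,
    )


def harder_and_easier(spec: FixtureSpec, fold_changes=(3.0, 10.0, 30.0), **kw):
    """Convenience: run the smoke test at several separability levels."""
    return {
        fc: end_to_end_smoke(replace(spec, fold_change=fc), **kw) for fc in fold_changes
    }
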