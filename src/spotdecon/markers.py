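"""One-vs-rest marker-gene ranking, top-X union selection and a
gradient-boosted verification gate.

Before any ranking, counts are depth-normalized per cell (scaled to sum 1,
multiplied by a fixed factor of 1e4) and log1p-transformed — the usual
single-cell convention, recorded in the marker-set metadata.

Two ranking statistics are offered per cell type (that type's cells versus
all remaining cells):

* ``t-test`` — the Welch t statistic per gene (default; cheap at large K).
* ``logistic-regression`` — signed coefficients of an unpenalized
  one-vs-rest logistic fit over all genes at once, with a fixed iteration
  cap so the fit (and hence the ranking) is deterministic.

Ties are broken by lexicographic gene id so rankings are reproducible.
The selected union is sanity-checked by training a gradient-boosted-trees
classifier (cell profile -> cell type) on a stratified 90/10 split; the set
passes if held-out accuracy reaches the threshold (default 90%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .io import CellTypeAnnotation, GeneCountMatrix

logger = logging.getLogger(__name__)

NORMALIZATION_SCALE = 1e4  # post depth-normalization multiplier before log1p


def lognormalize(values: np.ndarray, scale: float = NORMALIZATION_SCALE) -> np.ndarray:
    """Depth-normalize rows to sum 1, scale, then log1p."""
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("cells with zero total count cannot be normalized")
    return np.log1p(values / sums * scale)


@dataclass
class MarkerGeneSet:
    """Ranked markers per type plus the selected union and its verification."""

    per_type_ranking: dict[str, list[tuple[str, float]]]
    selected_genes: list[str]
    top_x: int
    method: str
    verification_accuracy: float | None = None
    passed: bool | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for ct, ranking in self.per_type_ranking.items():
            for rank, (gene, score) in enumerate(ranking, start=1):
                rows.append((ct, gene, rank, score))
        return pd.DataFrame(rows, columns=["cell_type", "gene_id", "rank", "score"])


def _ordered(gene_ids: list[str], scores: np.ndarray) -> list[tuple[str, float]]:
    # descending score, ties broken by lexicographic gene id
    order = sorted(range(len(gene_ids)), key=lambda j: (-scores[j], gene_ids[j]))
    return [(gene_ids[j], float(scores[j])) for j in order]


def rank_genes_one_vs_rest(
    reference: GeneCountMatrix,
    annotation: CellTypeAnnotation,
    method: str = "t-test",
    max_iter: int = 500,
) -> dict[str, list[tuple[str, float]]]:
    """Rank every gene per cell type by its one-vs-rest score.

    Returns ``{cell_type: [(gene_id, score), ...]}`` with genes in
    descending score order.  Genes with no variance contribute a score of 0
    under the t statistic.
    """
    if method not in ("t-test", "logistic-regression"):
        raise ValueError(f"unknown ranking method {method!r}")
    annotation.validate_against(reference)
    codes = annotation.labels_for(reference.obs_ids)
    counts = np.bincount(codes, minlength=annotation.n_types)
    for k, lab in enumerate(annotation.label_order):
        if counts[k] < 2:
            raise ValueError(
                f"cell type {lab!r} has {counts[k]} cell(s); at least 2 required"
            )
    X = lognormalize(reference.values)
    rankings: dict[str, list[tuple[str, float]]] = {}
    if method == "t-test":
        for k, lab in enumerate(annotation.label_order):
            grp = X[codes == k]
            rest = X[codes != k]
            t = stats.ttest_ind(grp, rest, axis=0, equal_var=False).statistic
            t = np.nan_to_num(t, nan=0.0)
            rankings[lab] = _ordered(reference.gene_ids, t)
    else:
        for k, lab in enumerate(annotation.label_order):
            y = (codes == k).astype(int)
            # C=inf: unpenalized fit; the iteration cap keeps coefficients
            # finite (and the ranking deterministic) on separable data
            clf = LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=max_iter, tol=1e-4
            )
            clf.fit(X, y)
            rankings[lab] = _ordered(reference.gene_ids, clf.coef_.ravel())
    return rankings


def select_top_markers(
    rankings: dict[str, list[tuple[str, float]]], top_x: int, method: str = "t-test"
) -> MarkerGeneSet:
    """Take the union of each type's top-``top_x`` genes.

    Duplicates across types are collapsed; first-occurrence order (over
    types in ranking order, then rank) is preserved.  ``top_x`` larger than
    the gene count is capped with a warning.
    """
    if top_x < 1:
        raise ValueError("top_x must be >= 1")
    n_genes = len(next(iter(rankings.values())))
    if top_x > n_genes:
        logger.warning("top_x=%d exceeds gene count %d; capping", top_x, n_genes)
        top_x = n_genes
    selected: list[str] = []
    seen: set[str] = set()
    for ranking in rankings.values():
        for gene, _ in ranking[:top_x]:
            if gene not in seen:
                seen.add(gene)
                selected.append(gene)
    return MarkerGeneSet(
        per_type_ranking=rankings,
        selected_genes=selected,
        top_x=top_x,
        method=method,
        metadata={"normalization": f"sum-to-1 * {NORMALIZATION_SCALE:g}, log1p"},
    )


def verify_marker_power(
    reference: GeneCountMatrix,
    annotation: CellTypeAnnotation,
    marker_set: MarkerGeneSet | None = None,
    train_fraction: float = 0.9,
    threshold: float = 0.9,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 6,
) -> tuple[float, bool]:
    """Score the marker set with a held-out gradient-boosted-trees classifier.

    Cells are split stratified by type into train/test (default 90/10); an
    XGBoost classifier maps normalized profiles to type labels; the set
    passes if test accuracy >= ``threshold``.  When ``marker_set`` is given
    it is updated in place and the reference is restricted to its genes.
    """
    from xgboost import XGBClassifier

    matrix = reference
    if marker_set is not None:
        matrix = reference.subset_genes(marker_set.selected_genes)
    annotation.validate_against(matrix)
    codes = annotation.labels_for(matrix.obs_ids)
    X = lognormalize(matrix.values)
    idx = np.arange(len(codes))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=codes,
        random_state=seed,
    )
    present = set(codes[test_idx].tolist())
    missing = [
        lab for k, lab in enumerate(annotation.label_order) if k not in present
    ]
    if missing:
        raise ValueError(f"cell types absent from the test split: {missing}")
    clf = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        verbosity=0,
        n_jobs=1,
    )
    clf.fit(X[train_idx], codes[train_idx])
    accuracy = float(accuracy_score(codes[test_idx], clf.predict(X[test_idx])))
    passed = accuracy >= threshold
    if marker_set is not None:
        marker_set.verification_accuracy = accuracy
        marker_set.passed = passed
        marker_set.metadata.update(
            {"train_fraction": train_fraction, "threshold": threshold, "seed": seed}
        )
    return accuracy, passed


def find_markers(
    reference: GeneCountMatrix,
    annotation: CellTypeAnnotation,
    top_x: int = 150,
    method: str = "t-test",
    verify: bool = True,
    seed: int = 0,
    threshold: float = 0.9,
) -> MarkerGeneSet:
    """Rank, select and (optionally) verify in one call."""
    rankings = rank_genes_one_vs_rest(reference, annotation, method=method)
    marker_set = select_top_markers(rankings, top_x, method=method)
    if verify:
        verify_marker_power(
            reference, annotation, marker_set, seed=seed, threshold=threshold
        )
    return marker_set
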