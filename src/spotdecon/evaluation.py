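"""Deconvolution of spot matrices and Jensen-Shannon-divergence scoring.

The Jensen-Shannon divergence between two proportion vectors P and Q is

    JSD(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q) / 2

with base-2 logarithms, so 0 <= JSD <= 1 and a value of 1 means disjoint
support; 0 * log 0 is taken as 0.  The divergence (not its square root) is
reported, both as a fraction and as a percentage.

Raw network outputs can carry small negative entries (from the leaky output
activation); before any divergence is computed or a proportion is reported,
negatives are clamped to zero and the vector renormalized, so every
reported composition is valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .io import GeneCountMatrix
from .network import DeconvolutionModel

logger = logging.getLogger(__name__)


def _as_distribution(v: np.ndarray) -> np.ndarray:
    """Clamp negatives to 0 and renormalize to sum 1."""
    v = np.asarray(v, dtype=float)
    v = np.where(v < 0, 0.0, v)
    total = v.sum()
    if total <= 0:
        raise ValueError("vector has zero sum after clamping negatives")
    return v / total


def jensen_shannon_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between two proportion vectors."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    P = _as_distribution(P)
    Q = _as_distribution(Q)
    M = 0.5 * (P + Q)
    jsd_nats = 0.5 * rel_entr(P, M).sum() + 0.5 * rel_entr(Q, M).sum()
    return float(jsd_nats / np.log(2.0))


def jensen_shannon_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon distance: sqrt of the natural-log divergence.

    This is the other convention under which "JSD" percentages circulate in
    the deconvolution literature (it is what
    ``scipy.spatial.distance.jensenshannon`` returns by default); its range
    is [0, sqrt(ln 2)] ~ [0, 0.8326].  Computed from the package's own
    base-2 divergence by rescaling, so the two reported conventions can
    never drift apart.
    """
    return float(np.sqrt(jensen_shannon_divergence(P, Q) * np.log(2.0)))


def baseline_uniform(K: int) -> np.ndarray:
    """The uninformed predictor: equal proportion 1/K for every type."""
    if K < 2:
        raise ValueError("at least two cell types are required")
    return np.full(K, 1.0 / K)


@dataclass
class JSDSummary:
    per_spot: np.ndarray
    mean: float
    sd: float

    @property
    def mean_percent(self) -> float:
        return 100.0 * self.mean

    @property
    def sd_percent(self) -> float:
        return 100.0 * self.sd

    def __str__(self) -> str:  # mirrors the usual "mean% (SD: sd%)" convention
        return f"mean JSD {self.mean_percent:.2f}% (SD: {self.sd_percent:.2f}%)"


def summarize_jsd(per_spot) -> JSDSummary:
    """Arithmetic mean and sample SD of a list of divergences."""
    per_spot = np.asarray(per_spot, dtype=float)
    if per_spot.size == 0:
        raise ValueError("no divergences to summarize")
    if np.any((per_spot < -1e-12) | (per_spot > 1 + 1e-12)):
        raise ValueError("divergences must lie in [0, 1]")
    sd = float(np.std(per_spot, ddof=1)) if per_spot.size > 1 else 0.0
    return JSDSummary(per_spot=per_spot, mean=float(np.mean(per_spot)), sd=sd)


def jsd_against_reference(predictions: np.ndarray, truths: np.ndarray) -> JSDSummary:
    """Row-wise JSD between two stacks of proportion vectors."""
    predictions = np.atleast_2d(predictions)
    truths = np.atleast_2d(truths)
    if predictions.shape[0] == 1 and truths.shape[0] > 1:
        predictions = np.repeat(predictions, truths.shape[0], axis=0)
    if predictions.shape != truths.shape:
        raise ValueError("prediction and truth stacks differ in shape")
    per_spot = np.array(
        [
            jensen_shannon_divergence(predictions[i], truths[i])
            for i in range(truths.shape[0])
        ]
    )
    return summarize_jsd(per_spot)


def deconvolute_spots(
    model: DeconvolutionModel,
    spots: GeneCountMatrix,
    max_missing_fraction: float = 0.5,
) -> tuple[np.ndarray, list[str]]:
    """Predict a proportion vector for every spot in a count matrix.

    The spot matrix is restricted and reordered to the checkpoint's
    marker-gene list; marker genes absent from the matrix are zero-filled
    (with a warning) unless more than ``max_missing_fraction`` of them are
    missing, which aborts.  Each spot profile is normalized to sum 1 over
    the marker genes; all-zero spots are skipped with a warning.  Reported
    vectors have negatives clamped and sum to 1.

    Returns ``(proportions, kept_spot_ids)``.
    """
    if model.gene_ids is None:
        raise ValueError("model checkpoint carries no marker-gene list")
    present = set(spots.gene_ids)
    missing = [g for g in model.gene_ids if g not in present]
    if len(missing) > max_missing_fraction * len(model.gene_ids):
        raise ValueError(
            f"{len(missing)}/{len(model.gene_ids)} checkpoint marker genes are "
            "absent from the spot matrix; the gene spaces are incompatible"
        )
    if missing:
        logger.warning(
            "%d marker gene(s) absent from the spot matrix; zero-filling", len(missing)
        )
    col = {g: j for j, g in enumerate(spots.gene_ids)}
    X = np.zeros((spots.n_obs, len(model.gene_ids)))
    for j, g in enumerate(model.gene_ids):
        if g in col:
            X[:, j] = spots.values[:, col[g]]
    sums = X.sum(axis=1)
    keep = sums > 0
    if not np.all(keep):
        logger.warning(
            "%d spot(s) have zero counts over the marker genes; skipping",
            int((~keep).sum()),
        )
    X = X[keep] / sums[keep, None]
    scaled = model.predict(X)
    proportions = np.vstack([_as_distribution(row) for row in scaled])
    kept_ids = [o for o, k in zip(spots.obs_ids, keep) if k]
    return proportions, kept_ids
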