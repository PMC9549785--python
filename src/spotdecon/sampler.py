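"""Synthetic pseudo-spot generation from an annotated single-cell split.

A spot of cell density D (the number of cells contributing to its profile)
is built in three steps:

1. *Temperature weights.*  For K cell types, unnormalized weights
   ``w_i = base ** (i * temp / steps)`` for ``i = 0..K-1`` are normalized to
   a probability vector and then shuffled.  ``temp = 0`` gives the uniform
   vector (fully mixed spots); ``temp = steps`` gives a geometric ladder
   whose largest/smallest ratio is ``base**(K-1)`` — essentially one-hot for
   the default ``base = 10`` at moderate K, so the extreme single-type
   spots are reachable.  The shuffle removes positional bias: every type can
   receive the large weight.
2. *Composition.*  The per-type cell count vector x is a single draw from
   Multinomial(D, p) with p the shuffled weights; the ground-truth
   proportion vector is x / D.
3. *Profile.*  For each type i, x_i cells are drawn uniformly with
   replacement from that type's cells in the split; the gene-count vectors
   of all D selected cells are averaged and the result rescaled to sum 1.

``temp`` itself is drawn uniformly over the integers {0, ..., steps} per
spot, so a generated dataset covers the mixed-to-extreme spectrum evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CellTypeAnnotation, GeneCountMatrix, save_json, write_proportions

DEFAULT_STEPS = 10
DEFAULT_BASE = 10.0


@dataclass
class TemperatureWeights:
    """A shuffled length-K probability vector from the temperature family."""

    p: np.ndarray
    temp: int
    steps: int
    base: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if np.any(self.p <= 0):
            raise ValueError("weights must be strictly positive")


@dataclass
class CellTypeCountVector:
    """Integer cells-per-type composition of one spot; sums to density."""

    x: np.ndarray
    density: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        if self.x.sum() != self.density:
            raise ValueError("composition does not sum to the cell density")

    @property
    def proportions(self) -> np.ndarray:
        return self.x / self.density


@dataclass
class SyntheticSpot:
    """A normalized pseudo-spot profile with its ground-truth proportions."""

    profile: np.ndarray
    proportions: np.ndarray
    density: int
    temp: int


@dataclass
class SpotDataset:
    """A batch of synthetic spots as dense arrays.

    ``profiles`` is spots x genes (rows sum to 1), ``proportions`` is
    spots x K (rows sum to 1); ``densities`` and ``temps`` record each
    spot's generating parameters.
    """

    profiles: np.ndarray
    proportions: np.ndarray
    densities: np.ndarray
    temps: np.ndarray
    gene_ids: list[str]
    label_order: list[str]
    role: str = "train"
    seed: int | None = None
    density_range: tuple[int, int] | None = None
    n_per_density: int | None = None
    steps: int = DEFAULT_STEPS
    base: float = DEFAULT_BASE
    extra: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return self.profiles.shape[0]

    def save(self, directory: str | Path) -> None:
        """Write profiles CSV, proportions CSV and a metadata JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ids = [f"spot_{i}" for i in range(self.n_spots)]
        GeneCountMatrix(self.profiles, ids, self.gene_ids)
        import pandas as pd

        pd.DataFrame(self.profiles, index=ids, columns=self.gene_ids).rename_axis(
            "spot_id"
        ).to_csv(directory / "profiles.csv", float_format="%.17g")
        write_proportions(
            self.proportions, ids, self.label_order, directory / "proportions.csv"
        )
        save_json(
            {
                "role": self.role,
                "seed": self.seed,
                "density_range": list(self.density_range)
                if self.density_range
                else None,
                "n_per_density": self.n_per_density,
                "steps": self.steps,
                "base": self.base,
                "densities": self.densities.tolist(),
                "temps": self.temps.tolist(),
                "label_order": self.label_order,
            },
            directory / "metadata.json",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "SpotDataset":
        import json

        import pandas as pd

        directory = Path(directory)
        prof = pd.read_csv(directory / "profiles.csv", index_col=0)
        props = pd.read_csv(directory / "proportions.csv", index_col=0)
        meta = json.loads((directory / "metadata.json").read_text())
        return cls(
            profiles=prof.to_numpy(dtype=float),
            proportions=props.to_numpy(dtype=float),
            densities=np.array(meta["densities"], dtype=int),
            temps=np.array(meta["temps"], dtype=int),
            gene_ids=list(prof.columns),
            label_order=meta["label_order"],
            role=meta["role"],
            seed=meta["seed"],
            density_range=tuple(meta["density_range"])
            if meta["density_range"]
            else None,
            n_per_density=meta["n_per_density"],
            steps=meta["steps"],
            base=meta["base"],
        )


def temperature_weights(
    temp: int,
    steps: int,
    base: float,
    K: int,
    rng: np.random.Generator,
) -> TemperatureWeights:
    """Draw the shuffled temperature-weight vector for one spot."""
    if not 0 <= temp <= steps:
        raise ValueError(f"temp must lie in [0, {steps}], got {temp}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if base <= 1:
        raise ValueError("base must exceed 1 (otherwise temperature has no effect)")
    if K < 2:
        raise ValueError("at least two cell types are required")
    exponents = np.arange(K, dtype=float) * (temp / steps)
    w = np.power(float(base), exponents)
    p = w / w.sum()
    rng.shuffle(p)
    return TemperatureWeights(p=p, temp=temp, steps=steps, base=float(base))


def sample_composition(
    weights: TemperatureWeights, density: int, rng: np.random.Generator
) -> CellTypeCountVector:
    """Draw the per-type cell counts of one spot from Multinomial(density, p)."""
    if density < 1:
        raise ValueError("cell density must be >= 1")
    x = rng.multinomial(density, weights.p)
    return CellTypeCountVector(x=x, density=density)


class _TypeIndex:
    """Row indices of each cell type within a split, for fast cell draws."""

    def __init__(self, matrix: GeneCountMatrix, annotation: CellTypeAnnotation):
        codes = annotation.labels_for(matrix.obs_ids)
        self.rows = [np.flatnonzero(codes == k) for k in range(annotation.n_types)]
        self.matrix = matrix
        self.label_order = annotation.label_order


def synthesize_profile(
    counts: CellTypeCountVector,
    split: tuple[GeneCountMatrix, CellTypeAnnotation] | _TypeIndex,
    rng: np.random.Generator,
) -> SyntheticSpot:
    """Build one pseudo-spot profile for a given composition.

    Cells are drawn uniformly *with replacement* within each type, their
    count vectors averaged over all selected cells, and the mean profile
    rescaled to sum 1.
    """
    index = split if isinstance(split, _TypeIndex) else _TypeIndex(*split)
    chosen: list[np.ndarray] = []
    for k, xk in enumerate(counts.x):
        if xk == 0:
            continue
        rows = index.rows[k]
        if len(rows) == 0:
            raise ValueError(
                f"cell type {index.label_order[k]!r} required by the composition "
                "is absent from the split"
            )
        chosen.append(rows[rng.integers(0, len(rows), size=xk)])
    sel = np.concatenate(chosen)
    mean_profile = index.matrix.values[sel].mean(axis=0)
    total = mean_profile.sum()
    if total <= 0:
        raise ValueError("selected cells have an all-zero combined profile")
    return SyntheticSpot(
        profile=mean_profile / total,
        proportions=counts.proportions,
        density=counts.density,
        temp=-1,
    )


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Allocate n items to fractions, largest remainder, >=1 where fraction>0."""
    exact = [n * f for f in fractions]
    alloc = [int(np.floor(e)) for e in exact]
    remainder = n - sum(alloc)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - alloc[i], reverse=True)
    for i in order[:remainder]:
        alloc[i] += 1
    # force at least one item in every split with positive fraction
    for i, f in enumerate(fractions):
        if f > 0 and alloc[i] == 0:
            donor = int(np.argmax(alloc))
            if alloc[donor] <= 1:
                raise ValueError(f"too few items ({n}) for fractions {fractions}")
            alloc[donor] -= 1
            alloc[i] += 1
    return alloc


def stratified_split(
    reference: GeneCountMatrix,
    annotation: CellTypeAnnotation,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> list[tuple[GeneCountMatrix, CellTypeAnnotation]]:
    """Split cells into disjoint train/validation/test sets, stratified by type.

    Within each type, cell order is shuffled by ``seed`` and counts are
    allocated by the largest-remainder rule with at least one cell per
    nonzero-fraction split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    annotation.validate_against(reference)
    rng = np.random.default_rng(seed)
    codes = annotation.labels_for(reference.obs_ids)
    parts: list[list[str]] = [[] for _ in fractions]
    for k in range(annotation.n_types):
        rows = np.flatnonzero(codes == k)
        rng.shuffle(rows)
        alloc = _largest_remainder(len(rows), fractions)
        start = 0
        for j, a in enumerate(alloc):
            for r in rows[start : start + a]:
                parts[j].append(reference.obs_ids[r])
            start += a
    out = []
    for obs in parts:
        sub = reference.subset_obs(obs)
        ann = CellTypeAnnotation(
            {o: annotation.mapping[o] for o in obs}, list(annotation.label_order)
        )
        out.append((sub, ann))
    return out


def sample_proportions(
    K: int,
    density_range: tuple[int, int],
    n_per_density: int,
    steps: int = DEFAULT_STEPS,
    base: float = DEFAULT_BASE,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ground-truth proportion vectors only (no gene profiles).

    Returns (proportions, densities, temps).  Used when only compositions
    are needed, e.g. to score a proportion-space baseline.
    """
    lo, hi = density_range
    if hi < lo:
        raise ValueError("empty density range")
    rng = np.random.default_rng(seed)
    densities = np.repeat(np.arange(lo, hi + 1), n_per_density)
    n = len(densities)
    temps = rng.integers(0, steps + 1, size=n)
    props = np.empty((n, K))
    for i in range(n):
        w = temperature_weights(int(temps[i]), steps, base, K, rng)
        props[i] = sample_composition(w, int(densities[i]), rng).proportions
    return props, densities, temps


def generate_dataset(
    split: tuple[GeneCountMatrix, CellTypeAnnotation],
    density_range: tuple[int, int],
    n_per_density: int,
    steps: int = DEFAULT_STEPS,
    base: float = DEFAULT_BASE,
    seed: int = 0,
    role: str = "train",
) -> SpotDataset:
    """Generate ``n_per_density`` pseudo-spots for every density in the range.

    Fully reproducible from ``seed``: the same seed yields bit-identical
    datasets.
    """
    lo, hi = density_range
    if hi < lo:
        raise ValueError("empty density range")
    if n_per_density < 1:
        raise ValueError("n_per_density must be >= 1")
    matrix, annotation = split
    index = _TypeIndex(matrix, annotation)
    K = annotation.n_types
    rng = np.random.default_rng(seed)
    densities = np.repeat(np.arange(lo, hi + 1), n_per_density)
    n = len(densities)
    temps = rng.integers(0, steps + 1, size=n)
    profiles = np.empty((n, matrix.n_genes))
    proportions = np.empty((n, K))
    for i in range(n):
        w = temperature_weights(int(temps[i]), steps, base, K, rng)
        comp = sample_composition(w, int(densities[i]), rng)
        spot = synthesize_profile(comp, index, rng)
        profiles[i] = spot.profile
        proportions[i] = spot.proportions
    return SpotDataset(
        profiles=profiles,
        proportions=proportions,
        densities=densities,
        temps=temps,
        gene_ids=list(matrix.gene_ids),
        label_order=list(annotation.label_order),
        role=role,
        seed=seed,
        density_range=(lo, hi),
        n_per_density=n_per_density,
        steps=steps,
        base=base,
    )
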