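"""Reading, writing and aligning gene-count matrices and annotations.

The in-memory convention is observations (cells or spots) in rows and genes
in columns, whatever the on-disk orientation.  Two on-disk layouts are
supported: a 10x-style MatrixMarket triplet (``matrix.mtx`` plus gene and
barcode index files) and a dense delimited table with a header row of gene
identifiers and a first column of observation identifiers.

Gene identifiers are matched by exact, case-sensitive string equality; no
alias resolution is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MatrixFormatError(ValueError):
    """A count file could not be parsed or failed validation."""


@dataclass
class GeneCountMatrix:
    """Observations x genes non-negative count (or normalized) matrix.

    Parameters
    ----------
    values
        2-D non-negative array, one row per observation, one column per gene.
    obs_ids
        Unique observation (cell or spot) identifiers, one per row.
    gene_ids
        Unique gene identifiers, one per column.
    """

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("count matrix must be 2-dimensional")
        n, g = self.values.shape
        if len(self.obs_ids) != n:
            raise MatrixFormatError(
                f"{len(self.obs_ids)} observation ids for {n} rows"
            )
        if len(self.gene_ids) != g:
            raise MatrixFormatError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.obs_ids)) != n:
            raise MatrixFormatError("duplicate observation identifiers")
        if len(set(self.gene_ids)) != g:
            raise MatrixFormatError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("non-finite entries in count matrix")
        if np.any(self.values < 0):
            raise MatrixFormatError("negative entries in count matrix")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "GeneCountMatrix":
        """Restrict to ``genes``, in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        cols = [index[g] for g in genes]
        return GeneCountMatrix(self.values[:, cols], list(self.obs_ids), list(genes))

    def subset_obs(self, obs: Sequence[str]) -> "GeneCountMatrix":
        index = {o: i for i, o in enumerate(self.obs_ids)}
        rows = [index[o] for o in obs]
        return GeneCountMatrix(self.values[rows, :], list(obs), list(self.gene_ids))


@dataclass
class CellTypeAnnotation:
    """cell_id -> cell-type label mapping with a fixed label order.

    ``label_order`` fixes the index meaning of every proportion vector
    produced downstream; it defaults to first-appearance order of the
    labels in ``mapping``.
    """

    mapping: dict[str, str]
    label_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_order:
            seen: list[str] = []
            for lab in self.mapping.values():
                if lab not in seen:
                    seen.append(lab)
            self.label_order = seen
        if len(set(self.label_order)) != len(self.label_order):
            raise ValueError("duplicate labels in label_order")
        extra = set(self.mapping.values()) - set(self.label_order)
        if extra:
            raise ValueError(f"labels missing from label_order: {sorted(extra)}")
        if len(self.label_order) < 2:
            raise ValueError("at least two cell types are required")

    @property
    def n_types(self) -> int:
        return len(self.label_order)

    def labels_for(self, obs_ids: Sequence[str]) -> np.ndarray:
        """Integer label codes (indices into label_order) for ``obs_ids``."""
        code = {lab: k for k, lab in enumerate(self.label_order)}
        try:
            return np.array([code[self.mapping[o]] for o in obs_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"observation without annotation: {exc}") from exc

    def cells_of_type(self, label: str) -> list[str]:
        return [c for c, lab in self.mapping.items() if lab == label]

    def validate_against(self, matrix: GeneCountMatrix) -> None:
        obs = set(matrix.obs_ids)
        orphans = [c for c in self.mapping if c not in obs]
        if orphans:
            raise ValueError(
                f"{len(orphans)} annotated cells absent from the count matrix "
                f"(e.g. {orphans[:3]})"
            )


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_index_file(path: Path) -> list[str]:
    """First column of a headerless one-or-two-column index file."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            out.append(line.split("\t")[0].split(",")[0])
    return out


def read_count_matrix(
    path: str | Path,
    fmt: str | None = None,
    genes_file: str | Path | None = None,
    obs_file: str | Path | None = None,
) -> GeneCountMatrix:
    """Read a count matrix from disk.

    ``fmt`` is ``"mtx-triplet"`` or ``"dense-delimited"``; when omitted it is
    inferred from the suffix (``.mtx`` vs anything else).  For the triplet
    layout, gene and observation index files default to ``genes.tsv`` (or
    ``features.tsv``) and ``barcodes.tsv`` next to the matrix; the on-disk
    orientation (10x files are genes x cells) is resolved by matching the
    matrix dimensions against the two index lengths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mtx-triplet" if path.suffix == ".mtx" else "dense-delimited"

    if fmt == "mtx-triplet":
        if genes_file is None:
            for cand in ("genes.tsv", "features.tsv"):
                if (path.parent / cand).exists():
                    genes_file = path.parent / cand
                    break
        if obs_file is None and (path.parent / "barcodes.tsv").exists():
            obs_file = path.parent / "barcodes.tsv"
        if genes_file is None or obs_file is None:
            raise MatrixFormatError(
                f"MatrixMarket triplet {path} needs gene and observation index files"
            )
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse MatrixMarket file {path}: {exc}")
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes = _read_index_file(Path(genes_file))
        obs = _read_index_file(Path(obs_file))
        nr, nc = dense.shape
        if nr == len(obs) and nc == len(genes):
            pass  # already observations x genes
        elif nr == len(genes) and nc == len(obs):
            dense = dense.T
        else:
            raise MatrixFormatError(
                f"matrix shape {dense.shape} matches neither "
                f"({len(obs)} obs, {len(genes)} genes) orientation"
            )
        return GeneCountMatrix(dense, obs, genes)

    if fmt == "dense-delimited":
        with open(path) as fh:
            header = fh.readline()
        sep = _detect_delimiter(header)
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse dense table {path}: {exc}")
        return GeneCountMatrix(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
        )

    raise ValueError(f"unknown format {fmt!r}")


def write_count_matrix(
    matrix: GeneCountMatrix, path: str | Path, fmt: str = "dense-delimited"
) -> None:
    """Write a matrix as a dense CSV or a MatrixMarket triplet directory."""
    path = Path(path)
    if fmt == "dense-delimited":
        df = pd.DataFrame(matrix.values, index=matrix.obs_ids, columns=matrix.gene_ids)
        df.to_csv(path, float_format="%.17g")
    elif fmt == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"),
            scipy.sparse.csr_matrix(matrix.values),
            precision=17,
        )
        (path / "barcodes.tsv").write_text("\n".join(matrix.obs_ids) + "\n")
        (path / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_annotation(path: str | Path) -> CellTypeAnnotation:
    """Read a two-column (cell_id, cell_type) delimited table."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise MatrixFormatError(f"annotation table {path} needs two columns")
    cells = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(str)
    return CellTypeAnnotation(dict(zip(cells, labels)))


def write_annotation(annotation: CellTypeAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(
        {"cell_id": list(annotation.mapping), "cell_type": list(annotation.mapping.values())}
    )
    df.to_csv(path, index=False)


def intersect_genes(
    reference: GeneCountMatrix, spots: Iterable[GeneCountMatrix]
) -> tuple[GeneCountMatrix, list[GeneCountMatrix]]:
    """Restrict the reference and every spot matrix to their common genes.

    The shared column order is the reference's gene order filtered to the
    intersection.  Raises if the intersection is empty, which usually means
    the two sides use different identifier namespaces (e.g. symbols vs
    Ensembl ids).
    """
    spots = list(spots)
    if not spots:
        raise ValueError("at least one spot matrix is required")
    common = set(reference.gene_ids)
    for sp in spots:
        common &= set(sp.gene_ids)
    if not common:
        raise ValueError(
            "no genes shared between reference and spot matrices; "
            "harmonize gene identifier namespaces (case-sensitive symbols)"
        )
    order = [g for g in reference.gene_ids if g in common]
    return reference.subset_genes(order), [sp.subset_genes(order) for sp in spots]


def write_proportions(
    proportions: np.ndarray,
    spot_ids: Sequence[str],
    label_order: Sequence[str],
    path: str | Path,
) -> None:
    """Write one proportion vector per spot as CSV.

    Header is ``spot_id,<label_1>,...,<label_K>``; values round-trip within
    1e-9 (written at full precision).
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size == 0:
        proportions = proportions.reshape(0, len(label_order))
    if proportions.ndim != 2 or proportions.shape[1] != len(label_order):
        raise ValueError(
            f"proportion vectors have length {proportions.shape[-1] if proportions.size else 0}, "
            f"expected {len(label_order)}"
        )
    if len(spot_ids) != proportions.shape[0]:
        raise ValueError("one spot id per proportion vector is required")
    df = pd.DataFrame(proportions, index=list(spot_ids), columns=list(label_order))
    df.index.name = "spot_id"
    df.to_csv(path, float_format="%.17g")


def read_proportions(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`write_proportions`: (values, spot_ids, label_order)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], list(df.columns)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
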