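"""Expression-matrix and gene-set containers plus readers, writers and preprocessing.

The central container is :class:`ExpressionMatrix`, a genes x cells (or genes x
samples) matrix with unique string names on both axes, a ``layer`` tag recording
what the values are (raw ``counts``, ``cpm``, or ``lognorm``), and a per-cell
metadata table (``compartment``, optional ``state`` and ``sample_id``).

Supported on-disk formats are deliberately plain: Matrix Market triplets with
line-per-entry gene/cell name files, dense TSV/CSV with a header row of cell
ids, and the GMT dialect for gene sets and regulons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

LAYERS = ("counts", "cpm", "lognorm")
COMPARTMENTS = ("tumor", "cd8")


class DuplicateNameError(ValueError):
    """Raised when gene names, cell ids or set names are not unique."""


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of gene identifiers.

    Gene identifiers are opaque case-sensitive strings; no aliasing is done.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        genes = tuple(dict.fromkeys(self.genes))  # dedupe, keep order
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class Regulon:
    """A transcription factor together with its putative target genes."""

    tf: str
    targets: GeneSet

    @property
    def name(self) -> str:
        return self.targets.name

    @property
    def genes(self) -> tuple[str, ...]:
        return self.targets.genes

    def __len__(self) -> int:
        return len(self.targets)


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = pd.Index(names)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DuplicateNameError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression with names, a layer tag and cell metadata."""

    values: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    layer: str = "counts"
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_ids)} cells"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.cell_ids, "cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index.name = "cell_id"
            if set(self.cell_meta.index) != set(self.cell_ids):
                raise ValueError("cell_meta must cover exactly the cell ids")
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index([gene])[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.values[idx], self.gene_names[idx], self.cell_ids, self.layer, self.cell_meta
        )

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cells], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_names,
            self.cell_ids[idx],
            self.layer,
            self.cell_meta.iloc[idx],
        )

    def compartment(self, name: str) -> "ExpressionMatrix":
        if "compartment" not in self.cell_meta.columns:
            raise ValueError("cell_meta has no 'compartment' column")
        cells = self.cell_meta.index[self.cell_meta["compartment"] == name]
        if len(cells) == 0:
            raise ValueError(f"no cells in compartment {name!r}")
        return self.subset_cells(list(cells))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_names(path) -> np.ndarray:
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray(names, dtype=object)


def read_expression(path_matrix, path_genes=None, path_cells=None, layer="counts",
                    cell_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes x cells matrix from Matrix Market or a dense delimited table.

    Matrix Market input requires ``path_genes``/``path_cells`` (one name per
    line, rows resp. columns). Dense TSV/CSV carries gene names in the first
    column and cell ids in the header row; name files, if given, must agree.
    """
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise ValueError("matrix-market input requires gene and cell name files")
        mat = mmread(str(path_matrix))
        values = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        genes, cells = _read_names(path_genes), _read_names(path_cells)
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match name files "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    else:
        sep = "," if path_matrix.suffix == ".csv" else "\t"
        df = pd.read_csv(path_matrix, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        genes = np.asarray(df.index, dtype=object)
        cells = np.asarray(df.columns, dtype=object)
        if path_genes is not None and not np.array_equal(_read_names(path_genes), genes):
            raise ValueError("gene name file disagrees with dense table index")
        if path_cells is not None and not np.array_equal(_read_names(path_cells), cells):
            raise ValueError("cell name file disagrees with dense table header")
    return ExpressionMatrix(values, genes, cells, layer=layer, cell_meta=cell_meta)


def write_expression(x: ExpressionMatrix, path_matrix, path_genes=None, path_cells=None) -> None:
    """Write an :class:`ExpressionMatrix` back to .mtx + name files or a dense table."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise ValueError("matrix-market output requires gene and cell name paths")
        mmwrite(str(path_matrix), sparse.coo_matrix(x.values))
        Path(path_genes).write_text("\n".join(map(str, x.gene_names)) + "\n")
        Path(path_cells).write_text("\n".join(map(str, x.cell_ids)) + "\n")
    else:
        sep = "," if path_matrix.suffix == ".csv" else "\t"
        x.to_frame().to_csv(path_matrix, sep=sep)


def read_cell_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


_NO_TF_TOKENS = {"", "na", "NA", "n/a", "none", "."}


def read_gene_sets(path, as_regulons: bool | None = None) -> list:
    """Parse a GMT file into :class:`GeneSet`/:class:`Regulon` records.

    Each line is ``name<TAB>description<TAB>gene...``. A description that is a
    placeholder token (``na``, ``.``, empty, ...) yields a plain gene set;
    anything else is read as the TF of a regulon. ``as_regulons`` forces one
    interpretation for the whole file.
    """
    records, names = [], set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
        if name in names:
            raise DuplicateNameError(f"{path}:{lineno}: duplicate set name {name!r}")
        names.add(name)
        gs = GeneSet(name, tuple(genes))
        is_regulon = as_regulons if as_regulons is not None else desc not in _NO_TF_TOKENS
        records.append(Regulon(tf=desc, targets=gs) if is_regulon else gs)
    return records


def write_gene_sets(sets: Iterable, path) -> None:
    lines = []
    for s in sets:
        desc = s.tf if isinstance(s, Regulon) else "na"
        lines.append("\t".join([s.name, desc, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def cpm_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: scale each cell's counts to sum to 1e6."""
    if x.layer != "counts":
        raise ValueError(f"cpm_normalize expects a counts layer, got {x.layer!r}")
    totals = x.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total count: {list(x.cell_ids[zero[:5]])}")
    return ExpressionMatrix(
        x.values / totals * 1e6, x.gene_names, x.cell_ids, layer="cpm", cell_meta=x.cell_meta
    )


def log_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Variance-stabilized layer: log(1 + CPM/100)."""
    cpm = x if x.layer == "cpm" else cpm_normalize(x)
    return ExpressionMatrix(
        np.log1p(cpm.values / 100.0), x.gene_names, x.cell_ids,
        layer="lognorm", cell_meta=x.cell_meta,
    )


def filter_low_genes(x: ExpressionMatrix, min_frac: float = 0.10) -> ExpressionMatrix:
    """Drop genes expressed (value > 0) in less than ``min_frac`` of cells.

    Applied per compartment by the caller, matching the convention that tumor
    and CD8 matrices are filtered separately. A gene positive in exactly
    ``min_frac`` of cells is kept.
    """
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must be in (0, 1)")
    frac = (x.values > 0).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        warnings.warn("filter_low_genes removed every gene", stacklevel=2)
    return ExpressionMatrix(
        x.values[keep], x.gene_names[keep], x.cell_ids, x.layer, x.cell_meta
    )
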