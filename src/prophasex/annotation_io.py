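"""Expression-matrix and annotation I/O, and the gene-class partition.

Every downstream statistic in the package is stratified by a chromosome
class: autosomes (with chromosome 7 additionally tracked as its own
control class), X-linked genes split into XCI escapees (``CHRX_E``:
Balaton-style categories PAR / E / mostly E / mostly VE / VE) versus genes
subject to XCI (``CHRX_S``), the Y, and an ``EXCLUDED`` bucket
(mitochondrial, unplaced scaffolds). This module builds that partition and
reads/writes the gene x cell matrices it applies to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "AUTOSOME",
    "CHR7",
    "CHRX_E",
    "CHRX_S",
    "CHRY",
    "EXCLUDED",
    "CHROM_CLASSES",
    "ESCAPE_CATEGORIES",
    "ExpressionBundle",
    "classify_genes",
    "load_expression",
    "save_expression",
    "restrict_universe",
    "attach_annotation",
    "read_annotation_table",
    "read_escape_table",
    "autosome_universe",
]

AUTOSOME = "AUTOSOME"
CHR7 = "CHR7"
CHRX_E = "CHRX_E"
CHRX_S = "CHRX_S"
CHRY = "CHRY"
EXCLUDED = "EXCLUDED"
CHROM_CLASSES = (AUTOSOME, CHR7, CHRX_E, CHRX_S, CHRY, EXCLUDED)

#: canonical escape categories; the first five mark XCI escape
ESCAPE_CATEGORIES = ("PAR", "E", "mostly_E", "mostly_VE", "VE", "S", "unknown")
_ESCAPE_SET = {"par", "e", "mostly e", "mostly ve", "ve"}
_AUTOSOME_NAMES = {str(i) for i in range(1, 23)}


def _normalize_category(raw: str) -> str:
    return " ".join(str(raw).strip().lower().replace("_", " ").split())


def _canonical_category(raw: str) -> str:
    norm = _normalize_category(raw)
    mapping = {
        "par": "PAR",
        "e": "E",
        "mostly e": "mostly_E",
        "mostly ve": "mostly_VE",
        "ve": "VE",
        "s": "S",
    }
    return mapping.get(norm, "unknown")


def _normalize_chromosome(raw: str) -> str:
    c = str(raw).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in {"X", "Y", "MT", "M"}:
        return "MT" if c.upper() in {"MT", "M"} else c.upper()
    return c


@dataclass
class ExpressionBundle:
    """Aligned TPM matrix with optional spliced/unspliced counts.

    All matrices are gene x cell DataFrames sharing identical row and
    column labels; ``cells`` is indexed by cell id and ``genes`` by gene
    id, in matrix order.
    """

    tpm: pd.DataFrame
    cells: pd.DataFrame
    genes: pd.DataFrame
    spliced: pd.DataFrame | None = None
    unspliced: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if (self.spliced is None) != (self.unspliced is None):
            raise ValueError("spliced and unspliced matrices must be present together or both absent")
        if not self.tpm.index.equals(self.genes.index):
            raise ValueError("tpm row labels do not match gene table")
        if not self.tpm.columns.equals(self.cells.index):
            raise ValueError("tpm column labels do not match cell table")
        for name, mat in (("tpm", self.tpm), ("spliced", self.spliced), ("unspliced", self.unspliced)):
            if mat is None:
                continue
            if not mat.index.equals(self.tpm.index) or not mat.columns.equals(self.tpm.columns):
                raise ValueError(f"{name} matrix labels do not match the tpm matrix")
            vals = mat.to_numpy()
            if (vals < 0).any():
                g, c = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative value in {name} matrix at gene {mat.index[g]!r}, cell {mat.columns[c]!r}"
                )

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tpm.shape[1]

    def has_velocity(self) -> bool:
        return self.spliced is not None

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, gene_ids) -> "ExpressionBundle":
        idx = self.tpm.index.intersection(pd.Index(gene_ids))
        keep = self.tpm.index[self.tpm.index.isin(idx)]  # original order
        return replace(
            self,
            tpm=self.tpm.loc[keep],
            genes=self.genes.loc[keep],
            spliced=None if self.spliced is None else self.spliced.loc[keep],
            unspliced=None if self.unspliced is None else self.unspliced.loc[keep],
        )

    def subset_cells(self, cell_ids) -> "ExpressionBundle":
        keep = self.tpm.columns[self.tpm.columns.isin(pd.Index(cell_ids))]
        return replace(
            self,
            tpm=self.tpm[keep],
            cells=self.cells.loc[keep],
            spliced=None if self.spliced is None else self.spliced[keep],
            unspliced=None if self.unspliced is None else self.unspliced[keep],
        )


def classify_genes(genes: pd.DataFrame, escape_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Partition genes into chromosome classes.

    Parameters
    ----------
    genes
        Annotation rows with columns ``gene_id``, ``chromosome`` and
        optionally ``biotype`` (and, for locus maps, ``start``/``end``).
    escape_table
        Rows of (gene_id, category); category strings are matched
        case-insensitively with whitespace/underscore normalization.

    Returns
    -------
    DataFrame indexed by gene_id with columns ``chromosome``, ``biotype``,
    ``escape_category`` and ``chrom_class``. Every gene receives exactly
    one class: X genes with an escape-flavour category -> ``CHRX_E``,
    remaining X genes -> ``CHRX_S``, chromosome 7 -> ``CHR7`` (still part
    of the autosome universe), other chr1-22 -> ``AUTOSOME``, Y ->
    ``CHRY``, anything else (MT, scaffolds, unknown) -> ``EXCLUDED``.
    """
    df = genes.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    dup = df.index.duplicated(keep="first")
    if dup.any():
        logger.warning("dropping %d duplicate gene ids (keeping first occurrence)", int(dup.sum()))
        df = df[~dup]
    df["chromosome"] = df["chromosome"].map(_normalize_chromosome)
    if "biotype" not in df.columns:
        df["biotype"] = "other"

    escape: dict[str, str] = {}
    if escape_table is not None and len(escape_table):
        et = escape_table.copy()
        if "gene_id" in et.columns:
            et = et.set_index("gene_id")
        cat_col = "category" if "category" in et.columns else et.columns[0]
        for gid, raw in et[cat_col].items():
            if gid in escape:
                continue
            escape[gid] = raw

    categories = []
    classes = []
    for gid, row in df.iterrows():
        chrom = row["chromosome"]
        raw = escape.get(gid)
        cat = "unknown"
        if raw is not None:
            if chrom != "X":
                logger.warning("escape category %r assigned to non-X gene %s; ignored", raw, gid)
            else:
                cat = _canonical_category(raw)
        if chrom == "X":
            if raw is not None and _normalize_category(raw) in _ESCAPE_SET:
                classes.append(CHRX_E)
            else:
                classes.append(CHRX_S)
                if raw is None:
                    cat = "S"
        elif chrom == "7":
            classes.append(CHR7)
        elif chrom in _AUTOSOME_NAMES:
            classes.append(AUTOSOME)
        elif chrom == "Y":
            classes.append(CHRY)
        else:
            classes.append(EXCLUDED)
        categories.append(cat)
    df["escape_category"] = categories
    df["chrom_class"] = classes
    return df


def autosome_universe(genes: pd.DataFrame) -> pd.Index:
    """Gene ids of the autosome universe (chr1-22, chromosome 7 included)."""
    mask = genes["chrom_class"].isin([AUTOSOME, CHR7])
    return genes.index[mask]


# ----------------------------------------------------------------------
# file formats
# ----------------------------------------------------------------------

def _read_labels(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _load_matrix(matrix_path, gene_labels, cell_labels, fmt: str) -> pd.DataFrame:
    matrix_path = Path(matrix_path)
    if fmt == "tsv":
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mat.index = mat.index.astype(str)
        mat.columns = mat.columns.astype(str)
        if mat.shape[0] != len(gene_labels):
            raise ValueError(
                f"{matrix_path} has {mat.shape[0]} gene rows but the gene label file lists {len(gene_labels)}"
            )
        if mat.shape[1] != len(cell_labels):
            raise ValueError(
                f"{matrix_path} has {mat.shape[1]} cell columns but the cell label file lists {len(cell_labels)}"
            )
        if set(mat.index) != set(gene_labels) or list(mat.columns) != list(cell_labels) and set(mat.columns) != set(cell_labels):
            if set(mat.index) != set(gene_labels):
                raise ValueError(f"gene ids in {matrix_path} do not match the gene label file")
            raise ValueError(f"cell ids in {matrix_path} do not match the cell label file")
        mat = mat.loc[gene_labels, cell_labels]
    elif fmt == "mtx":
        coo = spio.mmread(matrix_path)
        if coo.shape[0] != len(gene_labels):
            raise ValueError(
                f"{matrix_path} declares {coo.shape[0]} rows but the gene label file lists {len(gene_labels)}"
            )
        if coo.shape[1] != len(cell_labels):
            raise ValueError(
                f"{matrix_path} declares {coo.shape[1]} columns but the cell label file lists {len(cell_labels)}"
            )
        dense = np.asarray(coo.todense() if sparse.issparse(coo) else coo, dtype=float)
        mat = pd.DataFrame(dense, index=gene_labels, columns=cell_labels)
    else:
        raise ValueError(f"unknown matrix format {fmt!r} (expected 'tsv' or 'mtx')")
    vals = mat.to_numpy()
    if (vals < 0).any():
        g, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative value in {matrix_path} at gene {mat.index[g]!r}, cell {mat.columns[c]!r}"
        )
    return mat


def load_expression(
    matrix_path,
    genes_path,
    cells_path,
    format: str = "tsv",
    spliced_path=None,
    unspliced_path=None,
) -> ExpressionBundle:
    """Load a TPM matrix (and optional spliced/unspliced counts) from disk.

    ``genes_path`` / ``cells_path`` are sidecar label files, one id per
    line; gene and cell order is taken from them. TSV matrices carry the
    gene id in the first column and a header row of cell ids; MTX files
    are MatrixMarket coordinate triplets.
    """
    gene_labels = _read_labels(genes_path)
    cell_labels = _read_labels(cells_path)
    tpm = _load_matrix(matrix_path, gene_labels, cell_labels, format)
    if (spliced_path is None) != (unspliced_path is None):
        raise ValueError("spliced and unspliced matrix paths must be given together")
    spliced = unspliced = None
    if spliced_path is not None:
        spliced = _load_matrix(spliced_path, gene_labels, cell_labels, format)
        unspliced = _load_matrix(unspliced_path, gene_labels, cell_labels, format)
    genes = pd.DataFrame(index=pd.Index(gene_labels, name="gene_id"))
    cells = pd.DataFrame(index=pd.Index(cell_labels, name="cell_id"))
    return ExpressionBundle(tpm=tpm, cells=cells, genes=genes, spliced=spliced, unspliced=unspliced)


def save_expression(bundle: ExpressionBundle, out_dir, format: str = "tsv") -> dict[str, Path]:
    """Write a bundle to ``out_dir``; inverse of :func:`load_expression`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, mat: pd.DataFrame) -> None:
        if format == "tsv":
            p = out_dir / f"{name}.tsv"
            mat.to_csv(p, sep="\t", index_label="gene_id")
        elif format == "mtx":
            p = out_dir / f"{name}.mtx"
            spio.mmwrite(str(p), sparse.coo_matrix(mat.to_numpy()))
        else:
            raise ValueError(f"unknown matrix format {format!r}")
        paths[name] = p

    _write("matrix", bundle.tpm)
    if bundle.spliced is not None:
        _write("spliced", bundle.spliced)
        _write("unspliced", bundle.unspliced)
    genes_p = out_dir / "genes.txt"
    genes_p.write_text("\n".join(bundle.tpm.index) + "\n")
    cells_p = out_dir / "cells.txt"
    cells_p.write_text("\n".join(bundle.tpm.columns) + "\n")
    paths["genes"] = genes_p
    paths["cells"] = cells_p
    if len(bundle.cells.columns):
        meta_p = out_dir / "cell_metadata.tsv"
        bundle.cells.to_csv(meta_p, sep="\t", index_label="cell_id")
        paths["cell_metadata"] = meta_p
    return paths


def restrict_universe(bundle: ExpressionBundle, gene_ids) -> ExpressionBundle:
    """Restrict a bundle to the listed genes (e.g. a ubiquitously-expressed set).

    Genes are kept in their original matrix order; an empty intersection
    is an error.
    """
    gene_ids = set(gene_ids)
    keep = [g for g in bundle.tpm.index if g in gene_ids]
    if not keep:
        raise ValueError("restrict_universe: no listed gene ids are present in the bundle")
    return bundle.subset_genes(keep)


def attach_annotation(bundle: ExpressionBundle, annotation: pd.DataFrame) -> ExpressionBundle:
    """Attach a classified gene-annotation table (see :func:`classify_genes`).

    Bundle genes missing from the annotation are classed ``EXCLUDED``.
    """
    genes = annotation.reindex(bundle.tpm.index)
    missing = genes["chrom_class"].isna()
    if missing.any():
        logger.warning("%d bundle genes missing from annotation -> EXCLUDED", int(missing.sum()))
        genes.loc[missing, "chrom_class"] = EXCLUDED
        genes.loc[missing, "chromosome"] = "unknown"
        genes.loc[missing, "escape_category"] = "unknown"
    genes.index.name = "gene_id"
    return replace(bundle, genes=genes)


def read_annotation_table(path) -> pd.DataFrame:
    """Read a gene annotation TSV (columns gene_id, chromosome, biotype, ...)."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})


def read_escape_table(path) -> pd.DataFrame:
    """Read an XCI-escape table TSV (columns gene_id, category)."""
    return pd.read_csv(path, sep="\t", dtype=str)
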