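"""Readers and writers for expression matrices, registries and tables.

Supported expression interchange formats:

* MatrixMarket coordinate (``.mtx``) with one-column TSV files listing gene
  and cell ids in matrix order — the standard sparse export of single-cell
  pipelines;
* a single dense CSV with genes as rows (index) and cells as columns.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CellAnnotationTable,
    FormatError,
    GeneExpressionMatrix,
    LigandReceptorRegistry,
    SurvivalTable,
    ValidationError,
)


def _read_id_file(path: Path) -> list:
    ids = pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()
    return ids


def load_expression(
    matrix_path,
    genes_path=None,
    cells_path=None,
    normalized: bool = False,
) -> GeneExpressionMatrix:
    """Load a gene × cell expression matrix from MTX+TSV or dense CSV.

    Ids are attached in file order. The returned matrix is flagged raw
    (``normalized=False``) unless stated otherwise.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("MTX input requires gene and cell id files")
        m = scipy.io.mmread(str(matrix_path))
        values = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
        genes = _read_id_file(Path(genes_path))
        cells = _read_id_file(Path(cells_path))
        if values.shape != (len(genes), len(cells)):
            raise FormatError(
                f"MTX declares shape {values.shape} but id files list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
    else:
        df = pd.read_csv(matrix_path, index_col=0)
        values = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    return GeneExpressionMatrix(values, genes, cells, normalized=normalized)


def write_expression(
    m: GeneExpressionMatrix,
    matrix_path,
    genes_path=None,
    cells_path=None,
) -> None:
    """Write MTX+TSV when ``matrix_path`` ends in .mtx, else dense CSV."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("MTX output requires gene and cell id paths")
        scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(m.values))
        pd.Series(m.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)
    else:
        m.to_frame().to_csv(matrix_path, float_format="%.10g")


def log_normalize(m: GeneExpressionMatrix, scale: float = 10_000.0) -> GeneExpressionMatrix:
    """Depth-normalize and log-transform counts: x ↦ ln(1 + scale·x/colsum).

    The scale factor rescales each cell to a common library size before the
    log1p transform; 10,000 is the community default.
    """
    if m.normalized:
        raise ValidationError("matrix is already log-normalized")
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValidationError(
            f"cells with zero total counts cannot be normalized: "
            f"{[m.cell_ids[i] for i in zero[:5]]}"
        )
    values = np.log1p(scale * m.values / colsums)
    return GeneExpressionMatrix(values, list(m.gene_ids), list(m.cell_ids), normalized=True)


def load_annotations(path) -> CellAnnotationTable:
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    if "compartment" not in df.columns:
        df["compartment"] = "hematopoietic"
    return CellAnnotationTable(df)


def write_annotations(t: CellAnnotationTable, path) -> None:
    t.table.to_csv(path, index=False)


def load_registry(path: Optional[object] = None) -> LigandReceptorRegistry:
    """Load a ligand–receptor registry CSV (columns ligand,receptor,class).

    Without ``path``, the bundled curated chemokine registry is returned.
    """
    if path is None:
        ref = importlib.resources.files("lymphochemnet").joinpath(
            "data/chemokine_lr_pairs.csv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for col in ("ligand", "receptor", "class"):
        if col not in df.columns:
            raise FormatError(f"registry missing column {col!r}")
    pairs = list(zip(df["ligand"].astype(str), df["receptor"].astype(str)))
    class_of = dict(zip(df["ligand"].astype(str), df["class"].astype(str)))
    return LigandReceptorRegistry(pairs, class_of)


def write_registry(reg: LigandReceptorRegistry, path) -> None:
    pd.DataFrame(
        {
            "ligand": reg.ligands,
            "receptor": reg.receptors,
            "class": [reg.class_of.get(l, "other") for l in reg.ligands],
        }
    ).to_csv(path, index=False)


def load_spatial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    for col in ("cell_id", "x_um", "y_um", "cell_type"):
        if col not in df.columns:
            raise FormatError(f"spatial table missing column {col!r}")
    if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy(float))):
        raise ValidationError("non-finite spatial coordinates")
    return df


def load_survival_table(path) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, dtype={"subject_id": str}))
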