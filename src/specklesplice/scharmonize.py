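"""Cross-dataset single-cell expression harmonization on the ln(TPM+1) scale.

Public single-cell atlases report *Slc12a2* (NKCC1) expression on incompatible
scales.  The common scale used here normalizes each cell's UMI count for the
gene by the cell's total UMIs, multiplies by 10^6 (TPM) and takes ln(TPM + 1).
The transform is scale-invariant in the library (multiplying a cell's whole
count vector by k leaves it unchanged) and zero iff the gene was not observed.

Detection follows each source dataset's own rule: by default any single
transcript counts as detected; a dataset may instead impose an inclusive
threshold on the ln(TPM+1) scale (e.g. 1.1).  One source provides only
subcluster aggregates; those bypass per-cell normalization and are carried
through flagged as ``subcluster``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DatasetSpec",
    "normalize_ln_tpm",
    "expression_records",
    "apply_detection",
    "aggregate_by_type",
    "read_mtx_dataset",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Per-dataset handling rules for harmonization."""

    name: str
    granularity: str = "cell"  # "cell" | "subcluster"
    detection_threshold: float = 0.0  # on the ln(TPM+1) scale; 0 => any transcript
    annotation_key: str = "cell_type"

    def __post_init__(self) -> None:
        if self.granularity not in ("cell", "subcluster"):
            raise ValueError("granularity must be 'cell' or 'subcluster'")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")


def normalize_ln_tpm(gene_umi, total_umi):
    """ln(gene_umi / total_umi * 10^6 + 1), elementwise.

    Monotone increasing in ``gene_umi`` for fixed ``total_umi``; equals 0 iff
    ``gene_umi`` is 0.  ``total_umi`` must be positive and at least
    ``gene_umi``.
    """
    gene = np.asarray(gene_umi, dtype=float)
    total = np.asarray(total_umi, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_umi must be > 0")
    if np.any(gene < 0):
        raise ValueError("gene_umi must be >= 0")
    if np.any(gene > total):
        raise ValueError("gene_umi cannot exceed total_umi")
    result = np.log1p(gene / total * 1e6)
    return float(result) if result.ndim == 0 else result


def expression_records(
    matrix,
    genes: list[str],
    annotations: pd.DataFrame,
    gene: str,
) -> pd.DataFrame:
    """Build the per-cell record table for one focal gene.

    ``matrix`` is genes x cells (sparse or dense); ``annotations`` must carry
    ``cell_id`` (column order matches the matrix) and a cell-type column.
    """
    import scipy.sparse

    if gene not in genes:
        raise KeyError(f"gene {gene!r} not in the gene list")
    mat = scipy.sparse.csr_matrix(matrix)
    gi = genes.index(gene)
    gene_umi = np.asarray(mat[gi].todense()).ravel()
    total_umi = np.asarray(mat.sum(axis=0)).ravel()
    if len(annotations) != mat.shape[1]:
        raise ValueError("annotation table length must match matrix columns")
    if np.any(total_umi <= 0):
        raise ValueError("every cell must have a positive total UMI count")
    tpm = gene_umi / total_umi * 1e6
    return pd.DataFrame(
        {
            "cell_id": annotations["cell_id"].to_numpy(),
            "cell_type": annotations.get(
                "cell_type", pd.Series([np.nan] * len(annotations))
            ).to_numpy(),
            "gene_umi": gene_umi.astype(int),
            "total_umi": total_umi.astype(int),
            "tpm": tpm,
            "ln_tpm1": np.log1p(tpm),
        }
    )


def apply_detection(records: pd.DataFrame, spec: DatasetSpec) -> pd.DataFrame:
    """Flag detection per the dataset's rule; sub-threshold cells are kept.

    With a positive threshold, detected means ln_tpm1 >= threshold
    (inclusive); with threshold 0, detected means at least one transcript.
    """
    out = records.copy()
    if spec.detection_threshold > 0:
        out["detected"] = out["ln_tpm1"] >= spec.detection_threshold
    else:
        out["detected"] = out["gene_umi"] >= 1
    out["dataset"] = spec.name
    out["granularity"] = spec.granularity
    return out


def aggregate_by_type(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type expression summary.

    One row per annotated cell type: n cells, fraction detected, mean/median
    ln(TPM+1) and quartiles.  Unannotated cells are counted and excluded with
    a warning.  The cell-count-weighted mean of the per-type means equals the
    global mean over annotated cells.
    """
    unannotated = records["cell_type"].isna()
    if unannotated.any():
        warnings.warn(
            f"{int(unannotated.sum())} unannotated cells excluded from aggregation",
            stacklevel=2,
        )
    usable = records[~unannotated]
    rows = []
    for ctype, grp in usable.groupby("cell_type", sort=True):
        vals = grp["ln_tpm1"]
        rows.append(
            {
                "cell_type": ctype,
                "n_cells": len(grp),
                "frac_detected": float(grp["detected"].mean())
                if "detected" in grp
                else np.nan,
                "mean_ln_tpm1": float(vals.mean()),
                "median_ln_tpm1": float(vals.median()),
                "q25_ln_tpm1": float(vals.quantile(0.25)),
                "q75_ln_tpm1": float(vals.quantile(0.75)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_type", "n_cells", "frac_detected",
            "mean_ln_tpm1", "median_ln_tpm1", "q25_ln_tpm1", "q75_ln_tpm1",
        ],
    )


def read_mtx_dataset(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> tuple["scipy.sparse.csr_matrix", list[str], pd.DataFrame]:  # noqa: F821
    """Read a MatrixMarket genes x cells matrix with its gene/cell TSVs."""
    import scipy.io
    import scipy.sparse

    matrix = scipy.sparse.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t")["gene"].tolist()
    cells = pd.read_csv(cells_path, sep="\t")
    return matrix, genes, cells
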