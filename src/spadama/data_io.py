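"""Expression-matrix I/O and reference preprocessing.

Reads and writes the formats single-cell practitioners exchange (AnnData
h5ad, observation-by-gene CSV, MatrixMarket triplets), selects per-type
marker genes from a labelled scRNA-seq reference with a one-vs-rest
Wilcoxon rank-sum test, restricts spatial and reference matrices to a
shared marker panel, and applies library-size normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input matrix violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """Observations x genes nonnegative expression matrix.

    ``obs_kind`` records whether rows are single cells (a reference) or
    spatial spots; the matrix values may be raw counts or normalized
    expression depending on pipeline stage.
    """

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    obs_kind: Literal["cells", "spots"] = "spots"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        validate_matrix(self.values, self.obs_ids, self.gene_ids)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def validate_matrix(values: np.ndarray, obs_ids: list[str], gene_ids: list[str]) -> None:
    if values.ndim != 2:
        raise ValidationError(f"expression matrix must be 2-D, got shape {values.shape}")
    if values.shape != (len(obs_ids), len(gene_ids)):
        raise ValidationError(
            f"matrix shape {values.shape} does not match "
            f"{len(obs_ids)} observations x {len(gene_ids)} genes"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("gene identifiers are not unique")
    if len(set(obs_ids)) != len(obs_ids):
        raise ValidationError("observation identifiers are not unique")
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite value at observation {obs_ids[i]!r}, gene {gene_ids[j]!r}"
        )
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative value {values[i, j]} at observation {obs_ids[i]!r}, "
            f"gene {gene_ids[j]!r}"
        )


@dataclass
class CellTypeLabels:
    """Per-cell categorical cell-type assignment over K >= 2 named types."""

    labels: list[str]
    type_names: list[str]

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        self.type_names = [str(x) for x in self.type_names]
        if len(self.type_names) < 2:
            raise ValidationError("need at least two cell types")
        if len(set(self.type_names)) != len(self.type_names):
            raise ValidationError("cell-type names are not unique")
        unknown = set(self.labels) - set(self.type_names)
        if unknown:
            raise ValidationError(f"labels not in type_names: {sorted(unknown)}")

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def indices(self) -> np.ndarray:
        lut = {t: k for k, t in enumerate(self.type_names)}
        return np.array([lut[x] for x in self.labels], dtype=np.int64)


@dataclass
class MarkerGeneSet:
    """Top differential genes per cell type plus their ordered union."""

    per_type: dict[str, list[str]]
    union: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.union:
            seen: set[str] = set()
            union: list[str] = []
            for genes in self.per_type.values():
                for g in genes:
                    if g not in seen:
                        seen.add(g)
                        union.append(g)
            self.union = union


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path,
    format: Literal["h5ad", "csv", "mtx"] | None = None,
    obs_kind: Literal["cells", "spots"] = "spots",
) -> ExpressionMatrix:
    """Read an observations x genes matrix from h5ad, CSV or MatrixMarket.

    CSV is expected with observation ids in the first column and a header
    row of gene symbols.  MTX expects companion ``genes.tsv`` and
    ``barcodes.tsv`` files next to the matrix; a genes x obs matrix is
    transposed to the obs x genes orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".h5ad": "h5ad", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix, "csv")
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        values = adata.X.toarray() if scipy.sparse.issparse(adata.X) else np.asarray(adata.X)
        return ExpressionMatrix(values, list(adata.obs_names), list(adata.var_names), obs_kind)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=np.float64), list(df.index), list(df.columns), obs_kind
        )
    if format == "mtx":
        genes_path = path.with_name("genes.tsv")
        obs_path = path.with_name("barcodes.tsv")
        for p in (genes_path, obs_path):
            if not p.exists():
                raise FileNotFoundError(f"companion file missing for mtx input: {p}")
        mat = np.asarray(scipy.io.mmread(path).todense(), dtype=np.float64)
        genes = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).tolist()
        obs = pd.read_csv(obs_path, header=None, sep="\t")[0].astype(str).tolist()
        if mat.shape == (len(genes), len(obs)) and mat.shape != (len(obs), len(genes)):
            mat = mat.T
        return ExpressionMatrix(mat, obs, genes, obs_kind)
    raise ValueError(f"unknown format {format!r}")


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    """Write to h5ad or CSV, chosen by file extension."""
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = ad.AnnData(
            X=x.values,
            obs=pd.DataFrame(index=pd.Index(x.obs_ids, name="obs_id")),
            var=pd.DataFrame(index=pd.Index(x.gene_ids, name="gene_id")),
        )
        adata.write_h5ad(path)
    else:
        pd.DataFrame(x.values, index=x.obs_ids, columns=x.gene_ids).to_csv(path)


def read_labels(path: str | Path, column: str | None = None) -> CellTypeLabels:
    """Read per-cell labels from a one-column (or named-column) CSV."""
    df = pd.read_csv(path, index_col=0)
    col = column if column is not None else df.columns[0]
    labels = df[col].astype(str).tolist()
    return CellTypeLabels(labels, sorted(set(labels)))


# ---------------------------------------------------------------------------
# preprocessing


def select_marker_genes(
    ref: ExpressionMatrix,
    labels: CellTypeLabels,
    n_top: int = 200,
) -> MarkerGeneSet:
    """Rank genes per cell type by a one-vs-rest Wilcoxon rank-sum test.

    The reference is library-size normalized and log1p-transformed before
    testing.  For each type, genes are ordered by descending test z-score
    with lexicographic gene-id tie-breaking, and the top ``n_top`` kept.
    The union preserves first-occurrence order across types in
    ``labels.type_names`` order.
    """
    if ref.obs_kind != "cells":
        raise ValidationError("marker selection expects a cells x genes reference")
    counts = pd.Series(labels.labels).value_counts()
    for t in labels.type_names:
        if counts.get(t, 0) < 2:
            raise ValidationError(f"cell type {t!r} has fewer than 2 cells")
    adata = ad.AnnData(
        X=ref.values.copy(),
        obs=pd.DataFrame(
            {"cell_type": pd.Categorical(labels.labels, categories=labels.type_names)},
            index=pd.Index(ref.obs_ids),
        ),
        var=pd.DataFrame(index=pd.Index(ref.gene_ids)),
    )
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.rank_genes_groups(
            adata, "cell_type", method="wilcoxon", n_genes=ref.n_genes, tie_correct=True
        )
    per_type: dict[str, list[str]] = {}
    for t in labels.type_names:
        names = np.asarray(adata.uns["rank_genes_groups"]["names"][t])
        scores = np.asarray(adata.uns["rank_genes_groups"]["scores"][t], dtype=float)
        order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
        per_type[t] = [str(names[i]) for i in order[:n_top]]
    return MarkerGeneSet(per_type=per_type)


def intersect_and_subset(
    st: ExpressionMatrix,
    ref: ExpressionMatrix,
    markers: MarkerGeneSet,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to marker-union genes present in both.

    The shared gene order is the marker-union order filtered to the
    intersection; this order is canonical for the rest of the pipeline.
    """
    st_genes = set(st.gene_ids)
    ref_genes = set(ref.gene_ids)
    shared = [g for g in markers.union if g in st_genes and g in ref_genes]
    if not shared:
        raise ValidationError("no genes shared between ST, reference and marker union")
    st_pos = {g: i for i, g in enumerate(st.gene_ids)}
    ref_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    st_idx = [st_pos[g] for g in shared]
    ref_idx = [ref_pos[g] for g in shared]
    st_out = ExpressionMatrix(st.values[:, st_idx], st.obs_ids, shared, st.obs_kind)
    ref_out = ExpressionMatrix(ref.values[:, ref_idx], ref.obs_ids, shared, ref.obs_kind)
    return st_out, ref_out


def normalize(x: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each row to ``target_sum`` total and log1p-transform.

    All-zero rows are left as zeros.  Applied identically to real ST and
    pseudo-ST so both domains share the same expression scale.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    sums = x.values.sum(axis=1, keepdims=True)
    if not (sums > 0).any():
        raise ValidationError("normalize requires at least one nonzero row")
    scale = np.divide(target_sum, sums, out=np.zeros_like(sums), where=sums > 0)
    return ExpressionMatrix(np.log1p(x.values * scale), x.obs_ids, x.gene_ids, x.obs_kind)
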