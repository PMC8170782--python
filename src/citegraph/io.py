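"""Loading, quality-filtering and splitting of paired RNA/protein matrices
and prior-knowledge edge tables.

Dense tables are CSV/TSV with the first column holding cell barcodes and the
header row holding gene identifiers.  Sparse input is a MatrixMarket ``.mtx``
with CellRanger-style ``barcodes.tsv`` / ``features.tsv`` sidecars next to
it; orientation is auto-detected from the sidecar lengths and an explicit
``orientation`` argument is required when they do not disambiguate (square
matrices).  Prior features are a TSV edge list with columns ``protein_a``,
``protein_b`` and one numeric column per evidence channel (STRING
detailed-scores dialect; a column on the 0–1000 integer scale is divided by
1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ExpressionMatrix",
    "ProteinMatrix",
    "QCReport",
    "CellSplit",
    "PriorFeatureSet",
    "load_expression",
    "load_protein",
    "qc_filter",
    "split_cells",
    "load_prior_features",
    "mito_genes_by_prefix",
    "write_expression_csv",
    "write_expression_mtx",
    "write_protein_csv",
    "write_priors_tsv",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} identifiers are not unique")
    return ids


@dataclass
class ExpressionMatrix:
    """Cells x genes continuous RNA expression with identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ProteinMatrix:
    """Cells x proteins abundances on a log-like scale (negatives allowed)."""

    values: np.ndarray
    protein_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.protein_ids = _check_unique(self.protein_ids, "protein")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.cell_ids), len(self.protein_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.protein_ids)} proteins"
            )
        if len(self.protein_ids) < 2:
            raise ValueError("need at least 2 proteins")
        if not np.isfinite(self.values).all():
            raise ValueError("protein matrix contains non-finite entries")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


@dataclass
class QCReport:
    n_cells_in: int
    n_removed_mito: int
    n_removed_low_genes: int
    n_cells_out: int

    def __post_init__(self):
        counts = (
            self.n_cells_in,
            self.n_removed_mito,
            self.n_removed_low_genes,
            self.n_cells_out,
        )
        if any(c < 0 for c in counts):
            raise ValueError("QC counts must be non-negative")
        if self.n_cells_out != (
            self.n_cells_in - self.n_removed_mito - self.n_removed_low_genes
        ):
            raise ValueError("QC counts are inconsistent")


@dataclass
class CellSplit:
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test cells overlap")


@dataclass
class PriorFeatureSet:
    """M named symmetric N x N non-negative score matrices over one panel."""

    feature_names: list[str]
    matrices: np.ndarray
    protein_ids: list[str]

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        self.protein_ids = _check_unique(self.protein_ids, "protein")
        n = len(self.protein_ids)
        if self.matrices.shape != (len(self.feature_names), n, n):
            raise ValueError(
                f"expected {len(self.feature_names)} matrices of {n} x {n}, "
                f"got {self.matrices.shape}"
            )
        if not np.isfinite(self.matrices).all():
            raise ValueError("prior scores must be finite")
        if (self.matrices < 0).any():
            raise ValueError("prior scores must be non-negative")
        if not np.allclose(self.matrices, np.swapaxes(self.matrices, 1, 2)):
            raise ValueError("prior matrices must be symmetric")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def load_expression(
    path,
    format: str | None = None,
    orientation: str | None = None,
) -> ExpressionMatrix:
    """Read an RNA matrix from a dense table or MatrixMarket triplet layout.

    ``format`` is ``"dense-table"`` or ``"matrix-market"`` (inferred from the
    suffix when omitted).  For MTX input, ``barcodes.tsv`` and
    ``features.tsv`` must sit next to the matrix file; when their lengths do
    not determine the orientation, pass ``orientation`` as ``"cells-rows"``
    or ``"genes-rows"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "matrix-market" if path.suffix == ".mtx" else "dense-table"

    if format == "dense-table":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed table {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64)
        return ExpressionMatrix(values, list(df.columns), list(df.index))

    if format != "matrix-market":
        raise ValueError(f"unknown format {format!r}")

    barcodes_path = path.parent / "barcodes.tsv"
    features_path = path.parent / "features.tsv"
    if not features_path.exists():
        features_path = path.parent / "genes.tsv"
    for p in (barcodes_path, features_path):
        if not p.exists():
            raise FileNotFoundError(f"missing sidecar file {p}")
    barcodes = _read_id_file(barcodes_path)
    features = _read_id_file(features_path)
    try:
        raw = mmread(path)
        mat = np.asarray(
            raw.todense() if hasattr(raw, "todense") else raw, dtype=np.float64
        )
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc

    nb, nf = len(barcodes), len(features)
    if mat.shape == (nb, nf) and mat.shape == (nf, nb) and orientation is None:
        raise ValueError(
            "sidecars do not disambiguate matrix orientation; pass "
            "orientation='cells-rows' or 'genes-rows'"
        )
    if orientation == "genes-rows" or (orientation is None and mat.shape == (nf, nb)):
        mat = mat.T
    elif orientation not in (None, "cells-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if mat.shape != (nb, nf):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {nb} barcodes x "
            f"{nf} features"
        )
    return ExpressionMatrix(mat, features, barcodes)


def load_protein(path) -> ProteinMatrix:
    """Read a dense cells x proteins table (first column = cell barcode)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ProteinMatrix(df.to_numpy(dtype=np.float64), list(df.columns), list(df.index))


# ---------------------------------------------------------------------------
# quality control and splitting
# ---------------------------------------------------------------------------


def mito_genes_by_prefix(gene_ids: Iterable[str], prefix: str = "MT-") -> set[str]:
    """Convenience: gene identifiers starting with the mitochondrial prefix."""
    return {g for g in gene_ids if str(g).upper().startswith(prefix.upper())}


def qc_filter(
    expr: ExpressionMatrix,
    mito_gene_ids: Iterable[str],
    max_mito_rate: float = 0.20,
    min_genes: int = 250,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells.

    First, cells whose mitochondrial read fraction is at least
    ``max_mito_rate`` are removed; then, of the survivors, cells with at most
    ``min_genes`` genes expressed (strictly positive value) are removed.
    Both thresholds are inclusive.  The report attributes removals in that
    order; the operation is idempotent.
    """
    mito = set(map(str, mito_gene_ids))
    unknown = mito - set(expr.gene_ids)
    if unknown:
        raise ValueError(f"mitochondrial genes not in the matrix: {sorted(unknown)}")
    mito_idx = [i for i, g in enumerate(expr.gene_ids) if g in mito]

    totals = expr.values.sum(axis=1)
    mito_sum = expr.values[:, mito_idx].sum(axis=1) if mito_idx else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_rate = np.where(totals > 0, mito_sum / totals, 0.0)
    keep_mito = mito_rate < max_mito_rate

    n_genes_expressed = (expr.values > 0).sum(axis=1)
    keep_genes = n_genes_expressed > min_genes

    n_removed_mito = int((~keep_mito).sum())
    n_removed_low = int((keep_mito & ~keep_genes).sum())
    keep = keep_mito & keep_genes
    if not keep.any():
        raise ValueError("quality filtering removed every cell")

    filtered = ExpressionMatrix(
        expr.values[keep],
        list(expr.gene_ids),
        [c for c, k in zip(expr.cell_ids, keep) if k],
    )
    report = QCReport(
        n_cells_in=expr.n_cells,
        n_removed_mito=n_removed_mito,
        n_removed_low_genes=n_removed_low,
        n_cells_out=int(keep.sum()),
    )
    return filtered, report


def split_cells(
    cell_ids: Sequence[str], train_fraction: float = 0.7, seed: int = 0
) -> CellSplit:
    """Random disjoint train/test partition; train size = floor(fraction * C)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    cell_ids = [str(c) for c in cell_ids]
    if len(cell_ids) < 2:
        raise ValueError("need at least 2 cells to split")
    n_train = int(np.floor(train_fraction * len(cell_ids)))
    order = np.random.default_rng(seed).permutation(len(cell_ids))
    train = [cell_ids[i] for i in sorted(order[:n_train])]
    test = [cell_ids[i] for i in sorted(order[n_train:])]
    return CellSplit(train_ids=train, test_ids=test, seed=seed)


# ---------------------------------------------------------------------------
# prior-knowledge edge tables
# ---------------------------------------------------------------------------


def load_prior_features(
    path,
    protein_ids: Sequence[str],
    feature_columns: Sequence[str] | None = None,
) -> PriorFeatureSet:
    """Build M symmetric N x N score matrices from a STRING-style edge list.

    Pairs absent from the table (and proteins absent entirely) score 0.
    Scores are normalized per column to 0–1 by dividing by 1000 when any
    value in the column exceeds 1.  Duplicate pair entries keep the maximum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_a", "protein_b"):
        if col not in df.columns:
            raise ValueError(f"edge table must contain a {col!r} column")
    available = [c for c in df.columns if c not in ("protein_a", "protein_b")]
    if feature_columns is None:
        feature_columns = available
    unknown = [c for c in feature_columns if c not in available]
    if unknown:
        raise ValueError(
            f"unknown feature column(s) {unknown}; available: {available}"
        )

    protein_ids = _check_unique(protein_ids, "protein")
    index = {p: i for i, p in enumerate(protein_ids)}
    n, m = len(protein_ids), len(feature_columns)
    matrices = np.zeros((m, n, n))
    for k, col in enumerate(feature_columns):
        scores = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=np.float64)
        if np.nanmax(scores, initial=0.0) > 1:
            scores = scores / 1000.0
        for a, b, s in zip(df["protein_a"], df["protein_b"], scores):
            ia, ib = index.get(str(a)), index.get(str(b))
            if ia is None or ib is None or not np.isfinite(s):
                continue
            matrices[k, ia, ib] = max(matrices[k, ia, ib], s)
            matrices[k, ib, ia] = matrices[k, ia, ib]
    return PriorFeatureSet(list(feature_columns), matrices, protein_ids)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def write_expression_csv(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids).to_csv(path)


def write_expression_mtx(expr: ExpressionMatrix, directory) -> Path:
    """Write CellRanger-style triplet layout (genes x cells) and return the mtx path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx_path = directory / "matrix.mtx"
    mmwrite(mtx_path, coo_matrix(expr.values.T))
    (directory / "barcodes.tsv").write_text("\n".join(expr.cell_ids) + "\n")
    (directory / "features.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    return mtx_path


def write_protein_csv(prot: ProteinMatrix, path) -> None:
    pd.DataFrame(prot.values, index=prot.cell_ids, columns=prot.protein_ids).to_csv(path)


def write_priors_tsv(priors: PriorFeatureSet, path) -> None:
    """Write the upper triangle of every channel as one edge-list TSV."""
    rows = []
    n = len(priors.protein_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(priors.matrices[:, i, j] != 0):
                rows.append(
                    [priors.protein_ids[i], priors.protein_ids[j]]
                    + [priors.matrices[k, i, j] for k in range(priors.n_features)]
                )
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b"] + priors.feature_names)
    df.to_csv(path, sep="\t", index=False)
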