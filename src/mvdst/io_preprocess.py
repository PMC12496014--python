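"""Reading SRT data into the dataset container and the preprocessing chain.

Supports the standard Space Ranger on-disk layout (Matrix Market counts +
barcode/feature tables + tissue positions, gzipped variants accepted) as
well as generic spots-by-genes CSV/TSV matrices with a matching coordinate
table.  The in-memory convention is spots-as-rows throughout; Matrix Market
orientation is auto-detected by matching a dimension to the barcode count.

Preprocessing follows the usual chain: off-tissue spot removal (at load
time), gene filtering by detection count, library-size normalization with
log1p, and an optional neighbourhood-mean augmentation that concatenates
each spot's own profile with the mean profile of its spatial neighbours.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .exceptions import ConsistencyError, InputError, ParameterError, StateError

__all__ = [
    "SRTDataset",
    "load_visium",
    "write_visium",
    "load_tables",
    "write_tables",
    "filter_genes",
    "normalize_log",
    "banksy_augment",
]


@dataclass
class SRTDataset:
    """Container for one spatially resolved transcriptomics sample.

    Attributes
    ----------
    expression
        Spots x genes matrix. Raw non-negative counts on load; real-valued
        after :func:`normalize_log`.
    coords
        Spots x 2 coordinates in platform units (x, y).
    spot_ids, gene_ids
        Unique row/column identifiers.
    morphology
        Optional spots x d_m real-valued feature matrix.
    truth_labels
        Optional per-spot integer ground-truth labels (simulations,
        annotated references).
    normalized
        Whether :func:`normalize_log` has been applied.
    """

    expression: np.ndarray | sp.spmatrix
    coords: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    morphology: np.ndarray | None = None
    truth_labels: np.ndarray | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.expression.shape
        if self.coords.shape != (n, 2):
            raise ConsistencyError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n:
            raise ConsistencyError(f"{len(self.spot_ids)} spot ids for {n} spots")
        if len(self.gene_ids) != g:
            raise ConsistencyError(f"{len(self.gene_ids)} gene ids for {g} genes")
        if len(set(self.spot_ids)) != n:
            raise ConsistencyError("duplicate spot ids")
        if len(set(self.gene_ids)) != g:
            raise ConsistencyError("duplicate gene ids")
        if self.morphology is not None:
            self.morphology = np.asarray(self.morphology, dtype=float)
            if self.morphology.shape[0] != n:
                raise ConsistencyError(
                    f"morphology has {self.morphology.shape[0]} rows for {n} spots"
                )
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if self.truth_labels.shape[0] != n:
                raise ConsistencyError("truth_labels length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coords contain non-finite values")
        if not self.normalized:
            mins = self.expression.min() if sp.issparse(self.expression) else self.expression.min(initial=0)
            if mins < 0:
                raise InputError("raw counts must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def dense_expression(self) -> np.ndarray:
        """Expression as a dense float array (copy only when sparse)."""
        if sp.issparse(self.expression):
            return np.asarray(self.expression.todense(), dtype=float)
        return np.asarray(self.expression, dtype=float)


# ---------------------------------------------------------------------------
# Space Ranger layout
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _find_file(root: Path, names: Sequence[str]) -> Path | None:
    for name in names:
        for cand in (root / name, root / "spatial" / name,
                     root / "filtered_feature_bc_matrix" / name,
                     root / "raw_feature_bc_matrix" / name):
            if cand.is_file():
                return cand
    return None

def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")

def _read_id_table(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_positions(path: Path) -> pd.DataFrame:
    # Space Ranger v1 files (tissue_positions_list.csv) have no header,
    # v2 files (tissue_positions.csv) do; sniff the first line.
    with _open_maybe_gz(path) as fh:
        first = fh.readline()
    header = 0 if "barcode" in first else None
    df = pd.read_csv(path, header=header)
    if header is None:
        df.columns = _POSITION_COLUMNS[: df.shape[1]]
    missing = {"barcode", "in_tissue"} - set(df.columns)
    if missing:
        raise InputError(f"position table {path} lacks columns {sorted(missing)}")
    return df.set_index("barcode")


def load_visium(path: str | Path) -> SRTDataset:
    """Read a Space Ranger style directory into an :class:`SRTDataset`.

    Off-tissue spots (``in_tissue == 0``) are dropped.  Counts are returned
    spots x genes regardless of the on-disk orientation.
    """
    root = Path(path)
    if not root.is_dir():
        raise InputError(f"not a directory: {root}")
    mtx = _find_file(root, ["matrix.mtx", "matrix.mtx.gz"])
    if mtx is None:
        raise InputError(f"missing matrix.mtx[.gz] under {root}")
    bc = _find_file(root, ["barcodes.tsv", "barcodes.tsv.gz"])
    if bc is None:
        raise InputError(f"missing barcodes.tsv[.gz] under {root}")
    ft = _find_file(root, ["features.tsv", "features.tsv.gz",
                           "genes.tsv", "genes.tsv.gz"])
    if ft is None:
        raise InputError(f"missing features.tsv[.gz] under {root}")
    pos_path = _find_file(root, ["tissue_positions.csv", "tissue_positions.csv.gz",
                                 "tissue_positions_list.csv",
                                 "tissue_positions_list.csv.gz"])
    if pos_path is None:
        raise InputError(f"missing tissue position table under {root}")

    with _open_maybe_gz(mtx) as fh:
        counts = sp.csr_matrix(mmread(fh))
    barcodes = _read_id_table(bc)
    genes = _read_id_table(ft)

    # Orientation: Space Ranger writes genes x barcodes; detect by matching
    # a dimension to the barcode count.
    if counts.shape == (len(genes), len(barcodes)):
        counts = counts.T.tocsr()
    elif counts.shape != (len(barcodes), len(genes)):
        raise ConsistencyError(
            f"matrix shape {counts.shape} matches neither "
            f"(barcodes={len(barcodes)}, genes={len(genes)}) orientation"
        )

    pos = _read_positions(pos_path)
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} barcodes absent from position table "
            f"(first: {missing[0]})"
        )
    pos = pos.loc[barcodes]
    keep = pos["in_tissue"].to_numpy().astype(int) == 1
    coords = pos[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(dtype=float)

    return SRTDataset(
        expression=counts[keep],
        coords=coords[keep],
        spot_ids=[b for b, k in zip(barcodes, keep) if k],
        gene_ids=genes,
    )


def write_visium(ds: SRTDataset, path: str | Path) -> None:
    """Write the container in Space Ranger v2 layout (uncompressed)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "spatial").mkdir(exist_ok=True)
    counts = sp.coo_matrix(ds.expression).T  # genes x barcodes on disk
    with open(root / "matrix.mtx", "wb") as fh:
        mmwrite(fh, counts)
    (root / "barcodes.tsv").write_text("".join(f"{b}\n" for b in ds.spot_ids))
    (root / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in ds.gene_ids)
    )
    pos = pd.DataFrame(
        {
            "barcode": ds.spot_ids,
            "in_tissue": 1,
            "array_row": 0,
            "array_col": 0,
            "pxl_row_in_fullres": ds.coords[:, 1],
            "pxl_col_in_fullres": ds.coords[:, 0],
        }
    )
    pos.to_csv(root / "spatial" / "tissue_positions.csv", index=False)


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"missing file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ConsistencyError(f"duplicate id {dup!r} in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise InputError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    return df


def load_tables(
    expr_path: str | Path,
    coords_path: str | Path,
    morph_path: str | Path | None = None,
    normalized: bool = False,
) -> SRTDataset:
    """Read a spots x genes expression table plus a coordinate table.

    Rows are aligned by spot id in the expression table's order; coordinate
    rows not referenced by the expression table are ignored.  Pass
    ``normalized=True`` when the table holds already-normalized (possibly
    negative) expression values rather than raw counts.
    """
    expr = _read_table(expr_path)
    coords = _read_table(coords_path)
    if coords.shape[1] < 2:
        raise InputError(f"coords table {coords_path} needs 2 numeric columns")
    missing = expr.index.difference(coords.index)
    if len(missing):
        raise ConsistencyError(
            f"spot {missing[0]!r} has expression but no coordinates"
        )
    coords = coords.loc[expr.index]
    morphology = None
    if morph_path is not None:
        morph = _read_table(morph_path)
        missing = expr.index.difference(morph.index)
        if len(missing):
            raise ConsistencyError(
                f"spot {missing[0]!r} has expression but no morphology row"
            )
        morphology = morph.loc[expr.index].to_numpy(dtype=float)
    return SRTDataset(
        expression=expr.to_numpy(dtype=float),
        coords=coords.iloc[:, :2].to_numpy(dtype=float),
        spot_ids=[str(s) for s in expr.index],
        gene_ids=[str(g) for g in expr.columns],
        morphology=morphology,
        normalized=normalized,
    )


def write_tables(
    ds: SRTDataset,
    expr_path: str | Path,
    coords_path: str | Path,
    morph_path: str | Path | None = None,
) -> None:
    """Write the container to CSV/TSV tables readable by :func:`load_tables`."""
    def _sep(p: str | Path) -> str:
        return "\t" if Path(p).suffix.lower() in {".tsv", ".txt"} else ","

    pd.DataFrame(
        ds.dense_expression(), index=ds.spot_ids, columns=ds.gene_ids
    ).to_csv(expr_path, sep=_sep(expr_path))
    pd.DataFrame(
        ds.coords, index=ds.spot_ids, columns=["x", "y"]
    ).to_csv(coords_path, sep=_sep(coords_path))
    if morph_path is not None:
        if ds.morphology is None:
            raise StateError("dataset has no morphology to write")
        pd.DataFrame(
            ds.morphology,
            index=ds.spot_ids,
            columns=[f"m{j}" for j in range(ds.morphology.shape[1])],
        ).to_csv(morph_path, sep=_sep(morph_path))


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def filter_genes(ds: SRTDataset, min_cells: int = 10) -> SRTDataset:
    """Drop genes detected (nonzero) in fewer than ``min_cells`` spots."""
    if min_cells < 0:
        raise ParameterError(f"min_cells must be >= 0, got {min_cells}")
    if ds.normalized:
        raise StateError("filter_genes expects raw counts (normalized=False)")
    X = ds.expression
    if sp.issparse(X):
        detected = np.asarray((X != 0).sum(axis=0)).ravel()
    else:
        detected = np.count_nonzero(X, axis=0)
    keep = detected >= min_cells
    if not keep.any():
        warnings.warn("all genes fall below the detection threshold", stacklevel=2)
    return replace(
        ds,
        expression=X[:, keep],
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
    )


def normalize_log(ds: SRTDataset, target_sum: float = 1e4) -> SRTDataset:
    """Library-size normalize each spot to ``target_sum`` then log1p."""
    if ds.normalized:
        raise StateError("dataset is already normalized")
    if target_sum <= 0:
        raise ParameterError(f"target_sum must be positive, got {target_sum}")
    X = ds.dense_expression()
    sums = X.sum(axis=1)
    nonempty = sums > 0
    if not nonempty.all():
        n_drop = int((~nonempty).sum())
        warnings.warn(f"dropping {n_drop} all-zero spot(s) before normalization",
                      stacklevel=2)
        X = X[nonempty]
        sums = sums[nonempty]
    scaled = X * (target_sum / sums)[:, None]
    out = np.log1p(scaled)
    return replace(
        ds,
        expression=out,
        coords=ds.coords[nonempty],
        spot_ids=[s for s, k in zip(ds.spot_ids, nonempty) if k],
        morphology=None if ds.morphology is None else ds.morphology[nonempty],
        truth_labels=None if ds.truth_labels is None else ds.truth_labels[nonempty],
        normalized=True,
    )


def banksy_augment(ds: SRTDataset, lam: float = 0.2, k: int = 6) -> np.ndarray:
    """Concatenate own expression with the spatial-neighbourhood mean.

    Returns ``[sqrt(1 - lam) * X, sqrt(lam) * N(X)]`` where ``N(X)`` is the
    mean expression over each spot's ``k`` nearest spatial neighbours (self
    excluded, ties broken by lower spot index).  Output has twice the gene
    count.
    """
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lam must lie in [0, 1], got {lam}")
    if not ds.normalized:
        raise StateError("banksy_augment expects a normalized dataset")
    if k >= ds.n_spots:
        raise ParameterError(f"k={k} must be < number of spots ({ds.n_spots})")
    from .multiview import knn_indices  # local import avoids a cycle

    X = ds.dense_expression()
    nbrs = knn_indices(ds.coords, k, metric="euclidean")
    neighbour_mean = X[nbrs].mean(axis=1)
    return np.hstack(
        [np.sqrt(1.0 - lam) * X, np.sqrt(lam) * neighbour_mean]
    )
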