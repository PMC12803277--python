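"""Readers and writers for the plain-text formats the pipeline touches.

All tables are UTF-8 CSV/TSV with a header row and "." decimal separator;
coordinates are micrometres in a continuous 2D slide frame.  The sparse
cell-by-gene matrix is stored as a MatrixMarket triplet (1-based indices)
next to a feature list and a cell-id list, the layout single-cell tooling
expects.  Unassigned transcripts carry the literal sentinel ``UNASSIGNED``
in their ``cell_id`` column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import shapely

UNASSIGNED = "UNASSIGNED"

#: Mandatory columns of a transcript table, one row per decoded transcript.
TRANSCRIPT_COLUMNS = (
    "transcript_id",
    "gene",
    "x",
    "y",
    "qv",
    "overlaps_nucleus",
    "cell_id",
)

_MASK_COLUMNS = ("cell_id", "sample_id", "ring", "vertex_index", "x", "y")


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an invalid layout."""


class MalformedPolygonError(ValueError):
    """A polygon ring is degenerate: <3 distinct vertices, self-intersecting
    or zero area."""


@dataclass(frozen=True)
class PanelDefinition:
    """A probe panel: a name ("V1", "Prime", ...) and its unique gene set."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise SchemaError(f"panel {self.name!r} has duplicate genes: {dupes[:5]}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_set

    @property
    def gene_set(self) -> frozenset[str]:
        # cached lazily; frozen dataclass so stash via object.__setattr__
        cached = self.__dict__.get("_gene_set")
        if cached is None:
            cached = frozenset(self.genes)
            object.__setattr__(self, "_gene_set", cached)
        return cached

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class LandmarkSet:
    """Paired anchor points: ``moving`` in the frame to be transformed,
    ``fixed`` in the target frame.  Shapes (n, 2), micrometres."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=float).reshape(-1, 2)
        self.fixed = np.asarray(self.fixed, dtype=float).reshape(-1, 2)
        if self.moving.shape != self.fixed.shape:
            raise SchemaError("moving and fixed landmark arrays differ in shape")

    def __len__(self) -> int:
        return len(self.moving)


@dataclass
class PolygonMask:
    """A cell's boundary polygon and (optionally) its nucleus polygon.

    Vertices are ordered (n, 2) arrays in µm; rings are simple and have
    positive area, with the nucleus no larger than the cell.
    """

    cell_id: str
    boundary: np.ndarray
    nucleus: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.boundary = _validate_ring(self.cell_id, "cell", self.boundary)
        if self.nucleus is not None:
            self.nucleus = _validate_ring(self.cell_id, "nucleus", self.nucleus)

    def boundary_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.boundary)

    def nucleus_polygon(self) -> shapely.Polygon | None:
        return None if self.nucleus is None else shapely.Polygon(self.nucleus)


def _validate_ring(cell_id: str, ring: str, vertices: np.ndarray) -> np.ndarray:
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2:
        raise MalformedPolygonError(f"{cell_id}/{ring}: vertices must be (n, 2)")
    # collapse consecutive duplicate vertices (incl. explicit ring closure)
    keep = np.ones(len(vertices), dtype=bool)
    keep[1:] = np.any(vertices[1:] != vertices[:-1], axis=1)
    vertices = vertices[keep]
    if len(vertices) > 1 and np.all(vertices[0] == vertices[-1]):
        vertices = vertices[:-1]
    if len(vertices) < 3:
        raise MalformedPolygonError(
            f"{cell_id}/{ring}: fewer than 3 distinct vertices"
        )
    poly = shapely.Polygon(vertices)
    if not poly.is_valid or poly.area <= 0:
        raise MalformedPolygonError(
            f"{cell_id}/{ring}: not a simple positive-area polygon"
        )
    return vertices


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def read_transcripts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a transcript table, validating the mandatory columns.

    Unknown columns are preserved untouched.  Raises :class:`SchemaError`
    naming the first missing mandatory column.
    """
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "gene": str, "transcript_id": str},
        float_precision="round_trip",
    )
    for col in TRANSCRIPT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"transcript table missing mandatory column {col!r}")
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    df["qv"] = df["qv"].astype(float)
    df["overlaps_nucleus"] = df["overlaps_nucleus"].astype(int)
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise SchemaError("transcript coordinates must be finite")
    if (df["qv"] < 0).any():
        raise SchemaError("qv must be nonnegative")
    return df


def write_transcripts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    for col in TRANSCRIPT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"transcript table missing mandatory column {col!r}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# masks (vertex-table layout)
# ---------------------------------------------------------------------------

def write_masks(masks: Sequence[PolygonMask], path: str | os.PathLike) -> None:
    """Write masks as a long vertex table: one row per vertex per ring."""
    rows: list[pd.DataFrame] = []
    for m in masks:
        rings = [("cell", m.boundary)]
        if m.nucleus is not None:
            rings.append(("nucleus", m.nucleus))
        for ring, verts in rings:
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": m.cell_id,
                        "sample_id": m.sample_id,
                        "ring": ring,
                        "vertex_index": np.arange(len(verts)),
                        "x": verts[:, 0],
                        "y": verts[:, 1],
                    }
                )
            )
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_MASK_COLUMNS)
    table.to_csv(path, index=False)


def read_masks(path: str | os.PathLike) -> list[PolygonMask]:
    df = pd.read_csv(
        path,
        dtype={"cell_id": str, "sample_id": str, "ring": str},
        float_precision="round_trip",
    )
    for col in _MASK_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mask table missing mandatory column {col!r}")
    masks: list[PolygonMask] = []
    if df.empty:
        return masks
    df = df.sort_values(["cell_id", "ring", "vertex_index"], kind="stable")
    for cell_id, group in df.groupby("cell_id", sort=True):
        rings = {ring: g[["x", "y"]].to_numpy(float) for ring, g in group.groupby("ring")}
        if "cell" not in rings:
            raise MalformedPolygonError(f"{cell_id}: no cell ring")
        sample = group["sample_id"].iloc[0]
        masks.append(
            PolygonMask(
                cell_id=str(cell_id),
                boundary=rings["cell"],
                nucleus=rings.get("nucleus"),
                sample_id="" if pd.isna(sample) else str(sample),
            )
        )
    return masks


# ---------------------------------------------------------------------------
# panels and landmarks
# ---------------------------------------------------------------------------

def write_panel(panel: PanelDefinition, path: str | os.PathLike) -> None:
    Path(path).write_text("\n".join(panel.genes) + ("\n" if panel.genes else ""))


def read_panel(path: str | os.PathLike, name: str) -> PanelDefinition:
    genes = tuple(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    return PanelDefinition(name=name, genes=genes)


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "x_moving": landmarks.moving[:, 0],
            "y_moving": landmarks.moving[:, 1],
            "x_fixed": landmarks.fixed[:, 0],
            "y_fixed": landmarks.fixed[:, 1],
        }
    ).to_csv(path, index=False)


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_moving", "y_moving", "x_fixed", "y_fixed"):
        if col not in df.columns:
            raise SchemaError(f"landmark table missing mandatory column {col!r}")
    return LandmarkSet(
        moving=df[["x_moving", "y_moving"]].to_numpy(float),
        fixed=df[["x_fixed", "y_fixed"]].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# cell-by-gene matrix
# ---------------------------------------------------------------------------

class CellByGeneMatrix:
    """Nonnegative integer counts over panel-tagged features.

    Rows are cells, columns are features named ``<gene>-<panel>``.  Per-cell
    QC metrics (``cell_area``, ``nucleus_area``, ``sample_id``) travel with
    the matrix in ``metrics`` (a DataFrame indexed by ``cell_id``).
    """

    def __init__(
        self,
        cell_ids: Sequence[str],
        feature_names: Sequence[str],
        counts: sp.spmatrix | np.ndarray,
        metrics: pd.DataFrame | None = None,
        name: str = "Combined",
    ) -> None:
        self.cell_ids = np.asarray(list(cell_ids), dtype=object)
        self.feature_names = np.asarray(list(feature_names), dtype=object)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("duplicate feature names in matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise SchemaError("duplicate cell ids in matrix")
        counts = sp.csr_matrix(counts, dtype=np.int64)
        counts.eliminate_zeros()
        if counts.shape != (len(self.cell_ids), len(self.feature_names)):
            raise SchemaError("counts shape does not match cell/feature lists")
        if counts.nnz and counts.data.min() < 0:
            raise SchemaError("counts must be nonnegative")
        self.counts = counts
        if metrics is not None:
            metrics = metrics.reindex(self.cell_ids)
        self.metrics = metrics
        self.name = name

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_counts(self) -> np.ndarray:
        """Row sums: total transcripts per cell on this view."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def n_genes(self) -> np.ndarray:
        """Number of features with a nonzero count per cell on this view."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def feature_panels(self) -> np.ndarray:
        return np.array([f.rsplit("-", 1)[1] for f in self.feature_names], dtype=object)

    def view(self, panel: str) -> "CellByGeneMatrix":
        """Restrict to one panel's features ("Combined" returns everything).

        The cell roster and metrics are shared across views so the three
        panel views stay comparable cell-for-cell.
        """
        if panel == "Combined":
            keep = np.ones(len(self.feature_names), dtype=bool)
        else:
            keep = self.feature_panels() == panel
        return CellByGeneMatrix(
            self.cell_ids,
            self.feature_names[keep],
            self.counts[:, np.flatnonzero(keep)],
            metrics=self.metrics,
            name=panel,
        )

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()


def write_matrix(matrix: CellByGeneMatrix, directory: str | os.PathLike) -> None:
    """Write a matrix directory: matrix.mtx (1-based triplets, genes as
    written by mmwrite), features.tsv, cells.tsv, cell_metadata.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        directory / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer"
    )
    (directory / "features.tsv").write_text(
        "".join(f"{f}\n" for f in matrix.feature_names)
    )
    (directory / "cells.tsv").write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    if matrix.metrics is not None:
        matrix.metrics.to_csv(directory / "cell_metadata.csv", index_label="cell_id")


def read_matrix(directory: str | os.PathLike, name: str = "Combined") -> CellByGeneMatrix:
    directory = Path(directory)
    counts = scipy.io.mmread(directory / "matrix.mtx")
    features = (directory / "features.tsv").read_text().splitlines()
    cells = (directory / "cells.tsv").read_text().splitlines()
    metrics = None
    meta = directory / "cell_metadata.csv"
    if meta.exists():
        metrics = pd.read_csv(
            meta, dtype={"cell_id": str, "sample_id": str}, float_precision="round_trip"
        )
        metrics = metrics.set_index("cell_id")
    return CellByGeneMatrix(cells, features, sp.csr_matrix(counts), metrics, name=name)
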