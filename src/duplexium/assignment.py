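"""Transcript quality filtering and re-assignment to segmentation masks.

Decoded transcripts are kept only if they pass the quality value cut
(QV >= 20 by default, the platform's usual confidence threshold), overlap
a segmented nucleus, and fall inside a cell mask.  Assignment is
boundary-inclusive point-in-polygon against the (transformed) masks; when
overlapping masks both contain a point the tie is broken deterministically
by smaller cell area, then lexicographic cell id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from .io_formats import UNASSIGNED, PolygonMask

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Transcript- and cell-level QC cuts.

    Transcript level: minimum decoding quality ``qv_min`` (kept when
    qv >= qv_min), nuclear-overlap requirement, and assignment requirement.
    Cell level: minimum transcripts and detected genes per cell, and
    segmentation-area ranges in µm².
    """

    qv_min: float = 20.0
    require_nucleus_overlap: bool = True
    require_assignment: bool = True
    min_counts: int = 50
    min_genes: int = 5
    cell_area_range: tuple[float, float] = (5.0, 140.0)
    nucleus_area_min: float = 3.0

    def __post_init__(self) -> None:
        if self.min_counts < 0 or self.min_genes < 0:
            raise ValueError("count thresholds must be nonnegative")
        lo, hi = self.cell_area_range
        if not lo < hi:
            raise ValueError("cell_area_range must satisfy low < high")


#: removal reasons, in the order they are attributed
REMOVAL_REASONS = ("qv", "nucleus", "unassigned")


def filter_transcripts(
    records: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the transcript-level filters; return kept rows and a tally.

    A removed transcript is attributed to the first failing check in the
    order qv -> nucleus -> unassigned; the tally values sum to the number
    removed.  Row order is preserved and the operation is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    fail_qv = records["qv"].to_numpy(float) < thresholds.qv_min
    fail_nuc = np.zeros(len(records), dtype=bool)
    if thresholds.require_nucleus_overlap:
        fail_nuc = records["overlaps_nucleus"].to_numpy(int) == 0
    fail_asn = np.zeros(len(records), dtype=bool)
    if thresholds.require_assignment:
        fail_asn = records["cell_id"].to_numpy(object) == UNASSIGNED
    reason = np.select(
        [fail_qv, ~fail_qv & fail_nuc, ~fail_qv & ~fail_nuc & fail_asn],
        ["qv", "nucleus", "unassigned"],
        default="",
    )
    kept = records.loc[reason == ""]
    tally = {r: int(np.sum(reason == r)) for r in REMOVAL_REASONS}
    return kept, tally


def assign_to_masks(
    points: np.ndarray, masks: Sequence[PolygonMask]
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each point to the mask containing it (boundary-inclusive).

    Returns ``(cell_ids, nucleus_flags)``: the containing cell's id or
    ``UNASSIGNED``, and 1 when the point also lies in that cell's nucleus
    ring.  Containment uses the even-odd rule including the boundary.
    Points claimed by several (overlapping) masks are resolved by smallest
    cell area, then lexicographic cell id; ties are logged.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    cell_ids = np.full(n, UNASSIGNED, dtype=object)
    nucleus_flags = np.zeros(n, dtype=int)
    if n == 0 or len(masks) == 0:
        return cell_ids, nucleus_flags

    polygons = np.array([m.boundary_polygon() for m in masks], dtype=object)
    areas = np.array([p.area for p in polygons])
    ids = np.array([m.cell_id for m in masks], dtype=object)
    # deterministic priority: smaller area first, then lexicographic id
    priority = np.lexsort((ids, areas))
    rank = np.empty(len(masks), dtype=int)
    rank[priority] = np.arange(len(masks))

    tree = STRtree(polygons)
    pts = shapely.points(points)
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    if len(pt_idx):
        n_multi = int(np.sum(np.bincount(pt_idx, minlength=n) > 1))
        if n_multi:
            logger.info("%d points fell inside more than one mask; tie-broken", n_multi)
        best_rank = np.full(n, len(masks), dtype=int)
        np.minimum.at(best_rank, pt_idx, rank[poly_idx])
        assigned = best_rank < len(masks)
        winner = priority[best_rank[assigned]]
        cell_ids[assigned] = ids[winner]
        # nucleus containment checked only against the winning cell
        nuc_polys = [masks[w].nucleus_polygon() for w in winner]
        has_nuc = np.array([p is not None for p in nuc_polys])
        if has_nuc.any():
            sel = np.flatnonzero(assigned)[has_nuc]
            nuc_arr = np.array([p for p in nuc_polys if p is not None], dtype=object)
            inside = shapely.intersects(nuc_arr, pts[sel])
            nucleus_flags[sel] = inside.astype(int)
    return cell_ids, nucleus_flags


def assign_transcripts(
    records: pd.DataFrame, masks: Sequence[PolygonMask]
) -> pd.DataFrame:
    """Return a copy of ``records`` with ``cell_id``/``overlaps_nucleus``
    (and ``sample_id``, from the assigned mask) recomputed from ``masks``."""
    out = records.copy()
    cell_ids, nuc = assign_to_masks(out[["x", "y"]].to_numpy(float), masks)
    out["cell_id"] = cell_ids
    out["overlaps_nucleus"] = nuc
    sample_of = {m.cell_id: m.sample_id for m in masks}
    out["sample_id"] = [sample_of.get(c, "") for c in cell_ids]
    return out


def compute_cell_metrics(masks: Sequence[PolygonMask]) -> pd.DataFrame:
    """Per-cell geometry: shoelace areas (µm²) and boundary centroid.

    ``nucleus_area`` is 0 for cells without a nucleus ring.  Degenerate
    polygons raise, naming the offending cell.
    """
    rows = []
    for m in masks:
        poly = m.boundary_polygon()
        if poly.area <= 0:
            raise ValueError(f"degenerate polygon for cell {m.cell_id!r}")
        nuc_area = 0.0
        if m.nucleus is not None:
            nuc_area = m.nucleus_polygon().area
        c = poly.centroid
        rows.append((m.cell_id, poly.area, nuc_area, c.x, c.y, m.sample_id))
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "cell_area", "nucleus_area", "centroid_x", "centroid_y", "sample_id"],
    )
    return df.set_index("cell_id")
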