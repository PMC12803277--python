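"""Cross-run cell matching, panel-tagged matrix assembly and cell QC.

Because the two decoding runs share one segmentation (the first run's
masks, transformed into the second run's frame), every cell has one id and
two transcript streams.  Features are tagged ``<gene>-<panel>`` so the two
panels' matrices concatenate without symbol collisions; a gene probed by
both panels yields two distinct features.  Cell-level QC applies four
inclusive thresholds (n_counts >= 50, n_genes >= 5, 5 <= cell_area <= 140,
nucleus_area >= 3 by default) per panel view, on a shared cell roster so
retention is comparable across views.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .assignment import QCThresholds
from .io_formats import UNASSIGNED, CellByGeneMatrix, PanelDefinition, PolygonMask


class IntegrityError(ValueError):
    """Inputs reference cells or genes unknown to the roster/panel."""


def tag_feature(gene: str, panel: PanelDefinition) -> str:
    """Panel-tagged feature name, e.g. ``("SFTPC", V1) -> "SFTPC-V1"``."""
    if gene not in panel:
        raise IntegrityError(f"gene {gene!r} is not on panel {panel.name!r}")
    return f"{gene}-{panel.name}"


def parse_feature(feature: str) -> tuple[str, str]:
    """Inverse of :func:`tag_feature`: ``"SFTPC-V1" -> ("SFTPC", "V1")``."""
    gene, sep, panel = feature.rpartition("-")
    if not sep or not gene or not panel:
        raise ValueError(f"feature {feature!r} is not panel-tagged")
    return gene, panel


def match_cells(
    run1_assignments: pd.DataFrame,
    run2_assignments: pd.DataFrame,
    masks: Sequence[PolygonMask],
) -> pd.DataFrame:
    """Unified per-cell table of transcript counts from both runs.

    One row per mask cell id (cells silent in one run get a zero), ordered
    by cell id; input row order is irrelevant.  Assignments referencing a
    cell id absent from the masks raise :class:`IntegrityError`.
    """
    roster = pd.Index(sorted(m.cell_id for m in masks), name="cell_id")
    out = pd.DataFrame(index=roster)
    for label, assignments in (("run1", run1_assignments), ("run2", run2_assignments)):
        ids = assignments["cell_id"]
        ids = ids[ids != UNASSIGNED]
        unknown = set(ids) - set(roster)
        if unknown:
            raise IntegrityError(
                f"{label} assignment references unknown cell ids: {sorted(unknown)[:5]}"
            )
        out[f"n_counts_{label}"] = ids.value_counts().reindex(roster, fill_value=0)
    return out


def build_matrix(
    transcripts_by_panel: Mapping[str, pd.DataFrame],
    panels: Mapping[str, PanelDefinition],
    cell_metrics: pd.DataFrame,
) -> CellByGeneMatrix:
    """Assemble the combined panel-tagged cell-by-gene matrix.

    ``transcripts_by_panel`` maps a panel name to that run's kept, assigned
    transcripts.  The cell roster is ``cell_metrics.index`` (every
    segmented cell, including transcript-free ones); features follow panel
    order then the panel's gene order.  A transcript whose gene is not on
    its declared panel raises :class:`IntegrityError`.
    """
    roster = pd.Index(cell_metrics.index, name="cell_id")
    if roster.has_duplicates:
        raise IntegrityError("duplicate cell ids in metrics roster")
    cell_pos = pd.Series(np.arange(len(roster)), index=roster)

    features: list[str] = []
    blocks: list[sp.csr_matrix] = []
    for name, panel in panels.items():
        panel_features = [f"{g}-{panel.name}" for g in panel.genes]
        features.extend(panel_features)
        df = transcripts_by_panel.get(name)
        gene_pos = pd.Series(np.arange(len(panel.genes)), index=pd.Index(panel.genes))
        if df is None or df.empty:
            blocks.append(sp.csr_matrix((len(roster), len(panel.genes)), dtype=np.int64))
            continue
        assigned = df[df["cell_id"] != UNASSIGNED]
        bad_genes = set(assigned["gene"]) - set(panel.genes)
        if bad_genes:
            raise IntegrityError(
                f"transcripts carry genes absent from panel {panel.name!r}: "
                f"{sorted(bad_genes)[:5]}"
            )
        bad_cells = set(assigned["cell_id"]) - set(roster)
        if bad_cells:
            raise IntegrityError(
                f"transcripts assigned to cells missing from roster: {sorted(bad_cells)[:5]}"
            )
        rows = cell_pos[assigned["cell_id"]].to_numpy()
        cols = gene_pos[assigned["gene"]].to_numpy()
        block = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)),
            shape=(len(roster), len(panel.genes)),
        ).tocsr()
        blocks.append(block)
    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((len(roster), 0))
    return CellByGeneMatrix(roster, features, counts, metrics=cell_metrics, name="Combined")


@dataclass
class RetentionSummary:
    """Cell retention under the four QC thresholds for one panel view."""

    panel: str
    total: int
    retained: int
    lost: int
    percent_retained: float
    per_sample: pd.DataFrame | None = None
    attrition: dict[str, int] | None = None

    @classmethod
    def from_counts(cls, panel: str, retained: int, lost: int) -> "RetentionSummary":
        total = retained + lost
        if total <= 0:
            raise ValueError("retention summary needs a positive cell total")
        return cls(
            panel=panel,
            total=total,
            retained=retained,
            lost=lost,
            percent_retained=100.0 * retained / total,
        )


def filter_cells(
    matrix: CellByGeneMatrix, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, np.ndarray, RetentionSummary]:
    """Retain cells passing ALL four thresholds on this view (inclusive).

    Returns (retained ids, lost ids, summary).  The summary's ``attrition``
    counts, per threshold, how many cells fail that condition (a cell can
    fail several), which identifies the dominant filter.  Missing metrics
    raise, naming a missing cell.
    """
    thresholds = thresholds or QCThresholds()
    if matrix.metrics is None:
        raise IntegrityError("matrix has no cell metrics; cannot filter")
    metrics = matrix.metrics
    for col in ("cell_area", "nucleus_area"):
        if col not in metrics.columns:
            raise IntegrityError(f"cell metrics missing column {col!r}")
        missing = metrics.index[metrics[col].isna()]
        if len(missing):
            raise IntegrityError(f"metric {col!r} missing for cell {missing[0]!r}")
    n_counts = matrix.n_counts
    n_genes = matrix.n_genes
    cell_area = metrics["cell_area"].to_numpy(float)
    nucleus_area = metrics["nucleus_area"].to_numpy(float)
    lo, hi = thresholds.cell_area_range
    fail = {
        "n_counts": n_counts < thresholds.min_counts,
        "n_genes": n_genes < thresholds.min_genes,
        "cell_area": (cell_area < lo) | (cell_area > hi),
        "nucleus_area": nucleus_area < thresholds.nucleus_area_min,
    }
    passing = ~np.logical_or.reduce(list(fail.values()))
    retained_ids = matrix.cell_ids[passing]
    lost_ids = matrix.cell_ids[~passing]
    per_sample = None
    if "sample_id" in metrics.columns:
        per_sample = (
            pd.DataFrame(
                {"sample_id": metrics["sample_id"].to_numpy(), "retained": passing}
            )
            .groupby("sample_id")
            .agg(total=("retained", "size"), retained=("retained", "sum"))
        )
        per_sample["lost"] = per_sample["total"] - per_sample["retained"]
        per_sample["percent_retained"] = np.where(
            per_sample["total"] > 0, 100.0 * per_sample["retained"] / per_sample["total"], np.nan
        )
    total = len(matrix.cell_ids)
    summary = RetentionSummary(
        panel=matrix.name,
        total=total,
        retained=int(passing.sum()),
        lost=int((~passing).sum()),
        percent_retained=100.0 * passing.sum() / total if total else float("nan"),
        per_sample=per_sample,
        attrition={k: int(v.sum()) for k, v in fail.items()},
    )
    return retained_ids, lost_ids, summary


def retention_report(summaries: Sequence[RetentionSummary]) -> pd.DataFrame:
    """Tabulate retention per view (rows) with per-sample columns appended.

    All views must cover the identical roster (same total); a mismatch
    raises, since comparisons across views are otherwise meaningless.
    """
    totals = {s.total for s in summaries}
    if len(totals) > 1:
        raise IntegrityError(f"views computed on different rosters: totals {sorted(totals)}")
    rows = []
    for s in summaries:
        row = {
            "panel": s.panel,
            "total": s.total,
            "retained": s.retained,
            "lost": s.lost,
            "percent_retained": s.percent_retained,
        }
        if s.attrition:
            for k, v in s.attrition.items():
                row[f"fail_{k}"] = v
        if s.per_sample is not None:
            for sample, r in s.per_sample.iterrows():
                row[f"retained_{sample}"] = int(r["retained"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("panel")
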