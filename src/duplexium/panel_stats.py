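"""Cross-run and cross-panel statistics.

These are pseudobulk-style comparisons between decoding runs and between
probe panels sharing target genes:

* per-gene totals aggregated over all cells (slide level and per TMA
  sample), and correlations of those totals between runs;
* within-run z-scores of per-gene totals, and a paired comparison of the
  solo-run vs dual-run z-scores for panel-overlapping genes against a
  random non-overlapping subset — the diagnostic for competitive-binding
  sensitivity loss;
* per-gene Spearman correlation across cells between the two chemistries'
  counts of the same gene;
* per-cell secreted-gene diversity;
* cluster-label concordance (contingency table + adjusted Rand index).

The Wilcoxon signed-rank statistic and the adjusted Rand index are
implemented here from first principles — they are the analytical contract
of this module — and are cross-checked against independent library
implementations in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io_formats import CellByGeneMatrix
from .merge_qc import IntegrityError, parse_feature


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: too few genes or zero variance."""


# ---------------------------------------------------------------------------
# aggregation and correlation
# ---------------------------------------------------------------------------

def aggregate_counts(matrix: CellByGeneMatrix) -> pd.DataFrame:
    """Per-gene totals summed over all cells, slide level and per sample.

    Returns a DataFrame indexed by feature with a ``total`` column and one
    ``sample:<id>`` column per sample present in the metrics.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    out = pd.DataFrame({"total": totals}, index=pd.Index(matrix.feature_names, name="feature"))
    if matrix.metrics is not None and "sample_id" in matrix.metrics.columns:
        samples = matrix.metrics["sample_id"].to_numpy(object)
        for sample in pd.unique(samples):
            rows = np.flatnonzero(samples == sample)
            out[f"sample:{sample}"] = np.asarray(
                matrix.counts[rows].sum(axis=0)
            ).ravel()
    return out


def _transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "raw":
        return np.asarray(x, float)
    if transform == "log1p":
        return np.log1p(np.asarray(x, float))
    raise ValueError(f"unknown transform {transform!r}")


def correlate_aggregates(
    a: pd.Series,
    b: pd.Series,
    genes: Sequence[str] | None = None,
    method: str = "pearson",
    transform: str = "log1p",
) -> float:
    """Correlation of two runs' per-gene totals over a shared gene set.

    ``a``/``b`` are totals indexed by gene.  Needs >= 3 shared genes with
    nonzero variance on the chosen transform; raises
    :class:`UndefinedCorrelationError` otherwise.
    """
    shared = a.index.intersection(b.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 shared genes, have {len(shared)}"
        )
    x = _transform(a.loc[shared].to_numpy(), transform)
    y = _transform(b.loc[shared].to_numpy(), transform)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in aggregated totals")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def per_sample_correlation_matrix(
    a: pd.DataFrame,
    b: pd.DataFrame,
    genes: Sequence[str] | None = None,
    method: str = "pearson",
    transform: str = "log1p",
    min_expressed: int = 3,
) -> pd.Series:
    """Solo-vs-dual correlation within each sample.

    ``a``/``b`` are :func:`aggregate_counts` outputs.  A sample with fewer
    than ``min_expressed`` expressed shared genes gets NaN rather than a
    correlation.  Returns a Series keyed by sample id.
    """
    samples = [c[len("sample:"):] for c in a.columns if c.startswith("sample:")]
    out: dict[str, float] = {}
    for sample in samples:
        col = f"sample:{sample}"
        if col not in b.columns:
            continue
        sa, sb = a[col], b[col]
        expressed = ((sa > 0) | (sb > 0)).sum()
        if expressed < min_expressed:
            out[sample] = float("nan")
            continue
        try:
            out[sample] = correlate_aggregates(
                sa, sb, genes=genes, method=method, transform=transform
            )
        except UndefinedCorrelationError:
            out[sample] = float("nan")
    return pd.Series(out, name=f"{method}_r")


# ---------------------------------------------------------------------------
# z-scores and the overlap sensitivity comparison
# ---------------------------------------------------------------------------

@dataclass
class ZScoreTable:
    """Per-gene z-scores of (transformed) slide totals within one run."""

    run: str
    z: pd.Series
    transform: str


def zscore_across_genes(
    totals: pd.Series, transform: str = "log1p", run: str = ""
) -> ZScoreTable:
    """z_g = (x_g − mean) / sd over the genes of one run's panel.

    ``x_g`` is the per-gene slide total, log1p-transformed by default; the
    sd uses the sample convention (ddof=1).  Raises on < 2 genes or zero
    spread.
    """
    if len(totals) < 2:
        raise UndefinedCorrelationError("z-scores need >= 2 genes")
    x = _transform(totals.to_numpy(), transform)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise UndefinedCorrelationError("all gene totals equal; z-scores undefined")
    z = (x - x.mean()) / sd
    return ZScoreTable(run=run, z=pd.Series(z, index=totals.index), transform=transform)


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of median(diffs) = 0.

    Zeros are dropped; ties get average ranks; the p-value uses the normal
    approximation with tie correction and a continuity correction.
    Returns ``(W_plus, p)``.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_plus, 1.0
    dev = w_plus - mu
    # continuity correction toward the mean, as in the classical approximation
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(min(p, 1.0))


@dataclass
class OverlapSensitivity:
    """Paired z-score shift (solo − dual) for overlap vs random genes."""

    overlap_median_dz: float
    random_median_dz: float
    overlap_p: float
    random_p: float
    n_overlap: int
    n_random: int
    random_genes: tuple[str, ...]
    alpha: float = 0.05
    null_alpha: float = 0.01

    @property
    def overlap_shifted(self) -> bool:
        """Overlap genes lost sensitivity in the dual run."""
        return self.overlap_median_dz > 0 and self.overlap_p < self.alpha

    @property
    def random_subset_null_consistent(self) -> bool:
        """No strong evidence of a shift in the random non-overlap subset.

        Judged at the strict ``null_alpha`` because within-run z-scoring
        arithmetically leaks a small opposite-sign shift into non-overlap
        genes whenever the overlap genes move.
        """
        return self.random_p >= self.null_alpha


def compare_overlap_sensitivity(
    z_solo: ZScoreTable,
    z_dual: ZScoreTable,
    overlap_genes: Sequence[str],
    n_random: int | None = None,
    seed: int = 0,
) -> OverlapSensitivity:
    """Compare solo-vs-dual z-score shifts of overlap genes to a random
    non-overlap subset of the same panel.

    Δz_g = z_solo,g − z_dual,g; a positive overlap median with a
    significant paired rank test, alongside a null-consistent random
    subset, is the signature of competitive-binding sensitivity loss.
    The random subset (size ``n_random``, default = overlap size) is drawn
    without replacement with the given seed.
    """
    shared = z_solo.z.index.intersection(z_dual.z.index)
    overlap = pd.Index(overlap_genes).intersection(shared)
    if len(overlap) == 0:
        raise ValueError("overlap gene set is empty (after intersecting panels)")
    non_overlap = shared.difference(pd.Index(overlap_genes))
    if n_random is None:
        n_random = len(overlap)
    if n_random > len(non_overlap):
        raise ValueError(
            f"n_random={n_random} exceeds the {len(non_overlap)} available "
            "non-overlapping genes"
        )
    rng = np.random.default_rng(seed)
    random_genes = pd.Index(
        rng.choice(np.asarray(non_overlap, dtype=object), size=n_random, replace=False)
    )
    dz = z_solo.z.loc[shared] - z_dual.z.loc[shared]
    dz_overlap = dz.loc[overlap].to_numpy()
    dz_random = dz.loc[random_genes].to_numpy()
    _, p_overlap = wilcoxon_signed_rank(dz_overlap)
    _, p_random = wilcoxon_signed_rank(dz_random)
    return OverlapSensitivity(
        overlap_median_dz=float(np.median(dz_overlap)),
        random_median_dz=float(np.median(dz_random)),
        overlap_p=p_overlap,
        random_p=p_random,
        n_overlap=len(overlap),
        n_random=n_random,
        random_genes=tuple(random_genes),
    )


# ---------------------------------------------------------------------------
# per-gene cross-chemistry correlation
# ---------------------------------------------------------------------------

def per_gene_cross_chemistry_rho(
    v1_view: CellByGeneMatrix,
    prime_view: CellByGeneMatrix,
    shared_genes: Sequence[str],
) -> pd.DataFrame:
    """Spearman rho across cells between each shared gene's V1 and Prime
    counts.

    Both views must share the cell roster (same segmentation).  Genes with
    zero variance in either view are flagged ``undefined`` with NaN rho.
    """
    if not np.array_equal(v1_view.cell_ids, prime_view.cell_ids):
        raise IntegrityError("V1 and Prime views have different cell rosters")
    v1_genes = {parse_feature(f)[0]: i for i, f in enumerate(v1_view.feature_names)}
    pr_genes = {parse_feature(f)[0]: i for i, f in enumerate(prime_view.feature_names)}
    rows = []
    for gene in shared_genes:
        if gene not in v1_genes or gene not in pr_genes:
            raise IntegrityError(f"gene {gene!r} missing from one of the views")
        x = np.asarray(v1_view.counts[:, v1_genes[gene]].todense()).ravel()
        y = np.asarray(prime_view.counts[:, pr_genes[gene]].todense()).ravel()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((gene, float("nan"), True))
            continue
        rho = stats.spearmanr(x, y).statistic
        rows.append((gene, float(rho), False))
    return pd.DataFrame(rows, columns=["gene", "rho", "undefined"]).set_index("gene")


# ---------------------------------------------------------------------------
# secretome diversity
# ---------------------------------------------------------------------------

def secretome_diversity(
    matrix: CellByGeneMatrix, secreted_genes: Sequence[str], min_count: int = 1
) -> pd.Series:
    """Per-cell number of distinct secreted genes with count >= min_count.

    The broader panel's larger secreted-gene complement is what drives its
    higher per-cell diversity, so the value is bounded by both the view's
    detected genes and the secreted set size.
    """
    secreted = set(secreted_genes)
    if not secreted:
        raise ValueError("secreted gene set is empty")
    cols = np.array(
        [parse_feature(f)[0] in secreted for f in matrix.feature_names], dtype=bool
    )
    sub = matrix.counts[:, np.flatnonzero(cols)]
    per_cell = np.asarray((sub >= min_count).sum(axis=1)).ravel()
    return pd.Series(per_cell, index=pd.Index(matrix.cell_ids, name="cell_id"),
                     name="n_secreted")


# ---------------------------------------------------------------------------
# cluster-label concordance
# ---------------------------------------------------------------------------

def adjusted_rand_index(contingency: np.ndarray) -> float:
    """Adjusted Rand index from a labels-by-labels contingency table."""
    c = np.asarray(contingency, dtype=np.int64)
    n = c.sum()
    if n < 2:
        return 1.0
    sum_comb = float((c * (c - 1) // 2).sum())
    a = c.sum(axis=1)
    b = c.sum(axis=0)
    comb_a = float((a * (a - 1) // 2).sum())
    comb_b = float((b * (b - 1) // 2).sum())
    comb_n = n * (n - 1) / 2.0
    expected = comb_a * comb_b / comb_n
    max_index = 0.5 * (comb_a + comb_b)
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


FILTERED_LABEL = "filtered"


def cluster_label_concordance(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two cluster labelings of the same cells.

    Cells present in only one labeling (e.g. filtered out under one panel's
    QC) appear under the ``filtered`` row/column of the contingency table
    (the alluvial-plot input); the adjusted Rand index is computed on the
    shared cells only.
    """
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValueError("labelings have no cells in common")
    union = labels_a.index.union(labels_b.index)
    a = labels_a.reindex(union).astype(object)
    a[a.isna()] = FILTERED_LABEL
    b = labels_b.reindex(union).astype(object)
    b[b.isna()] = FILTERED_LABEL
    table = pd.crosstab(a, b, rownames=["labels_a"], colnames=["labels_b"])
    core = pd.crosstab(labels_a.loc[shared], labels_b.loc[shared])
    ari = adjusted_rand_index(core.to_numpy())
    return table, float(ari)
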