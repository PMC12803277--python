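"""Synthetic dual-chemistry experiment generator with known ground truth.

Emulates two sequential decoding runs of the same tissue-microarray slide:
one set of cells (simple convex-ish polygons laid out in rectangular
sample regions), imaged twice.  Run 1 uses the high-sensitivity narrow
panel ("V1", 480 genes by default); run 2 uses the broad panel ("Prime",
5001 genes), with its coordinate frame displaced by a known small
similarity transform — the cassette re-seating offset the registration
stage must recover.  A configurable subset of genes (239 by default) is
targeted by both panels; in the dual run the broad panel's rates for those
genes are multiplied by an attenuation factor, modelling competitive probe
binding.

Counts are Poisson per cell × gene with gamma-distributed per-cell size
factors (negative-binomial marginals).  Genes shared between panels also
share a per-cell lognormal activity (plus independent noise), so the two
chemistries' counts of the same gene are positively correlated across
cells.  Each realised transcript gets a position inside its cell (mostly
nuclear, so the nucleus-overlap filter bites realistically), a Phred-like
quality value from a pass/fail mixture straddling the QV = 20 cut, and
background transcripts are scattered outside all cells as ``UNASSIGNED``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.strtree import STRtree

from . import io_formats
from .io_formats import (
    UNASSIGNED,
    LandmarkSet,
    PanelDefinition,
    PolygonMask,
)
from .registration import AffineTransform2D


class ConfigurationError(ValueError):
    """Simulation configuration violates an invariant."""


def _default_transform() -> AffineTransform2D:
    # a plausible cassette re-seating offset: sub-degree rotation, ~10 µm shift
    return AffineTransform2D.similarity(rotation_deg=0.4, scale=1.0, translation=(8.0, -5.0))


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic dual run.

    Defaults mirror the benchmarked slide design: a 17-core TMA, a 480-gene
    narrow panel vs a 5001-gene broad panel with 239 genes in common,
    per-cell transcript means of 125 (V1) and 115 (Prime, before
    attenuation) matching the observed per-cell medians, and a 0.8
    attenuation of the broad panel's overlapping-gene rates in the dual
    run.
    """

    n_cells: int = 400
    n_samples: int = 17
    n_genes_v1: int = 480
    n_genes_prime: int = 5001
    n_overlap: int = 239
    mean_counts_v1: float = 125.0
    mean_counts_prime: float = 115.0
    prime_overlap_attenuation: float = 0.8
    true_transform: AffineTransform2D = field(default_factory=_default_transform)
    background_rate: float = 0.002  # unassigned transcripts per µm² of slide
    qv_fail_fraction: float = 0.1
    seed: int = 0
    # secondary knobs (held fixed across the study unless noted)
    gamma_shape: float = 3.0          # size-factor Gamma shape (CV ≈ 0.58)
    latent_sd: float = 0.8            # per-cell×gene lognormal activity sd
    latent_corr: float = 0.5          # shared fraction of overlap-gene activity
    nuclear_fraction: float = 0.7     # transcripts placed inside the nucleus
    cell_radius: float = 5.0          # hexagon circumradius, µm
    nucleus_scale: float = 0.5        # nucleus ring scale about the centroid
    n_landmarks: int = 6
    landmark_jitter: float = 0.0      # Gaussian sigma on anchor placement, µm

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_genes_v1, self.n_genes_prime):
            raise ConfigurationError(
                "n_overlap exceeds a panel size: "
                f"{self.n_overlap} > min({self.n_genes_v1}, {self.n_genes_prime})"
            )
        if not 0.0 <= self.prime_overlap_attenuation <= 1.0:
            raise ConfigurationError("prime_overlap_attenuation must be in [0, 1]")
        if not 0.0 <= self.qv_fail_fraction <= 1.0:
            raise ConfigurationError("qv_fail_fraction must be in [0, 1]")
        for name in ("mean_counts_v1", "mean_counts_prime", "background_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.n_cells < 0 or self.n_samples < 1:
            raise ConfigurationError("n_cells >= 0 and n_samples >= 1 required")
        if not 0.0 <= self.latent_corr <= 1.0:
            raise ConfigurationError("latent_corr must be in [0, 1]")


@dataclass
class DualExperiment:
    """Ground-truth container for one synthetic dual run."""

    cells: list[PolygonMask]
    transcripts_run1: pd.DataFrame
    transcripts_run2: pd.DataFrame
    true_assignment: pd.Series          # transcript_id -> cell_id (incl. UNASSIGNED)
    true_transform: AffineTransform2D
    panels: dict[str, PanelDefinition]
    landmarks: LandmarkSet
    config: SimConfig
    counts_v1: pd.DataFrame             # true per-cell × gene counts, V1 run
    counts_prime: pd.DataFrame          # true per-cell × gene counts, Prime run


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def make_panels(
    n_genes_v1: int, n_genes_prime: int, n_overlap: int
) -> dict[str, PanelDefinition]:
    """Deterministic gene catalogue: OLG#### on both panels, V1G####/PRG####
    panel-specific."""
    overlap = [f"OLG{i:04d}" for i in range(n_overlap)]
    v1_only = [f"V1G{i:04d}" for i in range(n_genes_v1 - n_overlap)]
    prime_only = [f"PRG{i:04d}" for i in range(n_genes_prime - n_overlap)]
    return {
        "V1": PanelDefinition("V1", tuple(overlap + v1_only)),
        "Prime": PanelDefinition("Prime", tuple(overlap + prime_only)),
    }


def _hexagon(center: np.ndarray, radius: float, rng: np.random.Generator) -> np.ndarray:
    angles = np.deg2rad(60.0 * np.arange(6) + rng.uniform(-8.0, 8.0, size=6))
    angles += rng.uniform(0.0, 60.0)  # random overall orientation
    radii = radius * (1.0 + rng.uniform(-0.12, 0.12, size=6))
    return np.column_stack([center[0] + radii * np.cos(angles),
                            center[1] + radii * np.sin(angles)])


def _scale_about_centroid(vertices: np.ndarray, factor: float) -> np.ndarray:
    c = shapely.Polygon(vertices).centroid
    c = np.array([c.x, c.y])
    return c + factor * (vertices - c)


def make_cells(config: SimConfig, rng: np.random.Generator) -> list[PolygonMask]:
    """Non-overlapping jittered hexagons on a grid, partitioned into
    rectangular sample regions laid out like TMA cores."""
    if config.n_cells == 0:
        return []
    per_sample = np.full(config.n_samples, config.n_cells // config.n_samples)
    per_sample[: config.n_cells % config.n_samples] += 1
    pitch = 2.6 * config.cell_radius          # > 2 r (1 + jitter): no collisions
    region_cols = int(np.ceil(np.sqrt(per_sample.max()))) if per_sample.max() else 1
    region_size = region_cols * pitch
    gap = 4.0 * config.cell_radius
    grid_cols = int(np.ceil(np.sqrt(config.n_samples)))
    masks: list[PolygonMask] = []
    cell_no = 0
    for s in range(config.n_samples):
        sx = (s % grid_cols) * (region_size + gap)
        sy = (s // grid_cols) * (region_size + gap)
        for k in range(per_sample[s]):
            cx = sx + (k % region_cols + 0.5) * pitch
            cy = sy + (k // region_cols + 0.5) * pitch
            center = np.array([cx, cy]) + rng.uniform(
                -0.12 * pitch, 0.12 * pitch, size=2
            )
            boundary = _hexagon(center, config.cell_radius, rng)
            masks.append(
                PolygonMask(
                    cell_id=f"cell_{cell_no:06d}",
                    boundary=boundary,
                    nucleus=_scale_about_centroid(boundary, config.nucleus_scale),
                    sample_id=f"S{s + 1:02d}",
                )
            )
            cell_no += 1
    return masks


def _gene_base_expression(
    panels: Mapping[str, PanelDefinition], rng: np.random.Generator
) -> pd.Series:
    """Lognormal relative expression per gene; a gene shared by both panels
    has ONE base level, so panel aggregates of shared genes correlate."""
    genes = sorted(set(panels["V1"].genes) | set(panels["Prime"].genes))
    return pd.Series(rng.lognormal(mean=0.0, sigma=1.0, size=len(genes)), index=genes)


def draw_count_matrices(
    config: SimConfig,
    panels: Mapping[str, PanelDefinition],
    base_expression: pd.Series,
    rng: np.random.Generator,
    attenuated: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell × gene counts for one slide's V1 and Prime streams.

    Per-cell gamma size factors are shared between the two streams (same
    physical cells); overlap genes share a per-cell lognormal activity
    between streams with correlation ``latent_corr``.  With
    ``attenuated=True`` the Prime rates of overlap genes are multiplied by
    ``prime_overlap_attenuation`` (the dual-run condition); ``False``
    models a solo Prime slide.
    """
    n = config.n_cells
    v1_genes = np.array(panels["V1"].genes)
    pr_genes = np.array(panels["Prime"].genes)
    w_v1 = base_expression.loc[v1_genes].to_numpy()
    w_v1 = w_v1 / w_v1.sum() if w_v1.sum() else w_v1
    w_pr = base_expression.loc[pr_genes].to_numpy()
    w_pr = w_pr / w_pr.sum() if w_pr.sum() else w_pr
    if n == 0:
        return (np.zeros((0, len(v1_genes)), dtype=np.int64),
                np.zeros((0, len(pr_genes)), dtype=np.int64))

    size = rng.gamma(shape=config.gamma_shape, scale=1.0 / config.gamma_shape, size=n)

    lam_v1 = config.mean_counts_v1 * np.outer(size, w_v1)
    lam_pr = config.mean_counts_prime * np.outer(size, w_pr)

    # correlated per-cell activity for the genes both panels target
    k = config.n_overlap
    if k and config.latent_sd > 0:
        sd, c = config.latent_sd, config.latent_corr
        shared = rng.standard_normal((n, k))
        e1 = rng.standard_normal((n, k))
        e2 = rng.standard_normal((n, k))
        a = sd * (np.sqrt(c) * shared + np.sqrt(1 - c) * e1)
        b = sd * (np.sqrt(c) * shared + np.sqrt(1 - c) * e2)
        half_var = 0.5 * sd**2
        lam_v1[:, :k] *= np.exp(a - half_var)   # overlap genes lead both panels
        lam_pr[:, :k] *= np.exp(b - half_var)
    if attenuated and k:
        lam_pr[:, :k] *= config.prime_overlap_attenuation

    counts_v1 = rng.poisson(lam_v1).astype(np.int64)
    counts_pr = rng.poisson(lam_pr).astype(np.int64)
    return counts_v1, counts_pr


def simulate_gene_totals(
    config: SimConfig, seed: int | None = None, attenuated: bool = True
) -> tuple[pd.Series, pd.Series]:
    """Fast path: per-gene slide totals for the V1 and Prime streams of one
    slide, skipping transcript placement.  Used for aggregate-level
    statistics simulations at many seeds."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panels = make_panels(config.n_genes_v1, config.n_genes_prime, config.n_overlap)
    base = _gene_base_expression(panels, rng)
    c_v1, c_pr = draw_count_matrices(config, panels, base, rng, attenuated=attenuated)
    return (
        pd.Series(c_v1.sum(axis=0), index=pd.Index(panels["V1"].genes, name="gene")),
        pd.Series(c_pr.sum(axis=0), index=pd.Index(panels["Prime"].genes, name="gene")),
    )


def simulate_solo_dual_prime_totals(
    config: SimConfig, seed: int
) -> tuple[pd.Series, pd.Series]:
    """Prime-panel gene totals for a solo slide (no attenuation) and a dual
    slide (attenuated overlap genes) of the same tissue: shared gene base
    expression, independent cells (serial sections)."""
    rng = np.random.default_rng(seed)
    panels = make_panels(config.n_genes_v1, config.n_genes_prime, config.n_overlap)
    base = _gene_base_expression(panels, rng)
    _, solo = draw_count_matrices(config, panels, base, rng, attenuated=False)
    _, dual = draw_count_matrices(config, panels, base, rng, attenuated=True)
    idx = pd.Index(panels["Prime"].genes, name="gene")
    return pd.Series(solo.sum(axis=0), index=idx), pd.Series(dual.sum(axis=0), index=idx)


# ---------------------------------------------------------------------------
# transcript placement
# ---------------------------------------------------------------------------

def _sample_in_polygon(
    poly_vertices: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.zeros((0, 2))
    poly = shapely.Polygon(poly_vertices)
    minx, miny, maxx, maxy = poly.bounds
    out = np.zeros((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 8)
        cand = np.column_stack([
            rng.uniform(minx, maxx, size=m),
            rng.uniform(miny, maxy, size=m),
        ])
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        cand = cand[inside]
        take = min(len(cand), n - got)
        out[got : got + take] = cand[:take]
        got += take
    return out


def _draw_qv(n: int, fail_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Two-component QV mixture: passing transcripts ≈ 40, failing ≈ 10,
    strictly straddling the QV = 20 threshold."""
    fail = rng.random(n) < fail_fraction
    qv = np.clip(rng.normal(40.0, 3.0, size=n), 20.0, 50.0)
    qv[fail] = np.clip(rng.normal(10.0, 3.0, size=fail.sum()), 0.0, 19.5)
    return qv


def _place_run_transcripts(
    counts: np.ndarray,
    gene_names: np.ndarray,
    masks: list[PolygonMask],
    config: SimConfig,
    rng: np.random.Generator,
    run_tag: str,
) -> pd.DataFrame:
    """Expand a per-cell × gene count matrix into positioned transcript
    records (run-1 frame)."""
    frames = []
    serial = 0
    for i, mask in enumerate(masks):
        total = int(counts[i].sum())
        if total == 0:
            continue
        nz = np.flatnonzero(counts[i])
        genes = np.repeat(gene_names[nz], counts[i, nz])
        in_nucleus = rng.random(total) < config.nuclear_fraction
        pos = np.zeros((total, 2))
        n_nuc = int(in_nucleus.sum())
        pos[in_nucleus] = _sample_in_polygon(mask.nucleus, n_nuc, rng)
        pos[~in_nucleus] = _sample_in_polygon(mask.boundary, total - n_nuc, rng)
        # cytoplasm draws may still land in the nucleus; flag by true position
        nuc_poly = shapely.Polygon(mask.nucleus)
        overlaps = shapely.contains_xy(nuc_poly, pos[:, 0], pos[:, 1]) | in_nucleus
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": [
                        f"{run_tag}T{serial + j:08d}" for j in range(total)
                    ],
                    "gene": genes,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "qv": _draw_qv(total, config.qv_fail_fraction, rng),
                    "overlaps_nucleus": overlaps.astype(int),
                    "cell_id": mask.cell_id,
                    "sample_id": mask.sample_id,
                }
            )
        )
        serial += total
    if not frames:
        return pd.DataFrame(
            columns=list(io_formats.TRANSCRIPT_COLUMNS) + ["sample_id"]
        )
    return pd.concat(frames, ignore_index=True)


def _background_transcripts(
    masks: list[PolygonMask],
    panel: PanelDefinition,
    config: SimConfig,
    rng: np.random.Generator,
    run_tag: str,
) -> pd.DataFrame:
    """Uniform background outside every mask, decoding random panel genes."""
    cols = list(io_formats.TRANSCRIPT_COLUMNS) + ["sample_id"]
    if not masks or config.background_rate <= 0:
        return pd.DataFrame(columns=cols)
    all_xy = np.vstack([m.boundary for m in masks])
    minx, miny = all_xy.min(axis=0) - 10.0
    maxx, maxy = all_xy.max(axis=0) + 10.0
    area = (maxx - minx) * (maxy - miny)
    n = int(rng.poisson(config.background_rate * area))
    if n == 0:
        return pd.DataFrame(columns=cols)
    tree = STRtree(np.array([m.boundary_polygon() for m in masks], dtype=object))
    pos = np.zeros((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand = np.column_stack([
            rng.uniform(minx, maxx, size=m),
            rng.uniform(miny, maxy, size=m),
        ])
        pts = shapely.points(cand)
        hit_idx, _ = tree.query(pts, predicate="intersects")
        keep = np.ones(m, dtype=bool)
        keep[hit_idx] = False
        cand = cand[keep]
        take = min(len(cand), n - got)
        pos[got : got + take] = cand[:take]
        got += take
    return pd.DataFrame(
        {
            "transcript_id": [f"{run_tag}B{j:08d}" for j in range(n)],
            "gene": rng.choice(np.array(panel.genes), size=n),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "qv": _draw_qv(n, config.qv_fail_fraction, rng),
            "overlaps_nucleus": 0,
            "cell_id": UNASSIGNED,
            "sample_id": "",
        }
    )


# ---------------------------------------------------------------------------
# top-level generator
# ---------------------------------------------------------------------------

def generate_dual_experiment(config: SimConfig) -> DualExperiment:
    """Generate a complete dual-run experiment with ground truth.

    Deterministic given ``config.seed``.  Run-1 transcripts are in the
    segmentation (run-1) frame; run-2 transcript coordinates are the same
    cells' positions pushed through ``true_transform``.  Landmarks pair
    run-1 cell centroids with their transformed positions (optionally
    jittered).
    """
    rng = np.random.default_rng(config.seed)
    panels = make_panels(config.n_genes_v1, config.n_genes_prime, config.n_overlap)
    masks = make_cells(config, rng)
    base = _gene_base_expression(panels, rng)
    counts_v1, counts_pr = draw_count_matrices(config, panels, base, rng, attenuated=True)

    v1_gene_arr = np.array(panels["V1"].genes)
    pr_gene_arr = np.array(panels["Prime"].genes)
    def _with_background(placed: pd.DataFrame, panel, tag: str) -> pd.DataFrame:
        bg = _background_transcripts(masks, panel, config, rng, tag)
        frames = [f for f in (placed, bg) if len(f)]
        if not frames:
            return placed
        return pd.concat(frames, ignore_index=True)

    run1 = _with_background(
        _place_run_transcripts(counts_v1, v1_gene_arr, masks, config, rng, "R1"),
        panels["V1"], "R1",
    )
    run2 = _with_background(
        _place_run_transcripts(counts_pr, pr_gene_arr, masks, config, rng, "R2"),
        panels["Prime"], "R2",
    )
    # displace run 2 into its own (second-run) coordinate frame
    if len(run2):
        xy = config.true_transform.apply(run2[["x", "y"]].to_numpy(float))
        run2 = run2.assign(x=xy[:, 0], y=xy[:, 1])

    true_assignment = pd.concat(
        [
            pd.Series(run1["cell_id"].to_numpy(), index=run1["transcript_id"]),
            pd.Series(run2["cell_id"].to_numpy(), index=run2["transcript_id"]),
        ]
    )
    true_assignment.index.name = "transcript_id"
    true_assignment.name = "cell_id"

    if masks:
        centroids = np.array(
            [[shapely.Polygon(m.boundary).centroid.x,
              shapely.Polygon(m.boundary).centroid.y] for m in masks]
        )
        k = min(config.n_landmarks, len(masks))
        pick = np.linspace(0, len(masks) - 1, k).astype(int)
        moving = centroids[pick]
        fixed = config.true_transform.apply(moving)
        if config.landmark_jitter > 0:
            moving = moving + rng.normal(0, config.landmark_jitter, moving.shape)
            fixed = fixed + rng.normal(0, config.landmark_jitter, fixed.shape)
        landmarks = LandmarkSet(moving=moving, fixed=fixed)
    else:
        landmarks = LandmarkSet(
            moving=np.zeros((0, 2)), fixed=np.zeros((0, 2))
        )

    cell_index = pd.Index([m.cell_id for m in masks], name="cell_id")
    return DualExperiment(
        cells=masks,
        transcripts_run1=run1,
        transcripts_run2=run2,
        true_assignment=true_assignment,
        true_transform=config.true_transform,
        panels=panels,
        landmarks=landmarks,
        config=config,
        counts_v1=pd.DataFrame(counts_v1, index=cell_index, columns=panels["V1"].genes),
        counts_prime=pd.DataFrame(counts_pr, index=cell_index, columns=panels["Prime"].genes),
    )


def default_secreted_sets(
    panels: Mapping[str, PanelDefinition],
    n_v1: int | None = None,
    n_prime: int | None = None,
) -> dict[str, tuple[str, ...]]:
    """Deterministic secreted-gene lists mirroring the panel imbalance
    (59 narrow-panel vs 538 broad-panel secreted genes at full panel sizes),
    drawn from the panel-specific gene blocks.  With ``None`` sizes the
    defaults are capped at the available pool, preserving the imbalance on
    scaled-down panels."""
    v1_specific = [g for g in panels["V1"].genes if g.startswith("V1G")]
    pr_specific = [g for g in panels["Prime"].genes if g.startswith("PRG")]
    if n_v1 is None:
        n_v1 = min(59, len(v1_specific))
    if n_prime is None:
        n_prime = min(538, len(pr_specific))
    if n_v1 > len(v1_specific) or n_prime > len(pr_specific):
        raise ConfigurationError("secreted set larger than panel-specific gene pool")
    return {"V1": tuple(v1_specific[:n_v1]), "Prime": tuple(pr_specific[:n_prime])}


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(experiment: DualExperiment, directory) -> dict[str, Path]:
    """Write an experiment to a directory in the pipeline's file formats.

    Emits transcripts (per run), cell boundaries, panel gene lists,
    landmarks, the true transform and the true assignment; round-trips
    losslessly through the :mod:`duplexium.io_formats` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts_run1": directory / "transcripts_run1.csv",
        "transcripts_run2": directory / "transcripts_run2.csv",
        "cell_boundaries": directory / "cell_boundaries.csv",
        "panel_v1": directory / "panel_v1.txt",
        "panel_prime": directory / "panel_prime.txt",
        "landmarks": directory / "landmarks.csv",
        "true_transform": directory / "true_transform.json",
        "true_assignment": directory / "true_assignment.csv",
    }
    io_formats.write_transcripts(experiment.transcripts_run1, paths["transcripts_run1"])
    io_formats.write_transcripts(experiment.transcripts_run2, paths["transcripts_run2"])
    io_formats.write_masks(experiment.cells, paths["cell_boundaries"])
    io_formats.write_panel(experiment.panels["V1"], paths["panel_v1"])
    io_formats.write_panel(experiment.panels["Prime"], paths["panel_prime"])
    io_formats.write_landmarks(experiment.landmarks, paths["landmarks"])
    experiment.true_transform.save(paths["true_transform"])
    experiment.true_assignment.to_csv(paths["true_assignment"])
    return paths
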