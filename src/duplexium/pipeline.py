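"""End-to-end orchestration: simulate → register → assign → merge → stats.

Each stage reads only its declared inputs from disk and persists its
outputs, so any stage can be re-run in isolation; ``run_pipeline`` chains
them and writes a manifest with a SHA-256 hash of every artifact.  Fixed
seeds give byte-identical artifacts (and hence manifest hashes) across
reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io_formats, merge_qc, panel_stats
from .assignment import QCThresholds, assign_transcripts, compute_cell_metrics, filter_transcripts
from .registration import AffineTransform2D, apply_transform, estimate_transform, refine_by_centroids
from .simulate import SimConfig, default_secreted_sets, generate_dual_experiment, write_fixture

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the cause."""


DEFAULT_CONFIG: dict[str, Any] = {
    "workdir": "duplexium_run",
    "seed": 0,
    "simulate": {},          # SimConfig overrides
    "register": {"model": "similarity", "refine": True, "cutoff": 15.0},
    "thresholds": {},        # QCThresholds overrides
    "stats": {"transform": "log1p", "method": "pearson", "n_random": None, "seed": 0},
    "log_level": "INFO",
}


def _merge_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(config: dict, workdir: Path) -> dict[str, Path]:
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs.setdefault("seed", config.get("seed", 0))
    if "true_transform" in sim_kwargs and isinstance(sim_kwargs["true_transform"], dict):
        sim_kwargs["true_transform"] = AffineTransform2D.from_dict(sim_kwargs["true_transform"])
    experiment = generate_dual_experiment(SimConfig(**sim_kwargs))
    paths = write_fixture(experiment, workdir / "fixture")
    logger.info(
        "simulate: %d cells, %d + %d transcripts",
        len(experiment.cells),
        len(experiment.transcripts_run1),
        len(experiment.transcripts_run2),
    )
    return paths


def stage_register(config: dict, workdir: Path) -> Path:
    fixture = workdir / "fixture"
    landmarks = io_formats.read_landmarks(fixture / "landmarks.csv")
    reg_cfg = config["register"]
    transform = estimate_transform(landmarks, model=reg_cfg.get("model", "similarity"))
    if reg_cfg.get("refine", True):
        masks = io_formats.read_masks(fixture / "cell_boundaries.csv")
        run2 = io_formats.read_transcripts(fixture / "transcripts_run2.csv")
        metrics = compute_cell_metrics(masks)
        moving = metrics[["centroid_x", "centroid_y"]].to_numpy()
        # fixed targets: per-cell transcript centroids of a preliminary
        # assignment of run-2 transcripts against the coarsely moved masks
        moved = apply_transform(transform, masks)
        prelim = assign_transcripts(run2, moved)
        grouped = prelim[prelim["cell_id"] != io_formats.UNASSIGNED].groupby("cell_id")
        fixed = grouped[["x", "y"]].mean()
        shared = fixed.index.intersection(metrics.index)
        transform, info = refine_by_centroids(
            transform,
            metrics.loc[shared, ["centroid_x", "centroid_y"]].to_numpy(),
            fixed.loc[shared].to_numpy(),
            cutoff=reg_cfg.get("cutoff", 15.0),
        )
        logger.info("register: refined, mean matched distance %.4f µm", info.mean_distance)
    out = workdir / "transform.json"
    transform.save(out)
    return out


def stage_assign(config: dict, workdir: Path) -> dict[str, Path]:
    fixture = workdir / "fixture"
    transform = AffineTransform2D.load(workdir / "transform.json")
    masks = io_formats.read_masks(fixture / "cell_boundaries.csv")
    thresholds = QCThresholds(**config.get("thresholds", {}))
    out_paths: dict[str, Path] = {}
    report: dict[str, dict] = {}
    for run, frame_masks in (("run1", masks), ("run2", apply_transform(transform, masks))):
        records = io_formats.read_transcripts(fixture / f"transcripts_{run}.csv")
        assigned = assign_transcripts(records, frame_masks)
        kept, tally = filter_transcripts(assigned, thresholds)
        path = workdir / f"assigned_{run}.csv"
        io_formats.write_transcripts(kept, path)
        out_paths[run] = path
        report[run] = {"total": len(records), "kept": len(kept), "removed": tally}
        logger.info("assign %s: kept %d / %d", run, len(kept), len(records))
    report_path = workdir / "assignment_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    out_paths["report"] = report_path
    return out_paths


def stage_merge(config: dict, workdir: Path) -> dict[str, Path]:
    fixture = workdir / "fixture"
    masks = io_formats.read_masks(fixture / "cell_boundaries.csv")
    panels = {
        "V1": io_formats.read_panel(fixture / "panel_v1.txt", "V1"),
        "Prime": io_formats.read_panel(fixture / "panel_prime.txt", "Prime"),
    }
    metrics = compute_cell_metrics(masks)
    kept = {
        "V1": io_formats.read_transcripts(workdir / "assigned_run1.csv"),
        "Prime": io_formats.read_transcripts(workdir / "assigned_run2.csv"),
    }
    matrix = merge_qc.build_matrix(kept, panels, metrics)
    thresholds = QCThresholds(**config.get("thresholds", {}))
    paths: dict[str, Path] = {}
    summaries = []
    flags = pd.DataFrame(index=pd.Index(matrix.cell_ids, name="cell_id"))
    for view_name, subdir in (("Combined", "combined"), ("V1", "v1"), ("Prime", "prime")):
        view = matrix.view(view_name)
        io_formats.write_matrix(view, workdir / "matrices" / subdir)
        retained, _, summary = merge_qc.filter_cells(view, thresholds)
        summaries.append(summary)
        flags[f"pass_{subdir}"] = np.isin(matrix.cell_ids, retained)
        paths[f"matrix_{subdir}"] = workdir / "matrices" / subdir / "matrix.mtx"
    report = merge_qc.retention_report(summaries)
    report_path = workdir / "retention_report.tsv"
    report.to_csv(report_path, sep="\t")
    meta_path = workdir / "cell_metadata.csv"
    metrics.join(flags).to_csv(meta_path)
    paths["retention_report"] = report_path
    paths["cell_metadata"] = meta_path
    logger.info(
        "merge: retention %s",
        {s.panel: round(s.percent_retained, 1) for s in summaries},
    )
    return paths


def stage_stats(config: dict, workdir: Path) -> dict[str, Path]:
    stats_cfg = config["stats"]
    transform = stats_cfg.get("transform", "log1p")
    combined = io_formats.read_matrix(workdir / "matrices" / "combined")
    v1 = combined.view("V1")
    prime = combined.view("Prime")
    paths: dict[str, Path] = {}

    agg_v1 = panel_stats.aggregate_counts(v1)
    agg_pr = panel_stats.aggregate_counts(prime)
    def strip(df):  # feature names -> bare gene symbols
        return df.set_axis([f.rsplit("-", 1)[0] for f in df.index], axis=0)

    agg_v1g, agg_prg = strip(agg_v1), strip(agg_pr)
    shared = sorted(set(agg_v1g.index) & set(agg_prg.index))
    corr_rows = []
    for method in ("pearson", "spearman"):
        for tr in ("raw", "log1p"):
            try:
                r = panel_stats.correlate_aggregates(
                    agg_v1g["total"], agg_prg["total"], genes=shared,
                    method=method, transform=tr,
                )
            except panel_stats.UndefinedCorrelationError:
                r = float("nan")
            corr_rows.append({"comparison": "V1_vs_Prime_overlap", "method": method,
                              "transform": tr, "r": r, "n_genes": len(shared)})
    corr_path = workdir / "correlations.tsv"
    pd.DataFrame(corr_rows).to_csv(corr_path, sep="\t", index=False)
    paths["correlations"] = corr_path

    z_v1 = panel_stats.zscore_across_genes(agg_v1["total"], transform=transform, run="V1")
    z_pr = panel_stats.zscore_across_genes(agg_pr["total"], transform=transform, run="Prime")
    z_path = workdir / "zscore_comparison.tsv"
    pd.DataFrame({"z_v1": z_v1.z.set_axis([f.rsplit("-", 1)[0] for f in z_v1.z.index]),
                  "z_prime": z_pr.z.set_axis([f.rsplit("-", 1)[0] for f in z_pr.z.index])}
                 ).to_csv(z_path, sep="\t", index_label="gene", na_rep="NA")
    paths["zscores"] = z_path

    rho = panel_stats.per_gene_cross_chemistry_rho(v1, prime, shared)
    rho_path = workdir / "per_gene_rho.tsv"
    rho.to_csv(rho_path, sep="\t", na_rep="NA")
    paths["per_gene_rho"] = rho_path

    secreted_cfg = stats_cfg.get("secretome")
    if secreted_cfg:
        secreted = {
            name: tuple(Path(p).read_text().split())
            for name, p in secreted_cfg.items()
        }
    else:
        panels = {
            "V1": io_formats.read_panel(workdir / "fixture" / "panel_v1.txt", "V1"),
            "Prime": io_formats.read_panel(workdir / "fixture" / "panel_prime.txt", "Prime"),
        }
        secreted = default_secreted_sets(panels)
    div = pd.DataFrame(
        {
            "n_secreted_v1": panel_stats.secretome_diversity(v1, secreted["V1"]),
            "n_secreted_prime": panel_stats.secretome_diversity(prime, secreted["Prime"]),
        }
    )
    div_path = workdir / "secretome_per_cell.tsv"
    div.to_csv(div_path, sep="\t")
    paths["secretome"] = div_path
    return paths


STAGES = ("simulate", "register", "assign", "merge", "stats")

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "register": stage_register,
    "assign": stage_assign,
    "merge": stage_merge,
    "stats": stage_stats,
}


def run_pipeline(config: dict | None = None, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write ``manifest.json``.

    Returns the manifest dict: per-stage timings plus a SHA-256 hash of
    every file under the working directory.  Fails fast with
    :class:`StageError` naming the failing stage.
    """
    config = _merge_config(config)
    logging.basicConfig(level=config.get("log_level", "INFO"))
    workdir = Path(config["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    for stage in stages:
        start = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, workdir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - start, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])
    manifest = {
        "stages": list(stages),
        "timings_s": timings,
        "artifacts": {
            str(p.relative_to(workdir)): _sha256(p)
            for p in sorted(workdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
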