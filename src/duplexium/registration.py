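"""Landmark registration between the two decoding runs of one slide.

The two runs image the same physical section, but re-seating the slide
cassette between runs introduces a small rigid-like offset, so the first
run's segmentation masks must be mapped into the second run's coordinate
frame before transcripts can be pooled per cell.  The map is a 2D linear
transform estimated from paired anchor points, optionally refined by an
iterative-closest-point pass over cell centroids.

Two models are supported:

* ``similarity`` (default): rotation + uniform scale + translation, the
  closed-form least-squares (Procrustes/Umeyama) solution.  This matches
  the physics of cassette re-seating.
* ``affine``: full 6-parameter linear map fitted by ordinary least squares,
  for slides where shear or anisotropic scaling is suspected.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import LandmarkSet, PolygonMask


class RankDeficiencyError(ValueError):
    """Landmarks are insufficient or degenerate for the requested model."""


class RefinementError(RuntimeError):
    """ICP refinement could not match any centroids; carries the initial
    transform in ``initial_transform``."""

    def __init__(self, message: str, initial_transform: "AffineTransform2D"):
        super().__init__(message)
        self.initial_transform = initial_transform


@dataclass
class AffineTransform2D:
    """``p  ->  linear @ p + translation`` on 2D points (µm)."""

    linear: np.ndarray
    translation: np.ndarray
    model: str = "affine"
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-15:
            raise ValueError("transform linear part is singular")

    @classmethod
    def identity(cls, model: str = "similarity") -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), model=model)

    @classmethod
    def similarity(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: Sequence[float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        t = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        return cls(scale * rot, np.asarray(translation, float), model="similarity")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.translation, model=self.model)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return ``self ∘ other``: apply ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
            model="affine" if "affine" in (self.model, other.model) else self.model,
        )

    # -- scalar descriptors (similarity decomposition) ---------------------
    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.linear))))

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.linear[1, 0], self.linear[0, 0])))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "linear": self.linear.ravel().tolist(),  # row-major
            "translation": self.translation.tolist(),
            "model": self.model,
            "residual_rms": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(
            np.asarray(d["linear"], float).reshape(2, 2),
            np.asarray(d["translation"], float),
            model=d.get("model", "affine"),
            residual_rms=d.get("residual_rms"),
        )

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "AffineTransform2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def estimate_transform(
    landmarks: LandmarkSet, model: str = "similarity"
) -> AffineTransform2D:
    """Least-squares transform minimising Σ‖T(moving_i) − fixed_i‖².

    ``similarity`` uses the closed-form Procrustes solution (proper rotation
    enforced); ``affine`` solves the 6-parameter normal equations.  The RMS
    landmark residual is stored on the returned transform.
    """
    moving, fixed = landmarks.moving, landmarks.fixed
    n = len(moving)
    if model == "similarity":
        if n < 2:
            raise RankDeficiencyError("similarity model needs >= 2 landmark pairs")
        transform = _procrustes_similarity(moving, fixed)
    elif model == "affine":
        if n < 3:
            raise RankDeficiencyError("affine model needs >= 3 landmark pairs")
        design = np.column_stack([moving, np.ones(n)])
        if np.linalg.matrix_rank(design) < 3:
            raise RankDeficiencyError("landmarks are collinear; affine fit is rank-deficient")
        coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
        transform = AffineTransform2D(coef[:2].T, coef[2], model="affine")
    elif model == "rigid":
        if n < 2:
            raise RankDeficiencyError("rigid model needs >= 2 landmark pairs")
        transform = _procrustes_similarity(moving, fixed, fix_scale=True)
    else:
        raise ValueError(f"unknown model {model!r}")
    resid = transform.apply(moving) - fixed
    transform.residual_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))) if n else 0.0
    return transform


def _procrustes_similarity(
    moving: np.ndarray, fixed: np.ndarray, fix_scale: bool = False
) -> AffineTransform2D:
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    xm = moving - mu_m
    xf = fixed - mu_f
    var_m = float(np.sum(xm**2))
    if var_m < 1e-24:
        raise RankDeficiencyError("moving landmarks are coincident")
    cov = xf.T @ xm / len(moving)
    u, s, vt = np.linalg.svd(cov)
    d = np.ones(2)
    if np.linalg.det(u @ vt) < 0:  # enforce a proper rotation
        d[-1] = -1.0
    rot = u @ np.diag(d) @ vt
    if fix_scale:
        scale = 1.0
        model = "rigid"
    else:
        scale = float(np.sum(s * d) * len(moving) / var_m)
        if scale <= 0:
            raise RankDeficiencyError("degenerate landmark configuration (scale <= 0)")
        model = "similarity"
    linear = scale * rot
    return AffineTransform2D(linear, mu_f - linear @ mu_m, model=model)


def apply_transform(
    transform: AffineTransform2D,
    target: np.ndarray | Iterable[PolygonMask],
):
    """Map points (n, 2) or a mask list through ``transform``.

    Masks keep their ids, sample labels and vertex order; areas scale by
    ``|det(linear)|``.
    """
    if isinstance(target, np.ndarray):
        return transform.apply(target)
    out = []
    for mask in target:
        out.append(
            PolygonMask(
                cell_id=mask.cell_id,
                boundary=transform.apply(mask.boundary),
                nucleus=None if mask.nucleus is None else transform.apply(mask.nucleus),
                sample_id=mask.sample_id,
            )
        )
    return out


@dataclass
class RefinementInfo:
    n_iterations: int
    n_matched: int
    unmatched_fraction: float
    mean_distance: float
    initial_mean_distance: float


def refine_by_centroids(
    transform0: AffineTransform2D,
    moving_centroids: np.ndarray,
    fixed_centroids: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    cutoff: float = 15.0,
) -> tuple[AffineTransform2D, RefinementInfo]:
    """Fine-scale ICP correction of an approximately correct transform.

    Alternates (a) one-to-one greedy nearest-neighbour matching of the
    transformed moving centroids to fixed centroids within ``cutoff`` µm
    and (b) re-estimation of a rigid (rotation + translation) correction
    from the matches.  Stops when the mean matched distance improves by
    less than ``tol`` µm; never returns a transform with a worse mean
    matched distance than the best iterate seen.
    """
    moving = np.asarray(moving_centroids, float).reshape(-1, 2)
    fixed = np.asarray(fixed_centroids, float).reshape(-1, 2)
    if len(moving) == 0 or len(fixed) == 0:
        raise RefinementError("no centroids to match", transform0)
    tree = cKDTree(fixed)

    def _match(t: AffineTransform2D):
        warped = t.apply(moving)
        dist, idx = tree.query(warped, distance_upper_bound=cutoff)
        cand = np.flatnonzero(np.isfinite(dist))
        order = cand[np.argsort(dist[cand], kind="stable")]
        used = np.zeros(len(fixed), dtype=bool)
        mi, fi = [], []
        for i in order:  # greedy one-to-one by ascending distance
            j = idx[i]
            if not used[j]:
                used[j] = True
                mi.append(i)
                fi.append(j)
        mi = np.array(mi, dtype=int)
        fi = np.array(fi, dtype=int)
        if len(mi) == 0:
            return mi, fi, np.inf
        d = np.linalg.norm(warped[mi] - fixed[fi], axis=1)
        return mi, fi, float(d.mean())

    current = transform0
    mi, fi, mean_dist = _match(current)
    if len(mi) == 0:
        raise RefinementError(
            f"no centroid matches within cutoff {cutoff} µm", transform0
        )
    initial_mean = mean_dist
    best = (current, mean_dist, len(mi))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if len(mi) < 2:
            break
        correction = _procrustes_similarity(
            current.apply(moving[mi]), fixed[fi], fix_scale=True
        )
        candidate = correction.compose(current)
        candidate = replace(candidate, model=transform0.model)
        mi2, fi2, new_mean = _match(candidate)
        if len(mi2) == 0:
            break
        if new_mean < best[1]:
            best = (candidate, new_mean, len(mi2))
        if mean_dist - new_mean < tol:
            mi, fi, mean_dist, current = mi2, fi2, new_mean, candidate
            break
        mi, fi, mean_dist, current = mi2, fi2, new_mean, candidate
    result, final_mean, n_matched = best
    result.residual_rms = final_mean
    info = RefinementInfo(
        n_iterations=n_iter,
        n_matched=n_matched,
        unmatched_fraction=1.0 - n_matched / len(moving),
        mean_distance=final_mean,
        initial_mean_distance=initial_mean,
    )
    return result, info
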