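"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from duplexium.simulate import SimConfig, generate_dual_experiment


# ---------------------------------------------------------------------------
# independent geometry oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (orientation-independent)."""
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def ray_cast_inside(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd ray-casting point-in-polygon test, one polygon at a time."""
    points = np.asarray(points, float)
    v = np.asarray(vertices, float)
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    j = len(v) - 1
    for i in range(len(v)):
        xi, yi = v[i]
        xj, yj = v[j]
        crosses = (yi > y) != (yj > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xcross = (xj - xi) * (y - yi) / (yj - yi) + xi
        inside ^= crosses & (x < xcross)
        j = i
    return inside


def brute_force_assign(points: np.ndarray, masks) -> np.ndarray:
    """O(points × polygons) assignment oracle with the same tie-break rule
    (smaller area, then lexicographic id) as the implementation."""
    from duplexium.io_formats import UNASSIGNED

    order = sorted(
        range(len(masks)),
        key=lambda i: (shoelace_area(masks[i].boundary), masks[i].cell_id),
    )
    out = np.full(len(points), UNASSIGNED, dtype=object)
    undecided = np.ones(len(points), dtype=bool)
    for i in order:
        hit = undecided & ray_cast_inside(points, masks[i].boundary)
        out[hit] = masks[i].cell_id
        undecided &= ~hit
    return out


# ---------------------------------------------------------------------------
# shared synthetic experiments
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_cells=120,
        n_samples=4,
        n_genes_v1=60,
        n_genes_prime=200,
        n_overlap=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_dual_experiment(small_config)


@pytest.fixture(scope="session")
def identity_experiment():
    """Identity offset, no background, no QV failures: the pipeline should
    reproduce the generator's ground truth exactly."""
    from duplexium.registration import AffineTransform2D

    config = SimConfig(
        n_cells=100,
        n_samples=4,
        n_genes_v1=60,
        n_genes_prime=200,
        n_overlap=30,
        true_transform=AffineTransform2D.identity(),
        background_rate=0.0,
        qv_fail_fraction=0.0,
        seed=7,
    )
    return generate_dual_experiment(config)
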