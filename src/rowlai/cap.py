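"""Clusters' Area Plane (CAP): a horizontal-structure canopy feature.

A thin horizontal slab is cut through the vegetation points at a height
quantile (default the 3rd quartile, ±4 cm); the slab's (x, y) points are
clustered with a k-nearest-neighbor region-growing scheme; each cluster's
footprint area is the area of its 2D convex hull; CAP is the summed area
of the clusters larger than a user-set threshold.

The region growing is realized as connected components of the symmetrized
neighbor graph (j is linked to i if j is among i's k nearest neighbors
within the radius, or vice versa). Iteratively joining clusters that share
points, as in the original description, converges to exactly these
components, so a single union-find pass is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .terrain import HeightCloud

__all__ = [
    "CapConfig",
    "SliceClustering",
    "take_slice",
    "region_grow_clusters",
    "cluster_area",
    "cap_feature",
]


@dataclass(frozen=True)
class CapConfig:
    """Tunable parameters of the CAP feature.

    quantile, half_thickness define the slab; radius, k the neighbor
    relation; area_threshold (m²) drops speckle clusters. The defaults
    (10 cm radius, k=10, 0.01 m² threshold) are engineering choices —
    all three are "user-defined" knobs of the method.
    """

    quantile: float = 0.75
    half_thickness: float = 0.04
    radius: float = 0.10
    k: int = 10
    area_threshold: float = 0.01


@dataclass
class SliceClustering:
    """Diagnostic record of one CAP evaluation."""

    slice_height: float
    points: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,)
    areas: np.ndarray  # per-cluster convex-hull areas, m²
    area_threshold: float
    cap: float

    def to_csv(self, points_path: str | Path, clusters_path: str | Path) -> None:
        """Dump (x, y, label) and (label, n_points, area) tables for
        cross-section plots."""
        import pandas as pd

        pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "label": self.labels}
        ).to_csv(points_path, index=False)
        counts = np.bincount(self.labels, minlength=len(self.areas))
        pd.DataFrame(
            {"label": np.arange(len(self.areas)), "n_points": counts, "area": self.areas}
        ).to_csv(clusters_path, index=False)


def take_slice(
    hc: HeightCloud, quantile: float = 0.75, half_thickness: float = 0.04
) -> tuple[np.ndarray, float]:
    """Cut the slab at the given quantile of vegetation heights.

    Returns the (n, 2) array of slab (x, y) coordinates and the slab
    center height. The quantile is of vegetation heights only — ground
    points are excluded from all statistical analysis.
    """
    veg = hc.vegetation_heights
    if veg.size == 0:
        raise ValueError("no vegetation points to slice")
    slice_height = float(np.quantile(veg, quantile))
    mask = ~hc.is_ground & (np.abs(hc.height - slice_height) <= half_thickness)
    pts = np.column_stack([hc.cloud.x[mask], hc.cloud.y[mask]])
    return pts, slice_height


def region_grow_clusters(pts: np.ndarray, radius: float, k: int) -> np.ndarray:
    """Label 2D points by k-NN-within-radius region growing.

    Two points share a label iff they are connected through the
    symmetrized relation {j among i's k nearest AND dist(i, j) ≤ radius,
    or vice versa}. With k ≥ n−1 this is exactly the radius-graph
    connected components. Labels are contiguous from 0 in order of first
    appearance, so the labeling is independent of internal component
    ordering.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(pts)
    kq = min(k + 1, n)  # +1: the query point is its own nearest neighbor
    dist, nbr = tree.query(pts, k=kq, distance_upper_bound=radius)
    dist = np.atleast_2d(dist.T).T
    nbr = np.atleast_2d(nbr.T).T
    src = np.repeat(np.arange(n), nbr.shape[1])
    dst = nbr.ravel()
    good = np.isfinite(dist.ravel()) & (dst < n) & (dst != src)
    src, dst = src[good], dst[good]
    adj = coo_matrix((np.ones(src.size, dtype=np.int8), (src, dst)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    # renumber in order of first appearance for determinism
    _, first = np.unique(comp, return_index=True)
    remap = np.empty(first.size, dtype=int)
    remap[comp[np.sort(first)]] = np.arange(first.size)
    return remap[comp]


def cluster_area(cluster_pts: np.ndarray) -> float:
    """Footprint area (m²) of one cluster: its 2D convex-hull area.

    Fewer than 3 points, or any collinear configuration, has zero area.
    """
    cluster_pts = np.asarray(cluster_pts, dtype=float).reshape(-1, 2)
    if len(cluster_pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(cluster_pts).volume)  # "volume" is area in 2D
    except QhullError:
        return 0.0


def cap_feature(
    hc: HeightCloud, config: CapConfig = CapConfig(), *, diagnostics: bool = False
) -> float | SliceClustering:
    """CAP = Σ A_i over clusters with hull area A_i > area_threshold.

    An empty slab (too few points near the quantile, as happens at lower
    quartiles under poor canopy penetration) yields CAP = 0.
    """
    try:
        pts, slice_height = take_slice(hc, config.quantile, config.half_thickness)
    except ValueError:
        pts, slice_height = np.empty((0, 2)), float("nan")
    labels = region_grow_clusters(pts, config.radius, config.k)
    n_clusters = int(labels.max()) + 1 if labels.size else 0
    areas = np.array(
        [cluster_area(pts[labels == c]) for c in range(n_clusters)], dtype=float
    )
    cap = float(areas[areas > config.area_threshold].sum()) if n_clusters else 0.0
    if diagnostics:
        return SliceClustering(
            slice_height=slice_height,
            points=pts,
            labels=labels,
            areas=areas,
            area_threshold=config.area_threshold,
            cap=cap,
        )
    return cap
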