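"""Per-nucleus morphometry: the 10 cell-level features.

For every segmented nucleus: area (px^2), major/minor axis lengths of
the moment-matched ellipse (px), their ratio, mean RGB intensities, and
the mean/max/min Euclidean distances to its neighbors in the Delaunay
triangulation of nucleus centroids.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from skimage.measure import regionprops

BASE_FEATURES = ("area", "major", "minor", "ratio", "rMean", "gMean", "bMean")
DIST_FEATURES = ("distMean", "distMax", "distMin")


def compute_nucleus_features(
    region_mask: np.ndarray, image: np.ndarray
) -> dict[str, float]:
    """Shape and intensity features of a single nucleus region.

    ``region_mask`` is a boolean array (same H, W as ``image``) marking
    the nucleus pixels.  The major/minor axis lengths are those of the
    ellipse with the region's second central moments; a degenerate
    region (zero minor axis, e.g. a single pixel or a perfect line) gets
    its minor axis clamped to 1 px and is flagged with a warning.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty nucleus region")
    props = regionprops(region_mask.astype(np.uint8), intensity_image=image)[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    if minor < 1.0:
        warnings.warn("degenerate nucleus region: minor axis clamped to 1 px", stacklevel=2)
        minor = 1.0
        major = max(major, minor)
    means = np.atleast_1d(props.intensity_mean)
    return {
        "area": float(props.area),
        "major": major,
        "minor": minor,
        "ratio": major / minor,
        "rMean": float(means[0]),
        "gMean": float(means[1] if means.size > 1 else means[0]),
        "bMean": float(means[2] if means.size > 2 else means[0]),
    }


def build_neighbor_graph(centroids: np.ndarray) -> set[tuple[int, int]]:
    """Undirected Delaunay neighbor edges over nucleus centroids.

    Returns a set of ``(i, j)`` index pairs with ``i < j``.  Exactly two
    centroids form a single edge; collinear sets (where triangulation is
    undefined) are connected as a path in coordinate order.  Fewer than
    two centroids give an empty graph with a warning.  Degenerate inputs
    that still fail triangulation are retried once with a tiny (1e-6 px)
    deterministic jitter.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        pts = pts.reshape(-1, 2)
    n = pts.shape[0]
    if n < 2:
        warnings.warn("fewer than 2 centroids: neighbor graph empty", stacklevel=2)
        return set()
    if n == 2:
        return {(0, 1)}
    try:
        tri = Delaunay(pts)
    except QhullError:
        return _fallback_graph(pts)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def _fallback_graph(pts: np.ndarray) -> set[tuple[int, int]]:
    # collinear (or otherwise degenerate) points: path in coordinate order
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    if np.unique(pts, axis=0).shape[0] == pts.shape[0]:
        return {tuple(sorted((int(order[k]), int(order[k + 1])))) for k in range(len(order) - 1)}
    # duplicate points: jitter deterministically and retry once
    rng = np.random.default_rng(0)
    try:
        tri = Delaunay(pts + rng.normal(0.0, 1e-6, size=pts.shape))
    except QhullError:
        return {tuple(sorted((int(order[k]), int(order[k + 1])))) for k in range(len(order) - 1)}
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def compute_distance_features(
    edges: set[tuple[int, int]],
    centroids: np.ndarray,
    max_edge_length: float | None = None,
) -> pd.DataFrame:
    """Per-node summary of Euclidean distances to Delaunay neighbors.

    Edges longer than ``max_edge_length`` (if given) are pruned first;
    isolated nodes get NaN distance features (and are excluded from
    histogram aggregation downstream).
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    neighbors: list[list[float]] = [[] for _ in range(n)]
    for i, j in edges:
        d = float(np.hypot(*(pts[i] - pts[j])))
        if max_edge_length is not None and d > max_edge_length:
            continue
        neighbors[i].append(d)
        neighbors[j].append(d)
    rows = np.full((n, 3), np.nan)
    for k, ds in enumerate(neighbors):
        if ds:
            rows[k] = (float(np.mean(ds)), float(np.max(ds)), float(np.min(ds)))
    return pd.DataFrame(rows, columns=list(DIST_FEATURES))


def extract_cell_features(
    labels: np.ndarray,
    image: np.ndarray,
    max_edge_length: float | None = None,
    scale_um_per_px: float | None = None,
) -> pd.DataFrame:
    """Full cell-level feature table for a labeled tile.

    One row per nucleus: id, centroid (row, col), and the 10 cell-level
    features.  If ``scale_um_per_px`` is given, all length features
    (major, minor, distances) are reported in micrometers and area in
    um^2; otherwise everything stays in pixel units.
    """
    props = regionprops(labels, intensity_image=image)
    if not props:
        return pd.DataFrame(
            columns=["id", "row", "col", *BASE_FEATURES, *DIST_FEATURES]
        )
    records = []
    for p in props:
        major = float(p.axis_major_length)
        minor = float(p.axis_minor_length)
        if minor < 1.0:
            minor = 1.0
            major = max(major, minor)
        means = np.atleast_1d(p.intensity_mean)
        records.append(
            {
                "id": int(p.label),
                "row": float(p.centroid[0]),
                "col": float(p.centroid[1]),
                "area": float(p.area),
                "major": major,
                "minor": minor,
                "ratio": major / minor,
                "rMean": float(means[0]),
                "gMean": float(means[1] if means.size > 1 else means[0]),
                "bMean": float(means[2] if means.size > 2 else means[0]),
            }
        )
    table = pd.DataFrame(records)
    centroids = table[["row", "col"]].to_numpy()
    edges = build_neighbor_graph(centroids) if len(table) >= 2 else set()
    dist = compute_distance_features(edges, centroids, max_edge_length=max_edge_length)
    table = pd.concat([table, dist], axis=1)
    if scale_um_per_px is not None:
        s = float(scale_um_per_px)
        table["area"] *= s * s
        for col in ("major", "minor", "distMean", "distMax", "distMin"):
            table[col] *= s
    return table
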