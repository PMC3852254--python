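"""Comparison region methods: the parametric ellipse and convex hull peeling.

Both are classical alternatives to the distribution-free polygon.  The
ellipse assumes bivariate normality; peeling is nonparametric but can only
exclude whole hull layers at a time, so its realized level is quantized.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import chi2

from .geometry import (
    ConvexRegion,
    DegenerateDataWarning,
    GeometryError,
    PointSet,
    _canonicalize,
)

__all__ = ["ellipse_region", "convex_hull_peeling_region", "peel_depths"]


def ellipse_region(
    points: PointSet, alpha: float = 0.05, n_arc: int = 360
) -> ConvexRegion:
    """Classical normal-theory confidence ellipse, discretized to a polygon.

    The region is ``{p : (p - mean)' S^{-1} (p - mean) <= q}`` with S the
    sample covariance and q the chi-square(2 df) quantile at ``1 - alpha``
    (the large-sample scaling; at the sample sizes this package targets the
    small-sample F scaling is indistinguishable).  The boundary is returned
    as ``n_arc`` vertices.
    """
    if not (0.0 < alpha < 1.0):
        raise GeometryError(f"alpha must lie in (0, 1), got {alpha}")
    if points.n < 3:
        raise GeometryError("need at least 3 points")
    mean = points.points.mean(axis=0)
    S = np.cov(points.points, rowvar=False)
    det = float(np.linalg.det(S))
    if not np.isfinite(det) or det <= 0.0:
        raise GeometryError("sample covariance is singular")
    L = np.linalg.cholesky(S)
    q = chi2.ppf(1.0 - alpha, df=2)
    t = np.linspace(0.0, 2.0 * np.pi, n_arc, endpoint=False)
    circle = np.sqrt(q) * np.column_stack([np.cos(t), np.sin(t)])
    verts = mean + circle @ L.T
    return ConvexRegion(vertices=_canonicalize(verts), source_alpha_dir=alpha)


def peel_depths(points: PointSet) -> np.ndarray:
    """Convex-hull peeling depth index for every point.

    The outermost hull layer gets index 1; its points are removed and the
    hull of the remainder gets index 2, and so on until every point is
    indexed — a center-outward ordering of the cloud.  Points lying on a
    hull's boundary (including non-vertex collinear ones) belong to that
    layer.
    """
    pts = points.points
    n = pts.shape[0]
    depth = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    layer = 0
    while remaining.size > 0:
        layer += 1
        sub = pts[remaining]
        if remaining.size <= 2:
            depth[remaining] = layer
            break
        try:
            hull = ConvexHull(sub)
        except QhullError:
            # collinear remainder: one degenerate final layer
            depth[remaining] = layer
            break
        # on-boundary test via the hull's facet equations
        margins = sub @ hull.equations[:, :2].T + hull.equations[:, 2]
        scale = max(1.0, float(np.abs(sub).max()))
        on_layer = margins.max(axis=1) >= -1e-9 * scale
        depth[remaining[on_layer]] = layer
        remaining = remaining[~on_layer]
    return depth


def convex_hull_peeling_region(points: PointSet, alpha: float = 0.05) -> ConvexRegion:
    """Confidence region by classical convex hull peeling.

    Hull layers are peeled from the outside in, accumulating the removed
    fraction of points; peeling stops before the layer whose removal would
    push the cumulative removed fraction above ``alpha``.  The region is the
    convex hull of the survivors, so the realized exclusion rate is always
    at most ``alpha`` (whole layers are excluded or kept together).
    """
    if not (0.0 <= alpha < 1.0):
        raise GeometryError(f"alpha must lie in [0, 1), got {alpha}")
    if points.n < 3:
        raise GeometryError("need at least 3 points")
    depth = peel_depths(points)
    n = points.n
    removed = 0
    layer = 1
    max_depth = depth.max()
    while layer <= max_depth:
        layer_size = int(np.sum(depth == layer))
        if (removed + layer_size) / n > alpha:
            break
        # never peel down to fewer than 3 survivors
        if n - removed - layer_size < 3:
            break
        removed += layer_size
        layer += 1
    survivors = points.points[depth >= layer]
    try:
        hull = ConvexHull(survivors)
        verts = survivors[hull.vertices]
    except QhullError:
        warnings.warn(
            "surviving points are collinear; degenerate hull",
            DegenerateDataWarning,
            stacklevel=2,
        )
        # degenerate zero-area triangle over the collinear extremes
        order = np.lexsort((survivors[:, 1], survivors[:, 0]))
        lo, hi = survivors[order[0]], survivors[order[-1]]
        verts = np.array([lo, hi, 0.5 * (lo + hi)])
    return ConvexRegion(vertices=_canonicalize(verts), source_alpha_dir=alpha)
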