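"""Directional distances, empirical quantiles, quantile bands and the
convex confidence polygon.

A *reference line* is a line through the origin at angle ``theta`` from the
horizontal axis, with ``theta`` restricted to ``[0, pi)`` since ``theta`` and
``theta + pi`` describe the same line.  The signed perpendicular distance of a
point ``(x, y)`` to that line is

    d = y * cos(theta) - x * sin(theta)

(positive above the line for ``theta = 0``).  Lines are always represented by
their unit normal ``(-sin theta, cos theta)`` and a scalar offset, so vertical
reference lines need no special case.

A *directional band* at per-direction level ``alpha_dir`` is the slab between
the ``alpha_dir/2`` and ``1 - alpha_dir/2`` empirical quantiles of the signed
distances.  Intersecting the slabs of a full direction grid yields a convex
polygon — the confidence region before calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointSet",
    "DirectionGrid",
    "DirectionalBand",
    "ConvexRegion",
    "GeometryError",
    "DegenerateDataWarning",
    "signed_distances",
    "empirical_quantile",
    "directional_band",
    "region_from_bands",
    "adjacent_crossover",
    "contains",
    "clip_polygon_halfplane",
]


class GeometryError(ValueError):
    """Raised for invalid geometric inputs or an empty region."""


class DegenerateDataWarning(UserWarning):
    """Issued for zero-width bands / collinear point sets."""


@dataclass(frozen=True)
class PointSet:
    """An ``(n, 2)`` cloud of paired observations ``(x_i, y_i)``.

    Typically the rows are bootstrap replicates of two parameter estimates.
    Coordinates must be finite; region construction additionally requires
    ``n >= 3``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError(
                f"expected an (n, 2) array of points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise GeometryError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class DirectionGrid:
    """An ordered grid of reference-line angles on ``[0, pi)``.

    ``delta`` is the spacing between adjacent directions; for the default
    equally spaced grid ``delta = pi / K``.  The slopes of the reference
    lines increase monotonically as the grid is traversed, which is the
    rotation convention the band construction assumes.
    """

    angles: np.ndarray

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        if ang.ndim != 1 or ang.size == 0:
            raise GeometryError("angles must be a nonempty 1-D sequence")
        if np.any(ang < 0.0) or np.any(ang >= np.pi):
            raise GeometryError("all angles must lie in [0, pi)")
        if ang.size > 1 and np.any(np.diff(ang) <= 0):
            raise GeometryError("angles must be strictly increasing")
        object.__setattr__(self, "angles", ang)

    @classmethod
    def equally_spaced(cls, K: int) -> "DirectionGrid":
        """K equally spaced directions ``theta_k = k * pi / K``."""
        if K < 1:
            raise GeometryError("K must be >= 1")
        return cls(np.arange(K) * np.pi / K)

    @property
    def K(self) -> int:
        return self.angles.size

    @property
    def delta(self) -> float:
        """Angular spacing (pi / K for an equally spaced grid)."""
        if self.K == 1:
            return np.pi
        return float(self.angles[1] - self.angles[0])


@dataclass(frozen=True)
class DirectionalBand:
    """The two-sided quantile band for one direction.

    ``B_l`` and ``B_u`` are the lower and upper signed-distance boundaries
    (the ``alpha_dir/2`` and ``1 - alpha_dir/2`` empirical percentiles);
    ``S_theta`` indexes the points strictly outside the band and
    ``m_theta = |S_theta|``.
    """

    theta: float
    alpha_dir: float
    B_l: float
    B_u: float
    S_theta: np.ndarray = field(repr=False)

    @property
    def m_theta(self) -> int:
        return int(self.S_theta.size)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the reference line, ``(-sin theta, cos theta)``."""
        return np.array([-np.sin(self.theta), np.cos(self.theta)])


@dataclass(frozen=True)
class ConvexRegion:
    """A convex confidence polygon with counter-clockwise vertices.

    Built as the intersection of the 2K half-planes of a band family; the
    vertex count therefore never exceeds 2K.  ``source_alpha_dir`` records
    the per-direction level the bands were cut at.
    """

    vertices: np.ndarray
    source_alpha_dir: float | None = None
    n_directions: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError(
                f"a polygon needs >= 3 (x, y) vertices, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise GeometryError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        """Polygon area by the shoelace formula (positive for CCW rings)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def signed_distances(points: PointSet | np.ndarray, theta: float) -> np.ndarray:
    """Signed perpendicular distances to the reference line at ``theta``.

    Parameters
    ----------
    points
        A :class:`PointSet` or a raw ``(n, 2)`` array.
    theta
        Reference-line angle in ``[0, pi)``.

    Returns
    -------
    Length-n vector ``d_i = y_i cos(theta) - x_i sin(theta)``.
    """
    if not (0.0 <= theta < np.pi):
        raise GeometryError(f"theta must lie in [0, pi), got {theta}")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float)
    if not np.all(np.isfinite(pts)):
        raise GeometryError("point coordinates must be finite")
    return pts[:, 1] * np.cos(theta) - pts[:, 0] * np.sin(theta)


def empirical_quantile(values: np.ndarray, p: float) -> float:
    """Empirical quantile by nearest-rank linear interpolation.

    Sorts ascending and interpolates linearly between the order statistics
    bracketing the target rank ``p * (n - 1) + 1``; ``p = 0`` returns the
    minimum and ``p = 1`` the maximum.  This is the classical interpolated
    percentile (numpy's ``linear`` method); all common percentile
    definitions converge for large n.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise GeometryError("cannot take a quantile of an empty sample")
    if np.any(np.isnan(v)):
        raise GeometryError("NaN present in quantile input")
    if not (0.0 <= p <= 1.0):
        raise GeometryError(f"p must lie in [0, 1], got {p}")
    return _quantile_sorted(np.sort(v), p)


def _quantile_sorted(sorted_v: np.ndarray, p: float) -> float:
    """Interpolated quantile of an already ascending-sorted vector."""
    n = sorted_v.size
    h = p * (n - 1)  # zero-based fractional rank
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    frac = h - lo
    return float(sorted_v[lo] * (1.0 - frac) + sorted_v[hi] * frac)


def directional_band(
    points: PointSet, theta: float, alpha_dir: float
) -> DirectionalBand:
    """Cut the two-sided empirical quantile band in direction ``theta``.

    The band spans the ``alpha_dir/2`` to ``1 - alpha_dir/2`` quantiles of
    the signed distances; points exactly on a boundary count as inside
    (conservative under ties), so the out-of-band fraction ``m_theta / n``
    approximates ``alpha_dir`` from below.
    """
    if not (0.0 < alpha_dir < 1.0):
        raise GeometryError(f"alpha_dir must lie in (0, 1), got {alpha_dir}")
    d = signed_distances(points, theta)
    s = np.sort(d)
    b_l = _quantile_sorted(s, alpha_dir / 2.0)
    b_u = _quantile_sorted(s, 1.0 - alpha_dir / 2.0)
    if b_u - b_l <= 0.0:
        warnings.warn(
            f"zero-width band at theta={theta:.4f} (degenerate distances)",
            DegenerateDataWarning,
            stacklevel=2,
        )
    outside = np.flatnonzero((d < b_l) | (d > b_u))
    return DirectionalBand(
        theta=float(theta),
        alpha_dir=float(alpha_dir),
        B_l=b_l,
        B_u=b_u,
        S_theta=outside,
    )


def clip_polygon_halfplane(
    poly: np.ndarray, normal: np.ndarray, offset: float, keep_leq: bool
) -> np.ndarray:
    """Sutherland–Hodgman clip of a polygon by one half-plane.

    Keeps the side ``normal . p <= offset`` when ``keep_leq`` else the side
    ``normal . p >= offset``.  Returns the (possibly empty) clipped vertex
    ring.
    """
    if poly.shape[0] == 0:
        return poly
    s = normal @ poly.T - offset
    if not keep_leq:
        s = -s
    out: list[np.ndarray] = []
    m = poly.shape[0]
    for i in range(m):
        j = (i + 1) % m
        inside_i, inside_j = s[i] <= 0.0, s[j] <= 0.0
        if inside_i:
            out.append(poly[i])
        if inside_i != inside_j:
            t = s[i] / (s[i] - s[j])
            out.append(poly[i] + t * (poly[j] - poly[i]))
    return np.array(out) if out else np.empty((0, 2))


def _canonicalize(vertices: np.ndarray) -> np.ndarray:
    """CCW order starting from the smallest centroid angle; drop duplicates."""
    c = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0])
    order = np.argsort(ang, kind="stable")
    v = vertices[order]
    # merge numerically duplicate consecutive vertices
    scale = max(1.0, float(np.abs(v).max()))
    keep = [0]
    for i in range(1, v.shape[0]):
        if np.abs(v[i] - v[keep[-1]]).max() > 1e-12 * scale:
            keep.append(i)
    if len(keep) > 1 and np.abs(v[keep[-1]] - v[keep[0]]).max() <= 1e-12 * scale:
        keep.pop()
    return v[keep]


def region_from_bands(
    bands: list[DirectionalBand],
    bounding_margin: float = 4.0,
    bounding_radius: float | None = None,
) -> ConvexRegion:
    """Intersect a family of directional bands into the confidence polygon.

    Each band contributes the slab ``B_l <= normal . p <= B_u``; the polygon
    is obtained by clipping a generous bounding rectangle by every
    half-plane in turn, which is robust to redundant (inactive) boundaries.
    For a single band the result is the slab clipped to the bounding box;
    pass ``bounding_radius`` (e.g. the data extent) to control the box when
    the slab intersection is unbounded.

    Raises
    ------
    GeometryError
        If the intersection of the bands is empty.
    """
    if not bands:
        raise GeometryError("at least one band is required")
    # bounding square comfortably containing every slab intersection of
    # interest: radius = largest |boundary offset| * margin
    r = max(max(abs(b.B_l), abs(b.B_u)) for b in bands)
    r = (r + 1.0) * bounding_margin
    if bounding_radius is not None:
        r = max(r, float(bounding_radius))
    poly = np.array([[-r, -r], [r, -r], [r, r], [-r, r]], dtype=float)
    for b in bands:
        u = b.normal
        poly = clip_polygon_halfplane(poly, u, b.B_u, keep_leq=True)
        poly = clip_polygon_halfplane(poly, u, b.B_l, keep_leq=False)
        if poly.shape[0] == 0:
            raise GeometryError(
                "band intersection is empty (pathological boundaries)"
            )
    if poly.shape[0] < 3:
        raise GeometryError("band intersection degenerated below a polygon")
    v = _canonicalize(poly)
    if v.shape[0] < 3:
        raise GeometryError("band intersection degenerated below a polygon")
    region = ConvexRegion(
        vertices=v,
        source_alpha_dir=bands[0].alpha_dir,
        n_directions=len(bands),
    )
    if region.area <= 0.0:
        warnings.warn(
            "zero-area region (collinear data)", DegenerateDataWarning,
            stacklevel=2,
        )
    return region


def adjacent_crossover(
    theta: float, delta: float, c1: float, c2: float
) -> np.ndarray:
    """Crossover point of two adjacent boundary lines.

    The boundary at angle ``theta`` with signed offset ``c1`` is the line
    ``y cos(theta) - x sin(theta) = c1``; likewise at ``theta + delta`` with
    offset ``c2``.  Solves the 2x2 linear system for their intersection.
    Used as a verification identity for polygon vertices when both adjacent
    constraints are active.
    """
    a = np.array(
        [
            [-np.sin(theta), np.cos(theta)],
            [-np.sin(theta + delta), np.cos(theta + delta)],
        ]
    )
    return np.linalg.solve(a, np.array([c1, c2]))


def contains(
    region: ConvexRegion, point: np.ndarray, rtol: float = 1e-9
) -> bool | np.ndarray:
    """Point-in-convex-polygon test (boundary counts as inside).

    Accepts a single ``(x, y)`` pair or an ``(m, 2)`` array; vectorized over
    rows.  A point is inside iff it lies on the inner side of every edge of
    the CCW ring, up to a relative tolerance that absorbs roundoff on edges.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    v = region.vertices
    e = np.roll(v, -1, axis=0) - v  # edge vectors, CCW
    scale = max(1.0, float(np.abs(v).max()))
    # cross(edge, point - vertex) >= 0 for all edges <=> inside
    cross = (
        e[None, :, 0] * (p[:, None, 1] - v[None, :, 1])
        - e[None, :, 1] * (p[:, None, 0] - v[None, :, 0])
    )
    inside = np.all(cross >= -rtol * scale * scale, axis=1)
    return bool(inside[0]) if single else inside
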