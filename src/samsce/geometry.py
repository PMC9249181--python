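"""Polygon measurements for wall-node rings.

A cell's wall is an ordered, closed ring of 2D points (the closing edge from
the last point back to the first is implicit).  All lengths are in micrometres.
The shape descriptors defined here follow the convention that x is the radial
direction and y the apical-basal direction, so an orientation of 0 deg means a
radially elongated cell and 90 deg an apical-basally elongated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import AreaWindowError, InvalidGeometryError

#: Even-area constraint on division: larger/smaller daughter area ratio.
AREA_RATIO_MAX = 1.11


def _as_ring(ring) -> np.ndarray:
    pts = np.asarray(ring, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidGeometryError(
            f"a polygon ring needs >= 3 two-dimensional points, got shape {pts.shape}"
        )
    return pts


def signed_area(ring) -> float:
    """Shoelace signed area (positive for counter-clockwise winding)."""
    pts = _as_ring(ring)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(ring) -> float:
    """Area enclosed by the ring, independent of winding direction."""
    return abs(signed_area(ring))


def polygon_centroid(ring) -> np.ndarray:
    """Area centroid of the polygon (falls back to vertex mean if degenerate)."""
    pts = _as_ring(ring)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def pair_split_areas(ring) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Areas of the two parts produced by joining every node pair.

    Returns ``(a_first, a_second, valid)`` where for i < j ``a_first[i, j]``
    is the area of the sub-polygon ``ring[i..j]`` closed by the chord j->i,
    ``a_second`` the complementary area, and ``valid`` marks pairs for which
    both parts have at least three vertices.  Entries with i >= j are invalid.
    """
    pts = _as_ring(ring)
    n = len(pts)
    x, y = pts[:, 0], pts[:, 1]
    edge_cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    prefix = np.concatenate([[0.0], np.cumsum(edge_cross[:-1])])  # prefix[k] = sum_{t<k}
    # chord term cross(P_j, P_i) for all pairs
    chord = np.subtract.outer(prefix, prefix).T  # [i, j] -> prefix[j] - prefix[i]
    close = np.outer(x, y).T - np.outer(y, x).T  # [i, j] -> x_j*y_i - y_j*x_i
    a1 = 0.5 * np.abs(chord + close)
    total = polygon_area(pts)
    a2 = total - a1
    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    span = j_idx - i_idx
    valid = (span >= 2) & (span <= n - 2)
    return a1, a2, valid


@dataclass(frozen=True)
class AxisResult:
    """A node-pair axis through a cell."""

    node_a: int
    node_b: int
    length: float
    area_ratio: float  # larger/smaller split area (short axis only; nan for long)
    window: float  # area window actually used (after any widening)
    widened: bool


def _shapely_polygon(pts: np.ndarray) -> shapely.Polygon:
    return shapely.Polygon(pts)


def short_axis(
    ring,
    ratio_max: float = AREA_RATIO_MAX,
    widen_step: float = 0.05,
    max_window: float = 3.0,
    check_containment: bool = True,
) -> AxisResult:
    """Shortest node-pair chord that divides the polygon area evenly.

    Implements the shortest-wall (Errera) construction: among all wall-node
    pairs whose connecting segment splits the polygon into parts with
    larger/smaller area ratio <= ``ratio_max``, return the pair at minimal
    Euclidean distance.  If no pair satisfies the window it is widened in
    steps of ``widen_step`` (the result records this).  Ties are broken by the
    smallest ``node_a`` ring index, then smallest ``node_b``.
    """
    pts = _as_ring(ring)
    n = len(pts)
    if n < 8:
        raise InvalidGeometryError(f"short_axis needs a ring of >= 8 nodes, got {n}")
    a1, a2, valid = pair_split_areas(pts)
    small = np.minimum(a1, a2)
    big = np.maximum(a1, a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(small > 1e-12, big / np.maximum(small, 1e-300), np.inf)
    diff = pts[None, :, :] - pts[:, None, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    poly = _shapely_polygon(pts) if check_containment else None

    window = ratio_max
    widened = False
    while window <= max_window + 1e-9:
        mask = valid & (ratio <= window)
        if mask.any():
            ii, jj = np.nonzero(mask)
            order = np.lexsort((jj, ii, dist[ii, jj]))
            for k in order:
                i, j = int(ii[k]), int(jj[k])
                if poly is not None:
                    seg = shapely.LineString([pts[i], pts[j]])
                    if not seg.covered_by(poly):
                        continue
                return AxisResult(i, j, float(dist[i, j]), float(ratio[i, j]), window, widened)
        window += widen_step
        widened = True
    raise AreaWindowError(
        f"no node pair divides the area within ratio <= {max_window}"
    )


def long_axis(ring, short: AxisResult) -> AxisResult:
    """Long axis from the perpendicular bisector of the short axis.

    The perpendicular bisector of the short-axis chord is constructed; the
    wall node nearest to the bisector on each side of the short axis is taken,
    and the pair forms the long axis.
    """
    pts = _as_ring(ring)
    a, b = pts[short.node_a], pts[short.node_b]
    seg = b - a
    norm = np.hypot(*seg)
    if norm < 1e-12:
        raise InvalidGeometryError("short axis has zero length")
    s_hat = seg / norm  # along the short axis
    n_hat = np.array([-s_hat[1], s_hat[0]])  # normal: side of the short axis
    mid = 0.5 * (a + b)
    rel = pts - mid
    side = rel @ n_hat  # signed distance from the short-axis line
    to_bisector = np.abs(rel @ s_hat)  # distance from the perpendicular bisector
    plus = np.nonzero(side > 1e-12)[0]
    minus = np.nonzero(side < -1e-12)[0]
    if len(plus) == 0 or len(minus) == 0:
        raise InvalidGeometryError("all wall nodes lie on one side of the short axis")
    k_plus = int(plus[np.argmin(to_bisector[plus])])
    k_minus = int(minus[np.argmin(to_bisector[minus])])
    length = float(np.hypot(*(pts[k_plus] - pts[k_minus])))
    return AxisResult(k_plus, k_minus, length, float("nan"), short.window, False)


def aspect_ratio_and_orientation(ring, **short_kwargs) -> tuple[float, float]:
    """(aspect ratio >= 1, orientation in degrees within [0, 90]).

    The aspect ratio is the long-axis length over the short-axis length; the
    orientation is the positive acute angle between the horizontal (radial)
    direction and the long axis.  If the constructed "long" axis comes out
    shorter than the short-axis chord (possible for nearly isotropic rings),
    the roles are swapped so the reported ratio stays >= 1.
    """
    pts = _as_ring(ring)
    s = short_axis(pts, **short_kwargs)
    l = long_axis(pts, s)
    if s.length < 1e-12:
        raise InvalidGeometryError("zero-length short axis")
    if l.length >= s.length:
        ratio = l.length / s.length
        vec = pts[l.node_b] - pts[l.node_a]
    else:
        ratio = s.length / l.length
        vec = pts[s.node_b] - pts[s.node_a]
    angle = float(np.degrees(np.arctan2(abs(vec[1]), abs(vec[0]))))
    return ratio, angle


def is_simple_ring(ring) -> bool:
    """True if the closed ring is a simple (non-self-intersecting) polygon."""
    pts = _as_ring(ring)
    return bool(shapely.LinearRing(pts).is_simple) and polygon_area(pts) > 1e-12


def points_in_polygon(ring, points) -> np.ndarray:
    """Boolean mask of which query points lie inside (or on) the ring."""
    pts = _as_ring(ring)
    q = np.atleast_2d(np.asarray(points, dtype=float))
    poly = _shapely_polygon(pts)
    return shapely.covers(poly, shapely.points(q[:, 0], q[:, 1]))
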