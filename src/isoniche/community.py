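"""Layman community metrics on group centroids in (δ¹³C, δ¹⁵N) space.

A "community" is a set of group centroids — e.g. per-individual scute
centroids within a lifestage, or lifestage centroids within a population.
The metrics summarise the spread and packing of the community:

=========  ===============================================================
dNR        δ¹⁵N range of the centroids (‰)
dCR        δ¹³C range of the centroids (‰)
HA         area of the convex hull of the centroids (‰²)
CD         mean Euclidean distance from each centroid to the centroid of
           the community (‰)
NND        mean distance from each centroid to its nearest neighbour (‰)
SDNND      sample standard deviation of those nearest-neighbour distances
=========  ===============================================================

The convex hull (Andrew monotone chain) and the shoelace polygon area are
implemented here directly; they are the computational core of the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LaymanMetrics", "convex_hull", "polygon_area", "layman_metrics"]


def _cross(o, a, b) -> float:
    """z component of (a−o) × (b−o); > 0 for a counter-clockwise turn."""
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> np.ndarray:
    """Convex hull of 2-D points, counter-clockwise (monotone chain).

    Collinear points interior to hull edges are dropped, so a fully
    collinear input yields a degenerate 2-vertex "hull" (the two extreme
    points) with zero area.  Duplicated points are tolerated.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) == 0:
        raise ValueError("need at least one point")
    uniq = np.unique(pts, axis=0)  # lexicographic sort on (x, y)
    if len(uniq) == 1:
        return uniq
    if len(uniq) == 2:
        return uniq

    def half(seq):
        chain: list[np.ndarray] = []
        for p in seq:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(uniq)
    upper = half(uniq[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) == 2 and np.allclose(hull[0], hull[1]):
        hull = hull[:1]
    return hull


def _segments_intersect(p1, p2, p3, p4) -> bool:
    d1 = _cross(p3, p4, p1)
    d2 = _cross(p3, p4, p2)
    d3 = _cross(p1, p2, p3)
    d4 = _cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def polygon_area(polygon, check_simple: bool = True) -> float:
    """Absolute shoelace area of a simple polygon.

    ``check_simple`` runs an O(n²) non-adjacent-edge intersection test and
    raises on self-intersecting input; disable it for polygons that are
    convex by construction.
    """
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    if n < 3:
        return 0.0
    if check_simple and n <= 2048:
        nxt = np.roll(np.arange(n), -1)
        for i in range(n):
            for j in range(i + 1, n):
                if j == i or nxt[i] == j or nxt[j] == i:
                    continue
                if _segments_intersect(poly[i], poly[nxt[i]], poly[j], poly[nxt[j]]):
                    raise ValueError(f"self-intersecting polygon (edges {i} and {j})")
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class LaymanMetrics:
    """Community metrics for one set of group centroids (see module doc)."""

    dNR: float
    dCR: float
    HA: float
    CD: float
    NND: float
    SDNND: float
    n_groups: int

    def as_dict(self) -> dict:
        return {
            "dNR": self.dNR, "dCR": self.dCR, "HA": self.HA,
            "NND": self.NND, "SDNND": self.SDNND, "CD": self.CD,
            "n_groups": self.n_groups,
        }


def layman_metrics(centroids, hull_centroid: str = "mean") -> LaymanMetrics:
    """Layman metrics for a community of (δ¹³C, δ¹⁵N) group centroids.

    Parameters
    ----------
    centroids
        (n, 2) array of group centroids, columns (δ¹³C, δ¹⁵N).
    hull_centroid
        Anchor of the centroid-dispersion metric: ``"mean"`` (arithmetic
        mean of the group centroids, the conventional choice) or
        ``"polygon"`` (area-weighted centroid of the convex hull).

    Requires at least two centroids; HA is 0 for fewer than three or for
    collinear centroids.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array of (d13C, d15N)")
    n = len(pts)
    if n < 2:
        raise ValueError("a community needs at least 2 group centroids")

    dCR = float(pts[:, 0].max() - pts[:, 0].min())
    dNR = float(pts[:, 1].max() - pts[:, 1].min())

    hull = convex_hull(pts)
    HA = polygon_area(hull, check_simple=False) if len(hull) >= 3 else 0.0

    if hull_centroid == "mean":
        anchor = pts.mean(axis=0)
    elif hull_centroid == "polygon":
        anchor = _polygon_centroid(hull) if len(hull) >= 3 else pts.mean(axis=0)
    else:
        raise ValueError("hull_centroid must be 'mean' or 'polygon'")
    CD = float(np.mean(np.hypot(*(pts - anchor).T)))

    d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    np.fill_diagonal(d, np.inf)
    nnd = d.min(axis=1)
    NND = float(nnd.mean())
    SDNND = float(np.std(nnd, ddof=1)) if n > 1 else 0.0

    return LaymanMetrics(dNR=dNR, dCR=dCR, HA=HA, CD=CD, NND=NND, SDNND=SDNND, n_groups=n)


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    c = x * yn - xn * y
    a = c.sum() / 2.0
    if a == 0:
        return poly.mean(axis=0)
    return np.array([((x + xn) * c).sum(), ((y + yn) * c).sum()]) / (6.0 * a)
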