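"""Containment-polygon geometry for cardiorespiratory scatterplots.

Each (driver, sub-space) scatterplot of (ΔBBI, ΔTT) points is summarised
by a convex polygon containing 95% of the points: the 95% of points
closest to the cloud centroid are kept and their convex hull is taken.
The polygon is characterized by its shoelace area and centroid, and by
the fan of triangles joining the centroid to consecutive vertex pairs —
per-triangle area Ar_i, point occupancy, the angle β_i at the centroid
and the mean base angle θ_i at the vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["shoelace", "Triangle", "PolygonModel", "fit_polygon"]


def shoelace(vertices: np.ndarray) -> tuple[float, float, float]:
    """Polygon area and centroid by the shoelace (surveyor's) formula.

    A  = |½ Σ_i (x_i y_{i+1} − x_{i+1} y_i)|
    Cx = 1/(6A_signed) Σ_i (x_i + x_{i+1})(x_i y_{i+1} − x_{i+1} y_i)
    Cy = 1/(6A_signed) Σ_i (y_i + y_{i+1})(x_i y_{i+1} − x_{i+1} y_i)

    Orientation-invariant: clockwise and counter-clockwise vertex orders
    give the same (A, Cx, Cy).  For a zero-area (collinear) polygon the
    centroid falls back to the vertex mean.

    Returns
    -------
    (area, cx, cy)
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a_signed = 0.5 * cross.sum()
    if a_signed == 0:
        return 0.0, float(x.mean()), float(y.mean())
    cx = ((x + x1) * cross).sum() / (6.0 * a_signed)
    cy = ((y + y1) * cross).sum() / (6.0 * a_signed)
    return float(abs(a_signed)), float(cx), float(cy)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Interior angle at vertex ``b`` of triangle (a, b, c), degrees."""
    u, w = a - b, c - b
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        return float("nan")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class Triangle:
    """One fan triangle (centroid, V_i, V_{i+1}) of the polygon."""

    area: float
    occupancy: int
    beta_deg: float   # angle at the centroid
    theta_deg: float  # mean of the two base angles at V_i and V_{i+1}
    degenerate: bool = False


@dataclass
class PolygonModel:
    """Fitted containment polygon with its triangle-fan morphology.

    Attributes
    ----------
    vertices : (m, 2) ndarray
        Hull vertices in counter-clockwise order.
    centroid : (cx, cy)
    area : float
        Shoelace area (normalized units²).
    triangles : list of Triangle
    kept : (k, 2) ndarray
        The points retained by the containment rule (all inside or on
        the hull by construction).
    degenerate : bool
        True when fewer than 4 points or a collinear cloud prevented a
        proper fit; area is 0 and morphology summaries are NaN.
    """

    vertices: np.ndarray
    centroid: tuple[float, float]
    area: float
    triangles: list[Triangle] = field(default_factory=list)
    kept: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    containment: float = 0.95
    degenerate: bool = False

    @property
    def n_vertices(self) -> int:
        return 0 if self.degenerate else int(self.vertices.shape[0])

    def _tri_values(self, attr: str) -> np.ndarray:
        vals = [getattr(t, attr) for t in self.triangles if not t.degenerate]
        return np.asarray(vals, dtype=float)

    @property
    def mean_triangle_area(self) -> float:
        v = self._tri_values("area")
        return float(v.mean()) if v.size else float("nan")

    @property
    def mean_beta_deg(self) -> float:
        v = self._tri_values("beta_deg")
        return float(v.mean()) if v.size else float("nan")

    @property
    def mean_theta_deg(self) -> float:
        v = self._tri_values("theta_deg")
        return float(v.mean()) if v.size else float("nan")

    @property
    def mean_occupancy(self) -> float:
        v = self._tri_values("occupancy")
        return float(v.mean()) if v.size else float("nan")

    @classmethod
    def fit(cls, points: np.ndarray, containment: float = 0.95) -> "PolygonModel":
        """Fit the containment polygon to a 2-D point cloud.

        The ⌈containment·n⌉ points nearest (Euclidean) to the cloud mean
        are retained; the polygon is their convex hull.  Distance ties
        resolve by point index, so the fit is deterministic.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if not 0 < containment <= 1:
            raise ValueError("containment must lie in (0, 1]")
        n = pts.shape[0]
        if n < 4:
            return cls._degenerate(pts, containment)
        center = pts.mean(axis=0)
        dist = np.linalg.norm(pts - center, axis=1)
        k = int(np.ceil(containment * n))
        order = np.argsort(dist, kind="stable")
        kept = pts[np.sort(order[:k])]
        try:
            hull = ConvexHull(kept)
        except QhullError:
            return cls._degenerate(kept, containment)
        verts = kept[hull.vertices]  # CCW order in 2-D
        area, cx, cy = shoelace(verts)
        if area == 0:
            return cls._degenerate(kept, containment)
        model = cls(verts, (cx, cy), area, [], kept, containment, False)
        model.triangles = _triangle_fan(model)
        return model

    @classmethod
    def _degenerate(cls, pts: np.ndarray, containment: float) -> "PolygonModel":
        c = pts.mean(axis=0) if pts.size else np.array([np.nan, np.nan])
        return cls(
            np.empty((0, 2)), (float(c[0]), float(c[1])), 0.0,
            [], pts, containment, True,
        )


def fit_polygon(points: np.ndarray, containment: float = 0.95) -> PolygonModel:
    """Functional alias for :meth:`PolygonModel.fit`."""
    return PolygonModel.fit(points, containment)


def _triangle_fan(model: PolygonModel) -> list[Triangle]:
    """Decompose the polygon into centroid-fan triangles with occupancy.

    Every kept point is assigned to exactly one triangle; points on a
    shared edge (or at the centroid) go to the lowest-index triangle.
    """
    c = np.asarray(model.centroid)
    verts = model.vertices
    m = verts.shape[0]
    pts = model.kept
    assigned = np.zeros(pts.shape[0], dtype=bool)
    tol = 1e-12 * max(1.0, float(np.abs(verts).max()))
    out: list[Triangle] = []
    for i in range(m):
        v1, v2 = verts[i], verts[(i + 1) % m]
        if np.linalg.norm(v1 - c) < tol or np.linalg.norm(v2 - c) < tol:
            out.append(Triangle(float("nan"), 0, float("nan"), float("nan"), True))
            continue
        tri_area, _, _ = shoelace(np.array([c, v1, v2]))
        beta = _angle(v1, c, v2)
        theta = 0.5 * (_angle(c, v1, v2) + _angle(v1, v2, c))
        occ = 0
        if pts.size:
            inside = _in_triangle(pts, c, v1, v2, tol) & ~assigned
            occ = int(inside.sum())
            assigned |= inside
        out.append(Triangle(float(tri_area), occ, beta, theta))
    return out


def _in_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 tol: float) -> np.ndarray:
    """Vectorized point-in-triangle test, boundary-inclusive."""
    def cross(o, u, q):
        return (u[0] - o[0]) * (q[:, 1] - o[1]) - (u[1] - o[1]) * (q[:, 0] - o[0])

    d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
    has_neg = (d1 < -tol) | (d2 < -tol) | (d3 < -tol)
    has_pos = (d1 > tol) | (d2 > tol) | (d3 > tol)
    return ~(has_neg & has_pos)
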