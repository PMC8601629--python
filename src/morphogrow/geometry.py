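"""Boundary curves and interior quadrature meshes for 2D cell clusters.

The cluster outline is a closed, simple, counterclockwise polygon of marker
points in rescaled length units (x̃ = √(γ/D)·x).  The interior is covered by a
grid-of-cells quadrature mesh: full cells carry weight h², cells straddling the
boundary are clipped against the polygon so that the weights sum to the exact
polygon area.  The mesh is regenerated from the polygon every time step; no
mesh state is advected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.polygon import orient


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


# ---------------------------------------------------------------------------
# boundary curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryCurve:
    """Closed, simple, counterclockwise polygon of (x̃, ỹ) marker points.

    The closing segment from ``points[-1]`` back to ``points[0]`` is implicit.
    """

    points: np.ndarray  # (M, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError("boundary curve needs an (M>=3, 2) point array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def is_simple(self) -> bool:
        return LineString(np.vstack([self.points, self.points[:1]])).is_simple

    def segment_lengths(self) -> np.ndarray:
        """Length of segment i -> i+1 (cyclic)."""
        d = np.roll(self.points, -1, axis=0) - self.points
        return np.hypot(d[:, 0], d[:, 1])

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def point_spacing(self) -> np.ndarray:
        """Arc length attributed to each marker (mean of adjacent segments)."""
        seg = self.segment_lengths()
        return 0.5 * (seg + np.roll(seg, 1))


def polygon_area(curve: BoundaryCurve) -> float:
    """Signed shoelace area; positive for counterclockwise orientation.

    Raises for self-intersecting curves: the area of a non-simple polygon is
    not meaningful for the quadrature and flow solves downstream.
    """
    if not curve.is_simple():
        raise GeometryError("self-intersecting boundary curve")
    p = curve.points
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(curve: BoundaryCurve) -> np.ndarray:
    """Area centroid of the enclosed region."""
    c = Polygon(curve.points).centroid
    return np.array([c.x, c.y])


def outward_normals(curve: BoundaryCurve) -> np.ndarray:
    """Unit outward normal at each marker point.

    Tangents are central differences of the cyclic point sequence; for a
    counterclockwise curve the outward normal is the tangent rotated by -90°.
    """
    p = curve.points
    t = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
    norm = np.hypot(t[:, 0], t[:, 1])
    if np.any(norm < 1e-14):
        raise GeometryError("repeated boundary points give degenerate normals")
    t = t / norm[:, None]
    return np.column_stack([t[:, 1], -t[:, 0]])


def symmetrize_curve(curve: BoundaryCurve) -> BoundaryCurve:
    """Average the curve with its ỹ → −ỹ mirror image.

    Each marker is averaged with its projection onto the mirrored polygon,
    which damps the antisymmetric shape component without requiring any
    marker correspondence.  Used by the simulator to keep mirror-symmetric
    problems on the symmetric solution branch: the side-lobe competition
    transmitted through the inhibitor fields makes the symmetric state
    dynamically unstable, and marker-level noise would otherwise pick a side.
    """
    p = curve.points
    mirror = np.column_stack([p[:, 0], -p[:, 1]])[::-1]
    a = mirror
    ab = np.roll(mirror, -1, axis=0) - mirror
    L2 = np.maximum((ab * ab).sum(axis=1), 1e-30)
    diff = p[:, None, :] - a[None, :, :]
    t = np.clip((diff * ab[None, :, :]).sum(axis=2) / L2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = ((p[:, None, :] - proj) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    foot = proj[np.arange(len(p)), j]
    return BoundaryCurve(0.5 * (p + foot))


def signed_curvature(curve: BoundaryCurve) -> np.ndarray:
    """Discrete signed curvature at each marker (positive = convex, CCW).

    Turning angle between adjacent segments divided by the local arc length.
    """
    p = curve.points
    v1 = p - np.roll(p, 1, axis=0)
    v2 = np.roll(p, -1, axis=0) - p
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    dtheta = np.arctan2(cross, dot)
    return dtheta / np.maximum(curve.point_spacing(), 1e-14)


def resample_boundary(curve: BoundaryCurve, h: float) -> BoundaryCurve:
    """Redistribute markers at approximately equal arc spacing ≈ h.

    Interpolation is a periodic cubic spline through the existing markers
    (chord-length parametrized), so repeated resampling does not erode area
    the way chordal interpolation would.  The first marker is the anchor:
    resampling an already-uniform curve is the identity.
    """
    if h <= 0:
        raise GeometryError("target spacing h must be positive")
    from scipy.interpolate import CubicSpline

    p = curve.points
    closed = np.vstack([p, p[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    if np.any(seg < 1e-14):
        keep = np.concatenate([[True], seg[:-1] > 1e-14])
        closed = np.vstack([p[keep], p[keep][:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 4 * h:
        raise GeometryError("target spacing h is too large for this curve")
    n = max(int(round(total / h)), 8)
    targets = total * np.arange(n) / n
    spl = CubicSpline(s, closed, bc_type="periodic")
    pts = spl(targets)
    return BoundaryCurve(pts)


def _dense_closed(points: Iterable[Sequence[float]]) -> np.ndarray:
    return np.asarray(list(points), dtype=float)


def make_parabolic_cluster(x0: float, y0: float, h: float = 0.05) -> BoundaryCurve:
    """Parabolic cluster of initial length x0 and width y0.

    Bounds the region {0 ≤ x̃ ≤ x0, |ỹ| ≤ (y0/2)·√((x0 − x̃)/x0)}: a
    rightward-pointing parabola with its tip at (x0, 0), closed by the flat
    vertical back at x̃ = 0.  Analytic area is (2/3)·x0·y0.
    """
    if x0 <= 0 or y0 <= 0 or h <= 0:
        raise GeometryError("cluster dimensions and spacing must be positive")
    # dense parametrization in sqrt-space so points crowd near the tip, where
    # the parabola curves fastest; anchored AT the tip so that resampling
    # produces a marker set symmetric under ỹ -> -ỹ
    m = 2000
    u = np.linspace(0.0, 1.0, m)          # u = sqrt((x0-x)/x0), u=0 at the tip
    x = x0 * (1.0 - u**2)
    y = 0.5 * y0 * u
    upper = np.column_stack([x, y])                       # tip -> back (0, y0/2)
    back = np.column_stack([np.zeros(20), np.linspace(y0 / 2, -y0 / 2, 22)[1:-1]])
    lower = np.column_stack([x[::-1][:-1], -y[::-1][:-1]])  # back -> just before tip
    dense = BoundaryCurve(np.vstack([upper, back, lower]))
    return resample_boundary(dense, h)


def make_elliptical_cluster(x0: float, y0: float, h: float = 0.05) -> BoundaryCurve:
    """Elliptical cluster with semi-axes x0/2, y0/2, centered at (x0/2, 0).

    The tip sits at (x0, 0) to match the parabolic convention.
    """
    if x0 <= 0 or y0 <= 0 or h <= 0:
        raise GeometryError("cluster dimensions and spacing must be positive")
    m = 3000
    th = 2 * np.pi * np.arange(m) / m
    pts = np.column_stack([x0 / 2 + (x0 / 2) * np.cos(th), (y0 / 2) * np.sin(th)])
    # start at the tip, counterclockwise
    return resample_boundary(BoundaryCurve(pts), h)


# ---------------------------------------------------------------------------
# interior quadrature mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteriorMesh:
    """Quadrature nodes and weights covering the interior of a boundary curve.

    Nodes are centers of grid cells of size ``h_mesh`` lying inside the
    polygon; cells straddling the boundary are clipped, their node moved to
    the clipped region's interior and weight set to the clipped area.  ``ij``
    holds each node's integer grid index (for connected-component work on the
    raster) relative to ``origin``.
    """

    nodes: np.ndarray        # (K, 2)
    weights: np.ndarray      # (K,)
    ij: np.ndarray           # (K, 2) integer grid indices
    grid_shape: tuple        # (ni, nj)
    origin: np.ndarray       # (2,) lower-left corner of cell (0, 0)
    h_mesh: float

    def __len__(self) -> int:
        return len(self.nodes)

    def raster(self, mask: np.ndarray) -> np.ndarray:
        """Scatter a boolean per-node mask onto the (ni, nj) grid raster."""
        grid = np.zeros(self.grid_shape, dtype=bool)
        sel = np.asarray(mask, dtype=bool)
        grid[self.ij[sel, 0], self.ij[sel, 1]] = True
        return grid


def mesh_interior(curve: BoundaryCurve, h_mesh: float) -> InteriorMesh:
    """Cover the curve's interior with a clipped-grid quadrature mesh.

    Σ weights equals the polygon area to shapely's clipping precision, every
    node lies strictly inside the closed curve, and element diameters are at
    most √2·h_mesh.
    """
    if h_mesh <= 0:
        raise GeometryError("h_mesh must be positive")
    poly = Polygon(curve.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.geom_type != "Polygon":
        raise GeometryError("cannot mesh a degenerate polygon")

    xmin, ymin, xmax, ymax = poly.bounds
    # grid aligned to absolute multiples of h_mesh: deterministic in the lab frame
    i0 = int(np.floor(xmin / h_mesh)) - 1
    j0 = int(np.floor(ymin / h_mesh)) - 1
    i1 = int(np.ceil(xmax / h_mesh)) + 1
    j1 = int(np.ceil(ymax / h_mesh)) + 1
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    cx = (ii + 0.5) * h_mesh
    cy = (jj + 0.5) * h_mesh

    inside = shapely.contains_xy(poly, cx.ravel(), cy.ravel()).reshape(cx.shape)
    pts = shapely.points(np.column_stack([cx.ravel(), cy.ravel()]))
    dist = shapely.distance(pts, poly.exterior).reshape(cx.shape)

    margin = 0.5 * np.sqrt(2.0) * h_mesh
    full = inside & (dist > margin)
    near = dist <= margin

    nodes, weights, idx = [], [], []
    # full cells: weight h², node at center
    fi, fj = np.nonzero(full)
    nodes.append(np.column_stack([cx[full], cy[full]]))
    weights.append(np.full(fi.size, h_mesh**2))
    idx.append(np.column_stack([fi, fj]))

    # boundary cells: clip exactly
    ni_, nj_ = np.nonzero(near)
    tiny = 1e-9 * h_mesh**2
    for i, j in zip(ni_, nj_):
        x_lo = (ii[i, j]) * h_mesh
        y_lo = (jj[i, j]) * h_mesh
        cell = box(x_lo, y_lo, x_lo + h_mesh, y_lo + h_mesh)
        inter = cell.intersection(poly)
        if inter.is_empty or inter.area <= tiny:
            continue
        c = inter.centroid
        if not inter.contains(c):
            c = inter.representative_point()
        nodes.append(np.array([[c.x, c.y]]))
        weights.append(np.array([inter.area]))
        idx.append(np.array([[i, j]]))

    nodes_a = np.vstack(nodes)
    weights_a = np.concatenate(weights)
    ij_a = np.vstack(idx).astype(int)
    if len(nodes_a) == 0:
        raise GeometryError("meshing produced no interior nodes")
    return InteriorMesh(
        nodes=nodes_a,
        weights=weights_a,
        ij=ij_a,
        grid_shape=(i1 - i0, j1 - j0),
        origin=np.array([i0 * h_mesh, j0 * h_mesh]),
        h_mesh=float(h_mesh),
    )


# alias kept for discoverability: the mesh is the quadrature triangulation's role
triangulate_interior = mesh_interior


# ---------------------------------------------------------------------------
# cuts (regeneration experiments)
# ---------------------------------------------------------------------------

def apply_cut(curve: BoundaryCurve, cut: dict, h: float = 0.05) -> BoundaryCurve:
    """Remove the cluster tip along a cut locus and reclose the boundary.

    ``cut`` is either ``{"kind": "straight", "xc": float}`` — keep the bulk
    side x̃ ≤ xc, closing with a flat vertical face (sharp corners) — or
    ``{"kind": "elliptical", "center": (xc, yc), "semi_axes": (a, b)}`` —
    keep x̃ ≤ xc but retain a smooth convex elliptical cap bulging toward the
    removed tip.  The result is resampled to spacing ``h``.
    """
    poly = Polygon(curve.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    xmin, _, xmax, _ = poly.bounds
    big = max(xmax - xmin, poly.bounds[3] - poly.bounds[1]) * 10 + 10

    kind = cut.get("kind")
    if kind == "straight":
        xc = float(cut["xc"])
        if not (xmin < xc < xmax):
            raise GeometryError("straight cut misses the cluster")
        keep = box(xmin - 1, -big, xc, big)
        result = poly.intersection(keep)
    elif kind == "elliptical":
        xc, yc = (float(v) for v in cut["center"])
        a, b = (float(v) for v in cut["semi_axes"])
        if a <= 0 or b <= 0:
            raise GeometryError("elliptical cut needs positive semi-axes")
        if not (xmin < xc < xmax):
            raise GeometryError("elliptical cut misses the cluster")
        ellipse = shapely.affinity.scale(Point(xc, yc).buffer(1.0, quad_segs=128), a, b)
        keep = box(xmin - 1, -big, xc, big).union(ellipse)
        result = poly.intersection(keep)
    else:
        raise GeometryError(f"unknown cut kind: {kind!r}")

    if result.is_empty:
        raise GeometryError("cut removed the entire cluster")
    if result.geom_type == "MultiPolygon":
        raise GeometryError("cut produced multiple components")
    result = orient(result, sign=1.0)  # counterclockwise
    pts = np.asarray(result.exterior.coords)[:-1]
    # densify long straight segments first: the spline resampler needs
    # closely spaced input points to follow a flat cut face faithfully
    dense = []
    for i in range(len(pts)):
        a, b = pts[i], pts[(i + 1) % len(pts)]
        n = max(int(np.ceil(np.hypot(*(b - a)) / (h / 4))), 1)
        frac = np.arange(n) / n
        dense.append(a[None, :] + frac[:, None] * (b - a)[None, :])
    return resample_boundary(BoundaryCurve(np.vstack(dense)), h)
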