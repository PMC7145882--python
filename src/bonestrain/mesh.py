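"""Vertebral contours and quality triangular meshes from BMD images.

The scan is segmented by tracing iso-contours of the areal-BMD field at a
fixed threshold; each retained component becomes a :class:`VertebraROI`.
Each ROI is then filled with a constrained Delaunay triangulation refined by
Ruppert's algorithm: encroached boundary segments are split at their
midpoints and circumcenters of poor-quality or oversized triangles are
inserted until every triangle has a minimum interior angle of at least 20
degrees and edges near the target length.  All boundary chords of the input
polygon are preserved as mesh edges, so the summed element area equals the
(simplified) polygon area to machine precision.

Coordinates are millimetres with y increasing downward (image convention);
the pixel at row r, column c has its centre at ((c+0.5) px, (r+0.5) px).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay, cKDTree
import shapely
from shapely.geometry import Polygon
from skimage import measure

from .errors import AmbiguityError, GeometryError, SegmentationError

__all__ = ["BMDImage", "VertebraROI", "TriMesh",
           "extract_contour", "triangulate", "assign_materials"]

DEFAULT_THRESHOLD_G_CM2 = 0.30
DEFAULT_LABELS = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class BMDImage:
    """Raster of areal BMD values (g/cm^2) with physical pixel spacing."""

    values: np.ndarray
    pixel_spacing_mm: float
    origin_mm: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be a 2D array")
        if np.any(v < 0):
            raise ValueError("BMD values must be nonnegative")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def extent_mm(self) -> tuple:
        h, w = self.values.shape
        return w * self.pixel_spacing_mm, h * self.pixel_spacing_mm

    def sample_bilinear(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the BMD field at mm coordinates."""
        px = self.pixel_spacing_mm
        rows = np.asarray(y_mm) / px - 0.5
        cols = np.asarray(x_mm) / px - 0.5
        return map_coordinates(self.values, [rows, cols], order=1, mode="nearest")


def _signed_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class VertebraROI:
    """Closed simple polygon outlining one vertebral body (mm coordinates).

    The contour is stored open (last vertex != first) and oriented so the
    shoelace signed area is positive.
    """

    level: str
    contour: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.contour, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
            raise GeometryError("contour must be an (n>=3, 2) array")
        if np.allclose(c[0], c[-1]):
            c = c[:-1]
        if _signed_area(c) < 0:
            c = c[::-1].copy()
        poly = Polygon(c)
        if not poly.is_simple or poly.area <= 0:
            raise GeometryError(f"ROI {self.level}: contour must be a simple "
                                "polygon with positive area")
        object.__setattr__(self, "contour", c)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.contour)

    @property
    def area_mm2(self) -> float:
        return _signed_area(self.contour)


@dataclass
class TriMesh:
    """Triangulation of one vertebra with optional per-element materials."""

    nodes: np.ndarray                         # (n, 2) mm
    triangles: np.ndarray                     # (m, 3) int, CCW
    element_bmd: np.ndarray | None = None     # (m,) g/cm^2
    element_modulus: np.ndarray | None = None  # (m,) MPa
    level: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        areas = self.areas()
        if np.any(areas <= 0):
            raise GeometryError("all triangles must have positive signed area")
        used = np.unique(self.triangles)
        if used.size != self.nodes.shape[0]:
            raise GeometryError("mesh contains unused nodes")

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def min_angles_deg(self) -> np.ndarray:
        """Minimum interior angle of each triangle, degrees."""
        p = self.nodes[self.triangles]
        angles = np.empty((len(self.triangles), 3))
        for k in range(3):
            a = p[:, (k + 1) % 3] - p[:, k]
            b = p[:, (k + 2) % 3] - p[:, k]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angles[:, k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return angles.min(axis=1)

    def boundary_edges(self) -> np.ndarray:
        """Edges belonging to exactly one triangle, as (k, 2) node indices."""
        edges = np.vstack([self.triangles[:, [0, 1]],
                           self.triangles[:, [1, 2]],
                           self.triangles[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                       return_counts=True)
        return edges[counts[inverse] == 1]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_edges())


# ---------------------------------------------------------------------------
# Contour extraction
# ---------------------------------------------------------------------------

def extract_contour(image: BMDImage, threshold: float = DEFAULT_THRESHOLD_G_CM2,
                    min_area_mm2: float = 100.0,
                    labels: tuple = DEFAULT_LABELS) -> list:
    """Segment vertebral bodies as iso-contours of the BMD field.

    Closed components of the ``BMD = threshold`` level set with area at least
    ``min_area_mm2`` are kept, ordered cranio-caudally (top of the image
    first) and labelled from ``labels``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    px = image.pixel_spacing_mm
    if image.values.max() < threshold:
        raise SegmentationError(
            f"no pixel above the segmentation threshold {threshold} g/cm^2")

    rois = []
    for contour in measure.find_contours(image.values, level=threshold):
        if not np.allclose(contour[0], contour[-1]):
            continue                        # open contour touching the border
        xy = np.column_stack([(contour[:, 1] + 0.5) * px,
                              (contour[:, 0] + 0.5) * px])
        poly = Polygon(xy)
        if not poly.is_valid or poly.area < min_area_mm2:
            continue
        rois.append(xy)

    if not rois:
        raise SegmentationError(
            f"no closed component with area >= {min_area_mm2} mm^2 at "
            f"threshold {threshold} g/cm^2")
    if len(rois) > len(labels):
        cands = sorted((Polygon(c).area for c in rois), reverse=True)
        raise AmbiguityError(
            f"found {len(rois)} components but only {len(labels)} labels; "
            f"candidate areas (mm^2): {[round(a, 1) for a in cands]}",
            candidates=cands)

    rois.sort(key=lambda c: Polygon(c).centroid.y)
    return [VertebraROI(level=labels[i], contour=c) for i, c in enumerate(rois)]


# ---------------------------------------------------------------------------
# Constrained Delaunay triangulation with Ruppert refinement
# ---------------------------------------------------------------------------

def _coarsen_boundary(roi: VertebraROI, target_edge: float) -> np.ndarray:
    """Resample the ROI outline: Douglas-Peucker at a tolerance that keeps
    the polygon area within 0.1%, then split chords longer than the target.
    """
    poly = roi.polygon
    tol = target_edge / 8.0
    simplified = poly
    while tol > 1e-6:
        simplified = poly.simplify(tol, preserve_topology=True)
        if abs(simplified.area - poly.area) <= 1e-3 * poly.area:
            break
        tol /= 2.0
    pts = np.asarray(simplified.exterior.coords)[:-1]

    out = []
    n = len(pts)
    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        out.append(a)
        length = np.linalg.norm(b - a)
        nseg = int(np.ceil(length / target_edge))
        for k in range(1, nseg):
            out.append(a + (b - a) * k / nseg)
    boundary = np.asarray(out)
    if _signed_area(boundary) < 0:
        boundary = boundary[::-1].copy()
    return boundary


def _circumcenters(p: np.ndarray):
    """Circumcenter and circumradius of triangles p with shape (m, 3, 2)."""
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    ab, ac = b - a, c - a
    d = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ac2 = np.einsum("ij,ij->i", ac, ac)
    ux = (ac[:, 1] * ab2 - ab[:, 1] * ac2) / d
    uy = (ab[:, 0] * ac2 - ac[:, 0] * ab2) / d
    centers = a + np.column_stack([ux, uy])
    radii = np.hypot(ux, uy)
    return centers, radii


def _tri_quality(points: np.ndarray, tris: np.ndarray):
    """Per-triangle (min angle deg, longest edge, signed area)."""
    p = points[tris]
    e0 = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    e1 = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    e2 = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    edges = np.column_stack([e0, e1, e2])
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area2 = np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    # law of sines: sin(angle opposite edge e) = e * area2 / prod(edges);
    # the smallest angle (opposite the shortest edge) is always <= 60 deg,
    # so arcsin is unambiguous
    with np.errstate(divide="ignore", invalid="ignore"):
        prod = edges.prod(axis=1)
        sin_min = np.where(prod > 0, area2 * edges.min(axis=1) / prod, 0.0)
    min_angle = np.degrees(np.arcsin(np.clip(sin_min, 0.0, 1.0)))
    return min_angle, edges.max(axis=1), 0.5 * area2


def _hex_seed(poly: Polygon, spacing: float) -> np.ndarray:
    """Hexagonal interior point lattice kept clear of the boundary."""
    margin = 0.7 * spacing
    core = poly.buffer(-margin)
    if core.is_empty:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = []
    y = miny + margin
    row = 0
    while y <= maxy - margin + 1e-9:
        x0 = minx + margin + (spacing / 2.0 if row % 2 else 0.0)
        xs = np.arange(x0, maxx - margin + 1e-9, spacing)
        if xs.size:
            rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    if not rows:
        return np.empty((0, 2))
    pts = np.vstack(rows)
    keep = shapely.contains_xy(core, pts[:, 0], pts[:, 1])
    return pts[keep]


def triangulate(roi: VertebraROI, target_edge_mm: float,
                min_angle_deg: float = 20.0, max_passes: int = 2000) -> TriMesh:
    """Quality constrained Delaunay triangulation of a vertebral ROI.

    The boundary is coarsened to chords near the target edge length and the
    interior pre-seeded with a hexagonal lattice at that spacing; Ruppert
    refinement then repairs the remaining defects one at a time: boundary
    chords whose diametral circle contains another point are split at their
    midpoint, and the worst triangle with a minimum angle below
    ``min_angle_deg`` or a longest edge above 1.5x the target has its
    circumcenter inserted (deferred to a segment split whenever the
    circumcenter would encroach the boundary).  The input polygon's chords
    are preserved, so the mesh covers the polygon exactly.
    """
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")
    poly = roi.polygon
    if not poly.is_valid or poly.area <= max(1e-12, 1e-6 * target_edge_mm ** 2):
        raise GeometryError(f"ROI {roi.level}: degenerate polygon")

    boundary = _coarsen_boundary(roi, target_edge_mm)
    nb = len(boundary)
    mesh_poly = Polygon(boundary)
    points = list(map(tuple, boundary))
    points.extend(map(tuple, _hex_seed(mesh_poly, target_edge_mm)))
    segments = [(i, (i + 1) % nb) for i in range(nb)]
    max_edge = 1.5 * target_edge_mm
    scale = np.sqrt(mesh_poly.area)

    interior = None
    for _ in range(max_passes):
        pts = np.asarray(points)
        tree = cKDTree(pts)

        # --- split encroached segments -----------------------------------
        seg = np.asarray(segments)
        mids = 0.5 * (pts[seg[:, 0]] + pts[seg[:, 1]])
        rads = 0.5 * np.linalg.norm(pts[seg[:, 0]] - pts[seg[:, 1]], axis=1)
        encroached = []
        for k, (m, r) in enumerate(zip(mids, rads)):
            idx = tree.query_ball_point(m, r * (1.0 - 1e-12))
            if any(i not in (seg[k, 0], seg[k, 1]) for i in idx):
                encroached.append(k)
        if encroached:
            new_segments = []
            for k, s in enumerate(segments):
                if k in set(encroached):
                    points.append(tuple(mids[k]))
                    j = len(points) - 1
                    new_segments += [(s[0], j), (j, s[1])]
                else:
                    new_segments.append(s)
            segments = new_segments
            continue

        # --- triangulate and classify ------------------------------------
        tri = Delaunay(pts)
        tp = pts[tri.simplices]
        tv1 = tp[:, 1] - tp[:, 0]
        tv2 = tp[:, 2] - tp[:, 0]
        tarea = 0.5 * np.abs(tv1[:, 0] * tv2[:, 1] - tv1[:, 1] * tv2[:, 0])
        cents = tp.mean(axis=1)
        inside = shapely.contains_xy(mesh_poly, cents[:, 0], cents[:, 1])
        inside &= tarea > 1e-12 * scale ** 2     # drop collinear slivers
        interior = tri.simplices[inside]
        if interior.size == 0:
            raise GeometryError(f"ROI {roi.level}: triangulation produced no "
                                "interior triangles")

        min_ang, long_edge, _ = _tri_quality(pts, interior)
        bad = np.flatnonzero((min_ang < min_angle_deg) | (long_edge > max_edge))
        if bad.size == 0:
            break

        # --- fix the single worst triangle -------------------------------
        # oversized-but-well-shaped triangles rank after genuinely skinny ones
        rank = np.where(min_ang[bad] < min_angle_deg, min_ang[bad],
                        min_angle_deg + 1.0 / np.maximum(long_edge[bad], 1e-12))
        k = bad[np.argmin(rank)]
        c, r = _circumcenters(pts[interior[[k]]])
        c, r = c[0], float(r[0])

        # defer to a segment split if the circumcenter encroaches a chord
        enc = np.flatnonzero(np.linalg.norm(mids - c, axis=1)
                             < rads * (1 - 1e-12))
        if enc.size:
            j = int(enc[np.argmax(rads[enc])])
            s = segments[j]
            points.append(tuple(mids[j]))
            jj = len(points) - 1
            segments[j:j + 1] = [(s[0], jj), (jj, s[1])]
            continue
        if not (np.all(np.isfinite(c))
                and shapely.contains_xy(mesh_poly, c[0], c[1])):
            c = pts[interior[k]].mean(axis=0)    # centroid fallback
        if tree.query(c)[0] < 1e-9 * scale:
            # circumcenter coincides with an existing node: bisect the
            # longest edge instead
            tpk = pts[interior[k]]
            el = [np.linalg.norm(tpk[(j + 1) % 3] - tpk[j]) for j in range(3)]
            j = int(np.argmax(el))
            c = 0.5 * (tpk[j] + tpk[(j + 1) % 3])
            if tree.query(c)[0] < 1e-9 * scale:
                raise GeometryError(
                    f"ROI {roi.level}: refinement stalled on a degenerate "
                    "triangle")
        points.append(tuple(c))
    else:
        raise GeometryError(f"ROI {roi.level}: refinement did not converge "
                            f"in {max_passes} passes")

    # orient CCW (positive shoelace area)
    p = pts[interior]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    flip = (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]) < 0
    interior[flip] = interior[flip][:, [0, 2, 1]]

    # drop unused nodes
    used = np.unique(interior)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TriMesh(nodes=pts[used], triangles=remap[interior], level=roi.level)


# ---------------------------------------------------------------------------
# Material mapping
# ---------------------------------------------------------------------------

def _subdivision_centroids(k: int) -> np.ndarray:
    """Barycentric centroids of the k^2 congruent subtriangles of a triangle.

    Rows i+j < k give 'upright' subtriangles with centroid
    ((i+1/3), (j+1/3), rest)/k; rows with i+j < k-1 add the inverted ones.
    All subtriangles have equal area, so equal-weight averaging is exact
    midpoint-rule quadrature.
    """
    cents = []
    for i in range(k):
        for j in range(k - i):
            cents.append(((i + 1 / 3), (j + 1 / 3)))
            if i + j < k - 1:
                cents.append(((i + 2 / 3), (j + 2 / 3)))
    arr = np.asarray(cents) / k
    return np.column_stack([1.0 - arr.sum(axis=1), arr[:, 0], arr[:, 1]])


def assign_materials(mesh: TriMesh, image: BMDImage, model) -> TriMesh:
    """Attach per-element BMD and elastic modulus to a mesh.

    Element BMD is the mean of the image field over the triangle, estimated
    by bilinear interpolation at barycentric quadrature points (the centroid
    alone for sub-pixel triangles); the modulus follows ``model.modulus``
    (a BMD -> MPa map with a positive floor).
    """
    w, h = image.extent_mm
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    if lo[0] < -1e-9 or lo[1] < -1e-9 or hi[0] > w + 1e-9 or hi[1] > h + 1e-9:
        raise GeometryError("mesh extends outside the image bounds")

    areas = mesh.areas()
    px = image.pixel_spacing_mm
    p = mesh.nodes[mesh.triangles]

    # subdivide each triangle into k^2 congruent subtriangles and average the
    # bilinear field at their centroids (an equal-weight midpoint rule); k is
    # chosen per element so the subcells are no larger than one pixel, which
    # keeps the estimated mean independent of the mesh resolution
    edge_len = np.maximum.reduce([
        np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
        np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
        np.linalg.norm(p[:, 0] - p[:, 2], axis=1)])
    k_per_elem = np.clip(np.ceil(edge_len / px).astype(int), 1, 8)

    element_bmd = np.empty(len(mesh.triangles))
    for k in np.unique(k_per_elem):
        sel = k_per_elem == k
        bary = _subdivision_centroids(k)
        pts = np.einsum("kj,mji->mki", bary, p[sel])
        vals = image.sample_bilinear(pts[..., 0].ravel(), pts[..., 1].ravel())
        element_bmd[sel] = vals.reshape(-1, bary.shape[0]).mean(axis=1)

    modulus = model.modulus(element_bmd)
    return replace(mesh, element_bmd=element_bmd, element_modulus=modulus)
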