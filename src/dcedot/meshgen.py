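"""Mesh generation from MR-like binary masks.

An anatomical slice enters the optical pipeline as a binary mask.  The mask is
thresholded at half its maximum intensity, the exterior boundary is traced and
decimated, the decimated contour seeds a linear-triangle finite-element mesh,
and sixteen rays at 22.5 degree increments map the eight sources and eight
detectors of the fan-beam interface onto boundary nodes.

Coordinates are Cartesian millimetres with the origin at the image centre and
the y axis pointing up; image row 0 is the top of the picture and the
conversion happens only here.  Nodes, elements, sources and detectors are all
0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage import measure

DEFAULT_PIXEL_MM = 0.5


def cross2(a, b):
    """z component of the cross product of 2-D vectors (broadcasting)."""
    a = np.asarray(a)
    b = np.asarray(b)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


@dataclass
class Mesh2D:
    """Triangulated 2-D domain.

    nodes : (N, 2) float array, mm.
    elements : (E, 3) int array of node indices; every element is oriented
        counter-clockwise (positive signed area).
    boundary_edges : (B, 2) int array of node pairs forming one closed
        counter-clockwise loop; the outward normal of edge (a, b) is the
        edge vector rotated by -90 degrees.
    region_labels : (N,) int array; 0 is background, regions are contiguous
        integers.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_edges: np.ndarray
    region_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.boundary_edges = np.asarray(self.boundary_edges, dtype=np.int64)
        if self.region_labels is None:
            self.region_labels = np.zeros(len(self.nodes), dtype=np.int64)
        self.region_labels = np.asarray(self.region_labels, dtype=np.int64)
        areas = self.element_areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise ValueError(f"element {bad} has non-positive signed area {areas[bad]:.3g}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def node_areas(self) -> np.ndarray:
        """Lumped nodal areas: one third of each incident element's area."""
        areas = self.element_areas()
        w = np.zeros(self.n_nodes)
        for a in range(3):
            np.add.at(w, self.elements[:, a], areas / 3.0)
        return w

    def total_area(self) -> float:
        return float(self.element_areas().sum())

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_edges)

    def edge_normals(self) -> np.ndarray:
        """Outward unit normal per boundary edge (CCW loop convention)."""
        d = self.nodes[self.boundary_edges[:, 1]] - self.nodes[self.boundary_edges[:, 0]]
        n = np.stack([d[:, 1], -d[:, 0]], axis=1)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def node_normal(self, node: int) -> np.ndarray:
        """Outward unit normal at a boundary node (mean of adjacent edges)."""
        mask = np.any(self.boundary_edges == node, axis=1)
        if not mask.any():
            raise ValueError(f"node {node} is not on the boundary")
        n = self.edge_normals()[mask].sum(axis=0)
        return n / np.linalg.norm(n)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True for points inside some element (used for source placement)."""
        return find_element(self, np.atleast_2d(points))[0] >= 0


@dataclass
class OptodeLayout:
    """Eight sources and eight detectors on the boundary, fan-beam style."""

    source_positions: np.ndarray
    detector_positions: np.ndarray
    center: np.ndarray
    source_nodes: np.ndarray = None
    detector_nodes: np.ndarray = None

    def __post_init__(self):
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        self.detector_positions = np.asarray(self.detector_positions, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_positions)


def mask_from_image(intensity_image: np.ndarray) -> np.ndarray:
    """Threshold an intensity image at half its maximum and keep the largest
    connected component.

    Parameters
    ----------
    intensity_image : 2-D array with at least one positive pixel.
    """
    img = np.asarray(intensity_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    vmax = img.max()
    if vmax <= 0:
        raise ValueError("image has no positive pixels")
    mask = img >= 0.5 * vmax
    if not mask.any():
        raise ValueError("empty mask after thresholding at half maximum")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def pixels_to_mm(rc: np.ndarray, shape: tuple, pixel_mm: float) -> np.ndarray:
    """(row, col) pixel coordinates -> (x, y) mm, origin at image centre, y up."""
    rc = np.asarray(rc, dtype=float)
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    x = (rc[..., 1] - cx) * pixel_mm
    y = (cy - rc[..., 0]) * pixel_mm
    return np.stack([x, y], axis=-1)


def mm_to_pixels(xy: np.ndarray, shape: tuple, pixel_mm: float) -> np.ndarray:
    """Inverse of :func:`pixels_to_mm`; returns float (row, col)."""
    xy = np.asarray(xy, dtype=float)
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    col = cx + xy[..., 0] / pixel_mm
    row = cy - xy[..., 1] / pixel_mm
    return np.stack([row, col], axis=-1)


def polygon_area(poly: np.ndarray) -> float:
    """Signed area; positive for counter-clockwise winding."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_boundary(binary_mask: np.ndarray, keep_every: int = 5,
                     pixel_mm: float = DEFAULT_PIXEL_MM) -> np.ndarray:
    """Trace the exterior boundary of a mask and decimate it.

    The ordered boundary contour is reduced by keeping one of every
    ``keep_every`` points, then converted to mm.  Returns an open CCW polygon
    (first point not repeated).
    """
    mask = np.asarray(binary_mask, dtype=bool)
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if not mask.any():
        raise ValueError("mask is empty")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("mask touches the image border; boundary is incomplete")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    # find_contours closes the loop by repeating the first point
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    contour = contour[::keep_every]
    poly = pixels_to_mm(contour, mask.shape, pixel_mm)
    if polygon_area(poly) < 0:
        poly = poly[::-1]
    return poly


def _resample_polygon(poly: np.ndarray, max_seg: float) -> np.ndarray:
    """Subdivide polygon segments longer than max_seg, keeping all vertices."""
    out = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / max_seg)))
        for t in range(k):
            out.append(a + (b - a) * (t / k))
    return np.array(out)


def build_mesh(boundary_polygon: np.ndarray, target_edge_mm: float) -> Mesh2D:
    """Triangulate the interior of a simple polygon.

    Boundary vertices are kept as mesh nodes (long segments are subdivided to
    the target edge length), the interior is filled with a hexagonal point
    lattice, and a Delaunay triangulation restricted to the polygon interior
    provides the elements.
    """
    poly = np.asarray(boundary_polygon, dtype=float)
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")
    shp = Polygon(poly)
    if not shp.is_valid or shp.area <= 0:
        raise ValueError("boundary polygon is self-intersecting or degenerate")
    ring = _resample_polygon(poly, target_edge_mm)

    h = target_edge_mm
    xmin, ymin, xmax, ymax = shp.bounds
    interior_ok = prep(shp.buffer(-0.45 * h))
    pts = []
    rows = np.arange(ymin, ymax + h, h * np.sqrt(3) / 2)
    for j, y in enumerate(rows):
        xs = np.arange(xmin + (h / 2 if j % 2 else 0.0), xmax + h, h)
        for x in xs:
            if interior_ok.contains(Point(x, y)):
                pts.append((x, y))
    points = np.vstack([ring, np.array(pts).reshape(-1, 2)]) if pts else ring

    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    inside = prep(shp)
    keep = np.array([inside.contains(Point(*c)) for c in cent])
    # collinear contour points produce zero-area slivers; drop them
    p = points[tri.simplices]
    area = 0.5 * np.abs(cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    keep &= area > 1e-6 * h * h
    elements = tri.simplices[keep]

    # drop unused nodes, re-index
    used = np.unique(elements)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    elements = remap[elements]

    # enforce CCW orientation
    p = nodes[elements]
    area2 = cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = area2 < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    boundary_edges = _boundary_loop(nodes, elements)
    return Mesh2D(nodes=nodes, elements=elements, boundary_edges=boundary_edges)


def _boundary_loop(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Edges used by exactly one element, ordered into one closed CCW loop."""
    edges = {}
    for tri in elements:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            if key in edges:
                edges.pop(key)
            else:
                edges[key] = (a, b)  # oriented as in its CCW element
    directed = {a: b for a, b in edges.values()}
    if not directed:
        raise ValueError("mesh has no boundary")
    start = next(iter(directed))
    loop = [start]
    cur = directed[start]
    while cur != start:
        loop.append(cur)
        cur = directed.get(cur)
        if cur is None or len(loop) > len(directed) + 1:
            raise ValueError("boundary edges do not form a single closed loop")
    loop = np.array(loop, dtype=np.int64)
    return np.stack([loop, np.roll(loop, -1)], axis=1)


def find_element(mesh: Mesh2D, points: np.ndarray, tol: float = 1e-9):
    """Locate the element containing each query point.

    Returns (element index or -1, barycentric weights (n, 3)).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p = mesh.nodes[mesh.elements]  # (E, 3, 2)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = cross2(v0, v1)
    elems = np.full(len(points), -1, dtype=np.int64)
    bary = np.zeros((len(points), 3))
    for i, q in enumerate(points):
        d = q - p[:, 0]
        l1 = cross2(d, v1) / det
        l2 = cross2(v0, d) / det
        l0 = 1.0 - l1 - l2
        ok = (l0 >= -tol) & (l1 >= -tol) & (l2 >= -tol)
        idx = np.flatnonzero(ok)
        if len(idx):
            e = idx[0]
            elems[i] = e
            bary[i] = np.clip([l0[e], l1[e], l2[e]], 0.0, 1.0)
            bary[i] /= bary[i].sum()
    return elems, bary


def map_optodes(mesh: Mesh2D, center) -> OptodeLayout:
    """Place 8 sources and 8 detectors with 16 rays at 22.5 degree increments.

    Rays from the centre intersect the boundary loop; alternate intersections
    become sources (even rays, starting at angle 0) and detectors (odd rays).
    Each optode is snapped to the nearest boundary node.
    """
    center = np.asarray(center, dtype=float)
    if not mesh.contains(center):
        raise ValueError("center must lie strictly inside the mesh")
    bnodes = mesh.boundary_nodes()
    bpos = mesh.nodes[bnodes]
    angles = np.deg2rad(np.arange(16) * 22.5)
    hits = []
    for th in angles:
        direction = np.array([np.cos(th), np.sin(th)])
        t = _ray_boundary_hit(mesh, center, direction)
        if t is None:
            raise ValueError(f"ray at {np.rad2deg(th):.1f} deg does not hit the boundary")
        hit = center + t * direction
        j = int(np.argmin(np.linalg.norm(bpos - hit, axis=1)))
        hits.append(bnodes[j])
    hits = np.array(hits)
    src_nodes = hits[0::2]
    det_nodes = hits[1::2]
    return OptodeLayout(
        source_positions=mesh.nodes[src_nodes],
        detector_positions=mesh.nodes[det_nodes],
        center=center,
        source_nodes=src_nodes,
        detector_nodes=det_nodes,
    )


def _ray_boundary_hit(mesh: Mesh2D, origin: np.ndarray, direction: np.ndarray):
    """Distance along a ray to the furthest boundary-edge intersection."""
    a = mesh.nodes[mesh.boundary_edges[:, 0]]
    b = mesh.nodes[mesh.boundary_edges[:, 1]]
    e = b - a
    denom = cross2(direction, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross2(a - origin, e) / denom
        u = cross2(a - origin, direction) / denom
    ok = (np.abs(denom) > 1e-12) & (u >= -1e-9) & (u <= 1 + 1e-9) & (t > 0)
    if not ok.any():
        return None
    return float(t[ok].max())


def label_region(mesh: Mesh2D, region_polygon: np.ndarray) -> Mesh2D:
    """Assign the next region id to nodes inside the polygon (in place)."""
    shp = Polygon(np.asarray(region_polygon, dtype=float))
    inside = np.array([shp.contains(Point(*p)) for p in mesh.nodes])
    if not inside.any():
        raise ValueError("region polygon encloses no mesh nodes")
    next_id = mesh.region_labels.max() + 1
    mesh.region_labels[inside] = next_id
    return mesh


# ---------------------------------------------------------------------------
# plain-text mesh IO

def save_mesh(mesh: Mesh2D, prefix: str) -> None:
    """Write ``<prefix>.node`` (index, x, y), ``<prefix>.ele``
    (index, n1, n2, n3, region) and ``<prefix>.region`` (index, label)."""
    with open(prefix + ".node", "w") as f:
        for i, (x, y) in enumerate(mesh.nodes):
            f.write(f"{i} {x:.9g} {y:.9g}\n")
    lab = mesh.region_labels
    with open(prefix + ".ele", "w") as f:
        for i, (a, b, c) in enumerate(mesh.elements):
            r = lab[a] if lab[a] == lab[b] == lab[c] else 0
            f.write(f"{i} {a} {b} {c} {r}\n")
    with open(prefix + ".region", "w") as f:
        for i, r in enumerate(lab):
            f.write(f"{i} {r}\n")


def load_mesh(prefix: str) -> Mesh2D:
    nodes = np.loadtxt(prefix + ".node", ndmin=2)[:, 1:3]
    ele = np.loadtxt(prefix + ".ele", dtype=np.int64, ndmin=2)
    elements = ele[:, 1:4]
    try:
        labels = np.loadtxt(prefix + ".region", dtype=np.int64, ndmin=2)[:, 1]
    except OSError:
        labels = np.zeros(len(nodes), dtype=np.int64)
    boundary = _boundary_loop(nodes, elements)
    return Mesh2D(nodes=nodes, elements=elements, boundary_edges=boundary,
                  region_labels=labels)


def save_layout(layout: OptodeLayout, path: str) -> None:
    doc = {
        "center": layout.center.tolist(),
        "source_positions": layout.source_positions.tolist(),
        "detector_positions": layout.detector_positions.tolist(),
        "source_nodes": None if layout.source_nodes is None else np.asarray(layout.source_nodes).tolist(),
        "detector_nodes": None if layout.detector_nodes is None else np.asarray(layout.detector_nodes).tolist(),
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def load_layout(path: str) -> OptodeLayout:
    with open(path) as f:
        doc = json.load(f)
    return OptodeLayout(
        source_positions=np.array(doc["source_positions"]),
        detector_positions=np.array(doc["detector_positions"]),
        center=np.array(doc["center"]),
        source_nodes=None if doc["source_nodes"] is None else np.array(doc["source_nodes"]),
        detector_nodes=None if doc["detector_nodes"] is None else np.array(doc["detector_nodes"]),
    )
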