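"""Multi-region triangulation of the layered wall geometry.

The mesher produces a conforming, material-labelled triangle mesh directly
from the shapely face polygons of a :class:`~plaquestress.geometry.LayeredGeometry`:

1. every face-boundary segment is densified deterministically to the local
   target size, with shared interface segments producing identical points on
   both sides (hence a conforming mesh across material interfaces);
2. graded interior points are laid on hexagonal lattices and thinned to the
   local size field (fine at the lumen, coarse at the outer boundary);
3. each face is Delaunay-triangulated, triangles outside the face are
   discarded, and interior nodes are Laplacian-smoothed.

The size field keeps lumen-adjacent elements below the 50 um superficial
resolution at which the peak wall stress is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Polygon

from .geometry import LayeredGeometry

__all__ = ["FEMesh", "MeshError", "generate_mesh", "extract_superficial_set"]


class MeshError(RuntimeError):
    pass


@dataclass
class FEMesh:
    """Conforming labelled triangle mesh of one cross-section."""

    nodes: np.ndarray            # (N, 2) mm
    elements: np.ndarray         # (M, 3) int, counterclockwise
    labels: np.ndarray           # (M,) material label per element
    lumen_edges: np.ndarray      # (L, 2) node pairs, closed CCW loop on the lumen
    outer_edges: np.ndarray      # (K, 2) node pairs on the outer boundary
    superficial_set: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.elements = np.asarray(self.elements, np.int64)
        a = self.areas()
        if np.any(a <= 0):
            raise MeshError(f"{int(np.sum(a <= 0))} inverted/degenerate elements")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def coords(self) -> np.ndarray:
        """Element corner coordinates, (M, 3, 2)."""
        return self.nodes[self.elements]

    def areas(self) -> np.ndarray:
        x = self.coords()
        return 0.5 * ((x[:, 1, 0] - x[:, 0, 0]) * (x[:, 2, 1] - x[:, 0, 1])
                      - (x[:, 2, 0] - x[:, 0, 0]) * (x[:, 1, 1] - x[:, 0, 1]))

    def centroids(self) -> np.ndarray:
        return self.coords().mean(axis=1)

    def edge_lengths(self) -> np.ndarray:
        """Per-element edge lengths, (M, 3)."""
        x = self.coords()
        return np.stack([np.hypot(*(x[:, (i + 1) % 3] - x[:, i]).T) for i in range(3)],
                        axis=1)

    def min_angles(self) -> np.ndarray:
        """Minimum interior angle per element, degrees."""
        L = np.sort(self.edge_lengths(), axis=1)
        a, b, c = L[:, 0], L[:, 1], L[:, 2]
        cosA = np.clip((b ** 2 + c ** 2 - a ** 2) / (2 * b * c), -1.0, 1.0)
        return np.degrees(np.arccos(cosA))

    def lumen_loop(self) -> np.ndarray:
        """Ordered node ids of the closed lumen boundary loop."""
        return self.lumen_edges[:, 0]

    def region_area(self, label: str) -> float:
        return float(self.areas()[self.labels == label].sum())


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

_SNAP = 9  # decimals for the global point registry


class _PointRegistry:
    def __init__(self):
        self.index: dict[tuple, int] = {}
        self.points: list[tuple] = []

    def add(self, x: float, y: float) -> int:
        key = (round(x, _SNAP), round(y, _SNAP))
        i = self.index.get(key)
        if i is None:
            i = len(self.points)
            self.index[key] = i
            self.points.append(key)
        return i

    def array(self) -> np.ndarray:
        return np.asarray(self.points, float)


def _size_field(lumen_ring: LineString, h_sup: float, h_bulk: float, ramp: float):
    guard = 2.0 * h_sup  # keep the full superficial resolution in the first band
    def h_at(xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        d = shapely.distance(shapely.points(xy), lumen_ring)
        return h_sup + (h_bulk - h_sup) * np.clip((d - guard) / ramp, 0.0, 1.0)
    return h_at


def _canonical_ring(coords: np.ndarray) -> np.ndarray:
    """Open ring, counterclockwise, rotated to start at its smallest vertex.

    Two shapely representations of the same interface ring (a face exterior
    vs. a neighbouring face's hole) differ in orientation and start vertex;
    canonicalizing makes every downstream decision identical on both sides.
    """
    pts = coords[:-1] if np.allclose(coords[0], coords[-1]) else coords
    x, y = pts[:, 0], pts[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        pts = pts[::-1]
    k = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    return np.roll(pts, -k, axis=0)


def _densify_ring(coords: np.ndarray, h_at, reg: _PointRegistry) -> list[int]:
    """Adapt a ring polyline to the local size field; deterministic per ring.

    Input vertices denser than the size field are decimated (greedy walk from
    the canonical start) and sparse segments are subdivided, so interface
    rings match the interior grading on both adjacent faces.
    """
    pts = _canonical_ring(np.asarray(coords, float))
    h_here = h_at(pts)
    # decimate: keep a vertex once the chord from the last kept one is long enough
    keep = [0]
    acc = 0.0
    n = len(pts)
    for k in range(1, n):
        acc += float(np.hypot(*(pts[k] - pts[k - 1])))
        if acc >= 0.75 * float(h_here[k]):
            keep.append(k)
            acc = 0.0
    # do not leave a sliver segment against the start vertex
    if len(keep) > 3 and acc + np.hypot(*(pts[keep[-1]] - pts[0])) < 0.5 * float(h_here[0]):
        keep.pop()
    kept = pts[keep]

    ids: list[int] = []
    m = len(kept)
    for k in range(m):
        p, q = kept[k], kept[(k + 1) % m]
        canonical = (p[0], p[1]) <= (q[0], q[1])
        a, b = (p, q) if canonical else (q, p)
        L = float(np.hypot(*(b - a)))
        if L == 0:
            continue
        nseg = max(1, int(np.ceil(L / float(h_at((a + b) / 2.0)[0]))))
        t = np.arange(1, nseg) / nseg
        inner = a + t[:, None] * (b - a)
        if not canonical:
            inner = inner[::-1]
        ids.append(reg.add(*p))
        ids.extend(reg.add(*xy) for xy in inner)
    return ids


def _interior_points(poly: Polygon, boundary_xy: np.ndarray, h_at,
                     h_sup: float, h_bulk: float) -> np.ndarray:
    """Graded interior fill: stacked hex lattices thinned to the size field."""
    minx, miny, maxx, maxy = poly.bounds
    levels = []
    h = h_sup
    while h < h_bulk * 0.999:
        levels.append(h)
        h *= np.sqrt(2.0)
    levels.append(h_bulk)

    half_octave = 2.0 ** 0.25
    cands = []
    for lvl, hl in enumerate(levels):
        dx, dy = hl, hl * np.sqrt(3.0) / 2.0
        ys = np.arange(miny + 0.4 * dy, maxy, dy)
        rows = []
        for j, y in enumerate(ys):
            xs = np.arange(minx + (0.25 + 0.5 * (j % 2)) * dx, maxx, dx)
            rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        if not rows:
            continue
        xy = np.vstack(rows)
        inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
        xy = xy[inside]
        if not len(xy):
            continue
        hloc = h_at(xy)
        # each candidate belongs to the level nearest its local size (log scale)
        keep = (hloc > hl / half_octave) & (hloc <= hl * half_octave)
        if lvl == 0:
            keep |= hloc <= hl
        if lvl == len(levels) - 1:
            keep |= hloc > hl
        cands.append(np.column_stack([xy[keep], hloc[keep]]))
    if not cands:
        return np.empty((0, 2))
    cand = np.vstack(cands)
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))
    cand = cand[order]

    btree = cKDTree(boundary_xy)
    accepted: list[np.ndarray] = []
    cell = h_sup  # bucket size for the greedy spacing filter
    buckets: dict[tuple, list[int]] = {}
    for row in cand:
        x, y, hloc = row
        r = 0.72 * hloc
        if btree.query([x, y], k=1)[0] < 0.72 * hloc:
            continue
        ok = True
        ci, cj = int(x // cell), int(y // cell)
        reach = int(np.ceil(r / cell))
        for ii in range(ci - reach, ci + reach + 1):
            for jj in range(cj - reach, cj + reach + 1):
                for idx in buckets.get((ii, jj), ()):
                    px, py = accepted[idx]
                    if (px - x) ** 2 + (py - y) ** 2 < r * r:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((ci, cj), []).append(len(accepted))
            accepted.append(np.array([x, y]))
    return np.asarray(accepted) if accepted else np.empty((0, 2))


def _triangulate_face(poly: Polygon, ring_ids: list[list[int]], reg: _PointRegistry,
                      h_at, h_sup: float, h_bulk: float,
                      layer_xy: np.ndarray | None = None,
                      smooth_iters: int = 4) -> np.ndarray:
    """Delaunay-triangulate one face; returns (m, 3) global node ids."""
    boundary_ids = np.array([i for ring in ring_ids for i in ring], dtype=np.int64)
    all_pts = reg.array()
    boundary_xy = all_pts[boundary_ids]
    # the face as tiled: decimated exterior ring with decimated holes
    poly = Polygon(all_pts[ring_ids[0]],
                   holes=[all_pts[r] for r in ring_ids[1:]])
    if not poly.is_valid:
        raise MeshError("decimated face boundary became invalid")
    # fixed structured points (near-lumen boundary layer) that fall in this face
    if layer_xy is not None and len(layer_xy):
        inside = shapely.contains_xy(poly, layer_xy[:, 0], layer_xy[:, 1])
        fixed = layer_xy[inside]
    else:
        fixed = np.empty((0, 2))
    bnd_and_fixed = np.vstack([boundary_xy, fixed])
    interior = _interior_points(poly, bnd_and_fixed, h_at, h_sup, h_bulk)

    local_xy = (np.vstack([bnd_and_fixed, interior]) if len(interior)
                else bnd_and_fixed)
    n_bnd = len(boundary_ids)
    n_fixed = n_bnd + len(fixed)  # boundary + layer points stay put

    def _delaunay(xy):
        tri = Delaunay(xy)
        cent = xy[tri.simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        simp = tri.simplices[keep]
        x = xy[simp]
        area = 0.5 * ((x[:, 1, 0] - x[:, 0, 0]) * (x[:, 2, 1] - x[:, 0, 1])
                      - (x[:, 2, 0] - x[:, 0, 0]) * (x[:, 1, 1] - x[:, 0, 1]))
        flip = area < 0
        simp[flip] = simp[flip][:, ::-1]
        return simp[np.abs(area) > 1e-12]

    simplices = _delaunay(local_xy)
    # Laplacian smoothing of free interior nodes only
    for _ in range(smooth_iters):
        if len(local_xy) <= n_fixed:
            break
        nbr_sum = np.zeros_like(local_xy)
        nbr_cnt = np.zeros(len(local_xy))
        for i in range(3):
            a, b = simplices[:, i], simplices[:, (i + 1) % 3]
            np.add.at(nbr_sum, a, local_xy[b])
            np.add.at(nbr_cnt, a, 1.0)
            np.add.at(nbr_sum, b, local_xy[a])
            np.add.at(nbr_cnt, b, 1.0)
        target = nbr_sum / np.maximum(nbr_cnt, 1.0)[:, None]
        moved = local_xy.copy()
        moved[n_fixed:] = target[n_fixed:]
        ok = shapely.contains_xy(poly, moved[n_fixed:, 0], moved[n_fixed:, 1])
        inter = moved[n_fixed:]
        inter[~ok] = local_xy[n_fixed:][~ok]
        moved[n_fixed:] = inter
        local_xy = moved
        simplices = _delaunay(local_xy)

    # verify boundary-edge recovery
    edge_set = set()
    for i in range(3):
        a, b = simplices[:, i], simplices[:, (i + 1) % 3]
        edge_set.update(zip(np.minimum(a, b).tolist(), np.maximum(a, b).tolist()))
    for ring in ring_ids:
        n = len(ring)
        local_of = {g: l for l, g in enumerate(boundary_ids.tolist())}
        for k in range(n):
            a, b = local_of[ring[k]], local_of[ring[(k + 1) % n]]
            if (min(a, b), max(a, b)) not in edge_set:
                raise MeshError("boundary edge lost during triangulation; "
                                "refine the size field")

    # map to global ids, registering smoothed interior nodes
    global_ids = np.empty(len(local_xy), dtype=np.int64)
    global_ids[:n_bnd] = boundary_ids
    for j in range(n_bnd, len(local_xy)):
        global_ids[j] = reg.add(local_xy[j, 0], local_xy[j, 1])
    return global_ids[simplices]


def generate_mesh(geom: LayeredGeometry, h_superficial: float = 0.045,
                  h_bulk: float = 0.15, ramp: float = 0.5,
                  superficial_depth_um: float = 50.0) -> FEMesh:
    """Triangulate a layered geometry with lumen-graded element size.

    ``h_superficial`` (mm) is the target size at the lumen (must stay below
    the 50 um superficial-readout resolution), ``h_bulk`` the size at depth
    ``ramp`` and beyond.
    """
    if not (0 < h_superficial < 0.05):
        raise MeshError("h_superficial must lie in (0, 0.05) mm")
    if h_bulk < h_superficial:
        raise MeshError("h_bulk must be >= h_superficial")

    lumen_pts = geom.lumen_boundary.points
    lumen_ring = LineString(np.vstack([lumen_pts, lumen_pts[:1]]))
    h_at = _size_field(lumen_ring, h_superficial, h_bulk, ramp)

    # structured boundary layer half an element inside the wall, so the first
    # course of lumen-adjacent triangles is uniformly below the 50 um readout
    layer_ring = geom.lumen_boundary.polygon.buffer(0.5 * h_superficial,
                                                    quad_segs=8).exterior
    coords = np.asarray(layer_ring.coords)
    seg = np.hypot(*np.diff(coords, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_layer = max(8, int(np.ceil(s[-1] / h_superficial)))
    tgt = np.linspace(0.0, s[-1], n_layer, endpoint=False)
    layer_xy = np.column_stack([np.interp(tgt, s, coords[:, 0]),
                                np.interp(tgt, s, coords[:, 1])])

    reg = _PointRegistry()
    elements: list[np.ndarray] = []
    labels: list[str] = []
    for label in ("intima_fibrous", "intima_lipid", "intima_calcium",
                  "media", "adventitia"):
        for poly in geom.faces.get(label, []):
            rings = [np.asarray(poly.exterior.coords)]
            rings += [np.asarray(r.coords) for r in poly.interiors]
            ring_ids = [_densify_ring(r, h_at, reg) for r in rings]
            simp = _triangulate_face(poly, ring_ids, reg, h_at,
                                     h_superficial, h_bulk, layer_xy=layer_xy)
            elements.append(simp)
            labels.extend([label] * len(simp))

    if not elements:
        raise MeshError("geometry has no faces to mesh")
    elems = np.vstack(elements)
    nodes = reg.array()

    lumen_ids = _densify_ring(np.vstack([lumen_pts, lumen_pts[:1]]), h_at, reg)
    outer_pts = geom.outer_boundary.points
    outer_ids = _densify_ring(np.vstack([outer_pts, outer_pts[:1]]), h_at, reg)
    if len(reg.points) != len(nodes):
        raise MeshError("lumen/outer boundary points missing from the face meshes")

    def _loop_edges(ids):
        ids = np.asarray(ids, np.int64)
        return np.column_stack([ids, np.roll(ids, -1)])

    mesh = FEMesh(nodes=nodes, elements=elems, labels=np.asarray(labels),
                  lumen_edges=_loop_edges(lumen_ids),
                  outer_edges=_loop_edges(outer_ids))
    mesh.superficial_set = extract_superficial_set(mesh, superficial_depth_um)
    return mesh


def extract_superficial_set(mesh: FEMesh, depth_um: float = 50.0) -> np.ndarray:
    """Element ids whose reference centroid lies within ``depth_um`` of the lumen.

    The band is defined in the reference (imaged, diastolic) configuration so
    membership never changes between load steps.
    """
    if depth_um <= 0:
        raise MeshError("superficial depth must be positive")
    loop = mesh.lumen_loop()
    ring = LineString(np.vstack([mesh.nodes[loop], mesh.nodes[loop[:1]]]))
    cent = mesh.centroids()
    d = shapely.distance(shapely.points(cent), ring)
    ids = np.flatnonzero(d <= depth_um / 1000.0)
    if len(ids) == 0:
        raise MeshError(f"no element centroid within {depth_um} um of the lumen; "
                        "mesh too coarse for the superficial readout")
    return ids
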