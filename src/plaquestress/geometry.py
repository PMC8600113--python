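"""Cross-sectional vessel geometry.

A cross-section is described by two nested closed contours — the lumen and the
internal elastic lamina (IEL) — plus labelled intimal plaque regions (lipid,
calcium) and the measured thicknesses of media and adventitia.  The wall model
is three-layered: the intima is the annulus between lumen and IEL (fibrous
tissue as background material, lipid/calcium pools as inclusions), and media
and adventitia are uniform bands obtained by offsetting the IEL outward.

All coordinates are millimetres in the image plane.  Contours are normalized
to counterclockwise orientation; the lumen centroid is the natural origin but
no translation is forced on input data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

__all__ = [
    "Contour",
    "PlaqueRegion",
    "CrossSection",
    "LayeredGeometry",
    "LesionMarkers",
    "GeometryError",
    "select_representative_frames",
    "offset_contour",
    "build_layered_geometry",
    "complete_partial_iel",
    "compute_plaque_burden",
    "measure_cap_thickness",
]

log = logging.getLogger(__name__)

PLAQUE_LABELS = ("lipid", "calcium")
LAYER_LABELS = ("intima_fibrous", "intima_lipid", "intima_calcium", "media", "adventitia")


class GeometryError(ValueError):
    """Raised when a contour or cross-section violates its geometric contract."""


def _polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area (positive for counterclockwise)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed simple planar polyline (mm).  The last vertex connects to the first."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("contour points must be an (n, 2) array")
        # drop an explicitly repeated closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 8:
            raise GeometryError(f"contour needs >=8 vertices, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("contour has non-finite coordinates")
        if _polygon_area(pts) < 0:  # normalize to counterclockwise
            pts = pts[::-1]
        poly = Polygon(pts)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("contour is self-intersecting or degenerate")
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)

    # -- convenience ----------------------------------------------------
    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return _polygon_area(self.points)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def resample(self, n: int = 128) -> "Contour":
        """Resample to ``n`` vertices uniformly spaced in arc length."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.hypot(*np.diff(pts, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        target = np.linspace(0.0, s[-1], n, endpoint=False)
        x = np.interp(target, s, pts[:, 0])
        y = np.interp(target, s, pts[:, 1])
        return Contour(np.column_stack([x, y]))

    @classmethod
    def circle(cls, radius: float, center=(0.0, 0.0), n: int = 128) -> "Contour":
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return cls(np.column_stack([center[0] + radius * np.cos(t),
                                    center[1] + radius * np.sin(t)]))

    @classmethod
    def ellipse(cls, a: float, b: float, center=(0.0, 0.0), angle: float = 0.0,
                n: int = 128) -> "Contour":
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        x, y = a * np.cos(t), b * np.sin(t)
        ca, sa = math.cos(angle), math.sin(angle)
        return cls(np.column_stack([center[0] + ca * x - sa * y,
                                    center[1] + sa * x + ca * y]))

    @classmethod
    def from_polygon(cls, poly: Polygon) -> "Contour":
        return cls(np.asarray(poly.exterior.coords)[:-1])


@dataclass(frozen=True)
class PlaqueRegion:
    """Labelled intimal inclusion: lipid pool or calcium deposit."""

    label: str
    boundary: Contour

    def __post_init__(self):
        if self.label not in PLAQUE_LABELS:
            raise GeometryError(
                f"unknown plaque label {self.label!r}; must be one of {PLAQUE_LABELS}")


@dataclass(frozen=True)
class CrossSection:
    """Full morphologic description of one imaged frame."""

    frame_id: int
    pullback_position: float  # mm along the pullback
    lumen: Contour
    iel: Contour
    regions: tuple[PlaqueRegion, ...] = ()
    media_thickness: float = 0.2  # mm
    adventitia_thickness: float = 0.3  # mm

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.media_thickness <= 0 or self.adventitia_thickness <= 0:
            raise GeometryError("media and adventitia thicknesses must be positive")
        if not self.iel.polygon.contains(self.lumen.polygon):
            raise GeometryError("lumen contour must lie strictly inside the IEL contour")

    @property
    def lumen_area(self) -> float:
        return self.lumen.area

    @property
    def plaque_burden(self) -> float:
        return compute_plaque_burden(self.lumen, self.iel)


@dataclass
class LayeredGeometry:
    """Multi-material tiling of the wall annulus between lumen and outer boundary.

    ``faces`` maps each material label to a list of disjoint shapely polygons;
    together the faces tile the annulus between ``lumen_boundary`` and
    ``outer_boundary`` exactly.
    """

    faces: dict[str, list[Polygon]]
    lumen_boundary: Contour
    outer_boundary: Contour
    interfaces: list[LineString] = field(default_factory=list)

    def area(self, label: str) -> float:
        return float(sum(p.area for p in self.faces.get(label, [])))

    def total_area(self) -> float:
        return float(sum(self.area(lbl) for lbl in self.faces))


@dataclass(frozen=True)
class LesionMarkers:
    """Representative frame ids within one lesion.

    mla: minimal-lumen-area frame; ps/ds: proximal/distal shoulders (midpoints
    between the reference — or lesion edge — and the MLA); pr/dr: plaque-free
    reference frames when present.
    """

    ps: int
    mla: int
    ds: int
    pr: int | None = None
    dr: int | None = None

    def __post_init__(self):
        present = [f for f in (self.pr, self.ps, self.mla, self.ds, self.dr)
                   if f is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise GeometryError(f"marker frames out of order: {present}")

    def labelled(self) -> dict[str, int]:
        out = {}
        for name in ("pr", "ps", "mla", "ds", "dr"):
            v = getattr(self, name)
            if v is not None:
                out[name.upper()] = v
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def select_representative_frames(lumen_areas, lesion_bounds=None,
                                 pr: int | None = None,
                                 dr: int | None = None) -> LesionMarkers:
    """Pick the representative frames of a lesion from its per-frame lumen areas.

    The MLA frame minimizes lumen area within ``lesion_bounds`` (inclusive
    frame-id range; defaults to the whole record).  Shoulders are frame-index
    midpoints between the reference frame (or the lesion edge when no
    reference exists) and the MLA, floored toward the proximal side.

    Parameters
    ----------
    lumen_areas : mapping or sequence
        ``{frame_id: area_mm2}`` or a sequence indexed by frame id.
    lesion_bounds : (first, last) frame ids, inclusive.
    pr, dr : frame ids of the proximal/distal plaque-free references, if seen.
    """
    if hasattr(lumen_areas, "items"):
        areas = {int(k): float(v) for k, v in lumen_areas.items()}
    else:
        areas = {i: float(a) for i, a in enumerate(lumen_areas)}
    if lesion_bounds is None:
        lesion_bounds = (min(areas), max(areas))
    lo, hi = int(lesion_bounds[0]), int(lesion_bounds[1])
    frames = [f for f in sorted(areas) if lo <= f <= hi]
    if not frames:
        raise GeometryError("empty lesion frame range")
    if len(frames) < 3:
        raise GeometryError(f"need >=3 frames in the lesion, got {len(frames)}")
    if any(areas[f] <= 0 for f in frames):
        raise GeometryError("lumen areas must be positive")

    amin = min(areas[f] for f in frames)
    tied = [f for f in frames if areas[f] == amin]
    mla = tied[0]
    if len(tied) > 1:
        log.info("MLA tie among frames %s; picking most proximal (%d)", tied, mla)

    p_anchor = pr if pr is not None else lo
    d_anchor = dr if dr is not None else hi
    if not (p_anchor < mla < d_anchor):
        raise GeometryError(
            f"MLA frame {mla} must lie strictly between anchors {p_anchor}, {d_anchor}")
    ps = (p_anchor + mla) // 2
    ds = (mla + d_anchor) // 2
    return LesionMarkers(pr=pr, ps=ps, mla=mla, ds=ds, dr=dr)


def offset_contour(c: Contour, t: float, n_vertices: int | None = None) -> Contour:
    """Offset a closed contour uniformly outward by ``t`` mm.

    The contour is resampled to uniform arc length first (stable normals),
    then buffered with round joins.  ``t = 0`` returns the contour unchanged.
    """
    if t < 0:
        raise GeometryError("offset distance must be non-negative")
    if t == 0:
        return c
    if n_vertices is None:
        n_vertices = max(128, len(c.points))
    base = c.resample(n_vertices)
    out = base.polygon.buffer(t, quad_segs=32, join_style="round")
    if out.geom_type != "Polygon" or not out.is_valid or out.interiors:
        raise GeometryError(f"offset by {t} mm self-intersects")
    return Contour.from_polygon(shapely.remove_repeated_points(out, 1e-12)).resample(n_vertices)


def build_layered_geometry(cs: CrossSection) -> LayeredGeometry:
    """Assemble the three-layer, multi-material wall model of one cross-section.

    Media and adventitia are uniform bands offset outward from the IEL; the
    intima (lumen-to-IEL annulus) is fibrous background with lipid/calcium
    inclusions clipped to it.  Where lipid and calcium overlap, calcium wins
    (its delineation is the higher-confidence one on OCT).
    """
    lumen_poly = cs.lumen.polygon
    iel_poly = cs.iel.polygon
    if not iel_poly.contains(lumen_poly):
        raise GeometryError("lumen and IEL contours intersect")

    media_outer = offset_contour(cs.iel, cs.media_thickness)
    outer = offset_contour(cs.iel, cs.media_thickness + cs.adventitia_thickness)
    media_band = media_outer.polygon.difference(iel_poly)
    adventitia_band = outer.polygon.difference(media_outer.polygon)

    intima = iel_poly.difference(lumen_poly)
    calcium_raw = unary_union([r.boundary.polygon for r in cs.regions
                               if r.label == "calcium"])
    lipid_raw = unary_union([r.boundary.polygon for r in cs.regions
                             if r.label == "lipid"])

    def _clip(geom, name):
        clipped = geom.intersection(intima)
        lost = geom.area - clipped.area
        if lost > 1e-6 * max(geom.area, 1e-12) and geom.area > 0:
            warnings.warn(
                f"{name} region extends outside the intima; "
                f"{lost:.4g} mm^2 clipped away", stacklevel=3)
        return clipped

    calcium = _clip(calcium_raw, "calcium")
    lipid = _clip(lipid_raw, "lipid").difference(calcium)  # calcium wins overlap
    fibrous = intima.difference(unary_union([calcium, lipid]))

    def _faces(geom) -> list[Polygon]:
        if geom.is_empty:
            return []
        polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
        return [p for p in polys if p.area > 1e-10]

    faces = {
        "intima_fibrous": _faces(fibrous),
        "intima_lipid": _faces(lipid),
        "intima_calcium": _faces(calcium),
        "media": _faces(media_band),
        "adventitia": _faces(adventitia_band),
    }
    geom = LayeredGeometry(faces=faces, lumen_boundary=cs.lumen, outer_boundary=outer,
                           interfaces=[LineString(cs.iel.points),
                                       LineString(media_outer.points)])
    intima_parts = sum(geom.area(k) for k in
                       ("intima_fibrous", "intima_lipid", "intima_calcium"))
    if abs(intima_parts - intima.area) > 1e-3 * intima.area:
        raise GeometryError("intimal faces fail to tile the lumen-IEL annulus")
    return geom


def complete_partial_iel(visible_arc: np.ndarray, method: str = "ellipse_fit",
                         n_vertices: int = 128) -> Contour:
    """Close a partially visible IEL arc by least-squares ellipse extrapolation.

    On OCT the outer wall is often shadowed behind lipid; when at least half of
    the IEL circumference is visible its near-elliptical shape can be
    extrapolated.  Arcs under 180 deg are refused — use the IEL of an adjacent
    frame instead.
    """
    if method != "ellipse_fit":
        raise ValueError(f"unknown completion method {method!r}")
    pts = np.asarray(visible_arc, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise GeometryError("visible arc must be an (n>=6, 2) point array")
    center = pts.mean(axis=0)
    # direct algebraic ellipse fit, numerically stable partitioned form
    # (Halir-Flusser variant of the Fitzgibbon constrained conic fit)
    x, y = pts[:, 0] - center[0], pts[:, 1] - center[1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1, S2, S3 = D1.T @ D1, D1.T @ D2, D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    w, v = np.linalg.eig(M)
    cond = 4.0 * v[0] * v[2] - v[1] ** 2  # ellipse condition per eigenvector
    good = np.flatnonzero(np.real(cond) > 0)
    if len(good) == 0:
        raise GeometryError("ellipse fit degenerated to a non-elliptic conic")
    a1 = np.real(v[:, good[0]])
    coef = np.concatenate([a1, T @ a1])
    a, b, cc, d, e, f = coef
    M = np.array([[a, b / 2], [b / 2, cc]])
    if np.linalg.det(M) <= 0:
        raise GeometryError("ellipse fit degenerated to a non-elliptic conic")
    c0 = np.linalg.solve(2 * M, -np.array([d, e]))
    # angular coverage measured about the fitted ellipse centre (a point
    # centroid or circle fit would misjudge the span of eccentric arcs)
    ang = np.unwrap(np.arctan2(pts[:, 1] - center[1] - c0[1],
                               pts[:, 0] - center[0] - c0[0]))
    span = float(ang.max() - ang.min())
    if span < np.pi - 1e-6:
        raise GeometryError(
            f"visible IEL arc spans only {math.degrees(span):.0f} deg (<180 deg); "
            "substitute the IEL of an adjacent frame instead")
    val = a * c0[0] ** 2 + b * c0[0] * c0[1] + cc * c0[1] ** 2 + d * c0[0] + e * c0[1] + f
    evals, evecs = np.linalg.eigh(M / (-val))
    axes = 1.0 / np.sqrt(evals)
    tilt = math.atan2(evecs[1, 0], evecs[0, 0])
    return Contour.ellipse(axes[0], axes[1], center=center + c0, angle=tilt,
                           n=n_vertices)


def compute_plaque_burden(lumen: Contour, iel: Contour) -> float:
    """Plaque burden in percent: 100 * (IEL area - lumen area) / IEL area."""
    if not iel.polygon.contains(lumen.polygon) and not iel.polygon.equals(lumen.polygon):
        if not iel.polygon.buffer(1e-9).contains(lumen.polygon):
            raise GeometryError("lumen must be nested inside the IEL")
    return 100.0 * (iel.area - lumen.area) / iel.area


def measure_cap_thickness(lumen: Contour, lipid: PlaqueRegion | None) -> float | None:
    """Minimum fibrous-cap thickness in micrometres.

    The cap is the tissue between the lumen surface and the lipid pool; its
    thickness is the minimum distance between the two boundary polylines.
    Returns ``None`` when the frame has no lipid pool (fibrous-only plaque has
    no cap to measure).
    """
    if lipid is None:
        return None
    ring_l = LineString(np.vstack([lumen.points, lumen.points[:1]]))
    ring_p = LineString(np.vstack([lipid.boundary.points, lipid.boundary.points[:1]]))
    return 1000.0 * float(ring_l.distance(ring_p))
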