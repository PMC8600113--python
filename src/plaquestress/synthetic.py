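"""Synthetic study generator.

No public OCT + pressure-wire dataset exists for this pipeline, so every
stage is exercised on idealized but physiologically scaled synthetic inputs:

* cross-sections: smoothly perturbed circular lumen/IEL contours with an
  eccentric lipid pool at a prescribed fibrous-cap thickness and an optional
  calcium arc (lumen radius ~0.8-2 mm, wall ~0.6-1 mm, caps 50-300 um);
* pressure tracings: a two-harmonic aortic waveform (systolic peak plus
  dicrotic bump) between prescribed systolic/diastolic bounds at ~1 Hz, with
  the distal channel a scaled copy (trans-lesion gradient) plus noise;
* OFR pullbacks: unity proximally with a sigmoidal drop across the lesion.

Everything is deterministic for a fixed seed.  The default parameter ranges
echo the scales of intermediate coronary lesions (MLA around 2.7 mm^2,
plaque burden ~30% in normal vs ~55-70% in diseased segments); they define
study conditions, never expected outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from .geometry import Contour, CrossSection, GeometryError, PlaqueRegion
from .pressure import OFRPullback, PressureTracing

__all__ = ["SectionSpec", "CohortSpec", "make_section", "make_pressure_tracing",
           "make_ofr_pullback", "make_cohort"]


@dataclass(frozen=True)
class SectionSpec:
    """Morphologic recipe for one idealized cross-section."""

    lumen_radius: float = 1.5        # mm
    wall_thickness: float = 0.5      # mm, mean intimal thickness (lumen to IEL)
    eccentricity: float = 0.0        # [0, 1): lumen offset / wall thickness
    lipid_arc: float = 0.0           # degrees of lipid pool, 0 = none
    cap_thickness: float = 150.0     # um, lumen-to-pool minimum distance
    calcium_arc: float = 0.0         # degrees of calcium deposit, 0 = none
    media_thickness: float = 0.2     # mm
    adventitia_thickness: float = 0.3  # mm
    perturbation: float = 0.02       # relative harmonic waviness of contours
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.eccentricity < 1):
            raise GeometryError("eccentricity must lie in [0, 1)")
        for arc in (self.lipid_arc, self.calcium_arc):
            if not (0 <= arc < 360):
                raise GeometryError("plaque arcs must lie in [0, 360) degrees")
        if self.cap_thickness >= self.wall_thickness * 1000.0:
            raise GeometryError("cap thickness must be smaller than the wall")
        if self.lumen_radius <= 0 or self.wall_thickness <= 0:
            raise GeometryError("radius and wall thickness must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for a mixed normal/diseased section cohort."""

    n_normal: int = 5
    n_diseased: int = 5
    seed: int = 0
    normal_lumen_radius: tuple = (1.35, 1.95)
    normal_wall: tuple = (0.28, 0.42)
    diseased_lumen_radius: tuple = (0.85, 1.35)
    diseased_wall: tuple = (0.60, 0.95)
    diseased_lipid_arc: tuple = (70.0, 140.0)
    diseased_cap: tuple = (50.0, 300.0)
    calcium_arc: tuple = (30.0, 70.0)
    calcium_probability: float = 0.5

    def __post_init__(self):
        if self.n_normal < 1 or self.n_diseased < 1:
            raise ValueError("cohort needs at least one section per group")


def _wavy_circle(radius: float, center, rng: np.random.Generator,
                 amplitude: float, n: int = 160) -> Contour:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = np.full_like(t, radius)
    for mode in (2, 3, 4):
        r += radius * amplitude * float(rng.uniform(-1, 1)) / mode * np.cos(
            mode * t + float(rng.uniform(0, 2 * np.pi)))
    return Contour(np.column_stack([center[0] + r * np.cos(t),
                                    center[1] + r * np.sin(t)]))


def make_section(spec: SectionSpec, frame_id: int = 0,
                 pullback_position: float = 0.0) -> CrossSection:
    """Build one idealized cross-section; deterministic for a fixed seed.

    The IEL is centred at the origin; the lumen is shifted toward +x by
    ``eccentricity * wall_thickness``, so the plaque is thickest on the -x
    side, where the lipid pool (as an annular band at ``cap_thickness`` from
    the lumen, cut by a disk) and the calcium deposit are placed.
    """
    rng = np.random.default_rng(spec.seed)
    r_iel = spec.lumen_radius + spec.wall_thickness
    shift = spec.eccentricity * spec.wall_thickness
    lumen = _wavy_circle(spec.lumen_radius, (shift, 0.0), rng,
                         spec.perturbation)
    iel = _wavy_circle(r_iel, (0.0, 0.0), rng, spec.perturbation * 0.5)
    if not iel.polygon.contains(lumen.polygon):
        raise GeometryError("spec puts the lumen outside the IEL "
                            "(eccentricity or waviness too large)")

    regions = []
    thick_wall = spec.wall_thickness * (1.0 + spec.eccentricity)
    if spec.lipid_arc > 0:
        cap_mm = spec.cap_thickness / 1000.0
        pool_outer = thick_wall - 0.12           # keep an outer fibrous margin
        if pool_outer - cap_mm < 0.1:
            raise GeometryError(
                "wall too thin for the requested cap thickness and lipid pool")
        band = (lumen.polygon.buffer(pool_outer, quad_segs=32)
                .difference(lumen.polygon.buffer(cap_mm, quad_segs=32)))
        r_mid = spec.lumen_radius + (cap_mm + pool_outer) / 2.0
        half = np.radians(spec.lipid_arc) / 2.0
        disk = Point(-r_mid + shift, 0.0).buffer(
            max(r_mid * np.sin(half), 0.18) + (pool_outer - cap_mm) / 2.0,
            quad_segs=32)
        pool = band.intersection(disk).intersection(
            iel.polygon.buffer(-0.05, quad_segs=16))
        pool = pool.buffer(-0.02, quad_segs=16).buffer(0.02, quad_segs=16)
        if pool.is_empty:
            raise GeometryError("lipid pool construction produced an empty region")
        if pool.geom_type != "Polygon":
            pool = max(pool.geoms, key=lambda g: g.area)
        regions.append(PlaqueRegion("lipid", Contour.from_polygon(pool)))

    if spec.calcium_arc > 0:
        # deposit deeper in the plaque, rotated 135 deg away from the pool
        theta = np.radians(135.0)
        depth_in = min(0.25, thick_wall * 0.35)
        depth_out = min(depth_in + 0.3, thick_wall - 0.08)
        if depth_out - depth_in < 0.05:
            raise GeometryError("wall too thin for a calcium deposit")
        band = (lumen.polygon.buffer(depth_out, quad_segs=32)
                .difference(lumen.polygon.buffer(depth_in, quad_segs=32)))
        r_mid = spec.lumen_radius + (depth_in + depth_out) / 2.0
        half = np.radians(spec.calcium_arc) / 2.0
        cx = shift + r_mid * np.cos(np.pi - theta)
        cy = r_mid * np.sin(np.pi - theta)
        disk = Point(cx, cy).buffer(
            max(r_mid * np.sin(half), 0.12) + (depth_out - depth_in) / 2.0,
            quad_segs=32)
        dep = band.intersection(disk).intersection(
            iel.polygon.buffer(-0.04, quad_segs=16))
        dep = dep.buffer(-0.015, quad_segs=16).buffer(0.015, quad_segs=16)
        if not dep.is_empty:
            if dep.geom_type != "Polygon":
                dep = max(dep.geoms, key=lambda g: g.area)
            if dep.area > 0.02:
                regions.append(PlaqueRegion("calcium", Contour.from_polygon(dep)))

    return CrossSection(frame_id=frame_id, pullback_position=pullback_position,
                        lumen=lumen, iel=iel, regions=tuple(regions),
                        media_thickness=spec.media_thickness,
                        adventitia_thickness=spec.adventitia_thickness)


def make_pressure_tracing(systolic: float = 120.0, diastolic: float = 80.0,
                          hr: float = 75.0, n_beats: int = 3,
                          gradient: float = 0.1, noise_sd: float = 0.0,
                          fs: float = 200.0, seed: int = 0) -> PressureTracing:
    """Two-harmonic aortic waveform with a scaled, noisy distal channel.

    ``gradient`` is the fractional trans-lesion pressure loss (Pd = (1 - g) Pa
    plus noise); the waveform attains the systolic/diastolic bounds exactly.
    """
    if not systolic > diastolic > 0:
        raise ValueError("need systolic > diastolic > 0")
    if not (0.0 <= gradient <= 0.9):
        raise ValueError("gradient must lie in [0, 0.9]")
    rng = np.random.default_rng(seed)
    period = 60.0 / hr
    t = np.arange(0.0, n_beats * period, 1.0 / fs)
    phase = (t / period) % 1.0
    raw = (np.sin(np.pi * np.clip(phase / 0.72, 0, 1)) ** 2
           + 0.18 * np.sin(2 * np.pi * np.clip((phase - 0.38) / 0.4, 0, 1)) ** 2)
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    pa = diastolic + (systolic - diastolic) * raw
    pd = pa * (1.0 - gradient)
    if noise_sd > 0:
        pd = pd + rng.normal(0.0, noise_sd, size=pd.shape)
        pd = np.minimum(pd, pa)  # the wire never reads above aortic
    return PressureTracing(t, pa, pd)


def make_ofr_pullback(length: float = 50.0, lesion_center: float = 25.0,
                      drop: float = 0.15, width: float = 6.0,
                      spacing: float = 0.2) -> OFRPullback:
    """Sigmoidal OFR pullback: 1.0 proximally, plateau 1 - drop distally."""
    if not (0.0 <= drop < 0.99):
        raise ValueError("drop must lie in [0, 0.99)")
    if width <= 0:
        raise ValueError("width must be positive")
    x = np.arange(0.0, length + spacing / 2, spacing)
    v = 1.0 - drop / (1.0 + np.exp((x - lesion_center) / (width / 8.0)))
    return OFRPullback(x, v)


_DISEASED_LABELS = ("PS", "MLA", "DS")
_NORMAL_LABELS = ("PR", "DR")

# pullback positions (mm, distal -> proximal) consistent with the marker
# anatomy on a 20 mm pullback whose lesion is centred at 10 mm: the proximal
# reference sits above the OFR drop, the distal reference below it, and the
# shoulders/MLA straddle the transition.
LABEL_PULLBACK_POSITION = {"PR": 16.0, "PS": 12.0, "MLA": 10.0, "DS": 8.0,
                           "DR": 4.0}


def make_cohort(spec: CohortSpec) -> list[tuple[CrossSection, str]]:
    """Sample a labelled cohort: fibrous-only normal sections (PR/DR) and
    lipid-bearing diseased sections (PS/MLA/DS), parameters uniform in the
    configured ranges, fully seeded.  Pullback positions follow the marker
    anatomy (see :data:`LABEL_PULLBACK_POSITION`)."""
    rng = np.random.default_rng(spec.seed)
    out = []
    fid = 0
    for i in range(spec.n_normal):
        s = SectionSpec(
            lumen_radius=float(rng.uniform(*spec.normal_lumen_radius)),
            wall_thickness=float(rng.uniform(*spec.normal_wall)),
            eccentricity=float(rng.uniform(0.0, 0.2)),
            lipid_arc=0.0, calcium_arc=0.0,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        label = _NORMAL_LABELS[i % 2]
        out.append((make_section(s, frame_id=fid,
                                 pullback_position=LABEL_PULLBACK_POSITION[label]),
                    label))
        fid += 1
    for i in range(spec.n_diseased):
        s = SectionSpec(
            lumen_radius=float(rng.uniform(*spec.diseased_lumen_radius)),
            wall_thickness=float(rng.uniform(*spec.diseased_wall)),
            eccentricity=float(rng.uniform(0.3, 0.6)),
            lipid_arc=float(rng.uniform(*spec.diseased_lipid_arc)),
            cap_thickness=float(rng.uniform(*spec.diseased_cap)),
            calcium_arc=(float(rng.uniform(*spec.calcium_arc))
                         if rng.uniform() < spec.calcium_probability else 0.0),
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        label = _DISEASED_LABELS[i % 3]
        out.append((make_section(s, frame_id=fid,
                                 pullback_position=LABEL_PULLBACK_POSITION[label]),
                    label))
        fid += 1
    return out
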