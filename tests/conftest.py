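"""Shared fixtures.

Heavy objects (meshes, solved load cycles) are session-scoped so the suite
meshes and solves each benchmark geometry once.
"""

import numpy as np
import pytest

from plaquestress.geometry import Contour, CrossSection, build_layered_geometry
from plaquestress.mesh import generate_mesh
from plaquestress.solver import SolverConfig, assign_materials, solve_cycle
from plaquestress.synthetic import SectionSpec, make_section

# uniform near-incompressible neo-Hookean wall: shear modulus G = 2 mu
NEOHOOKEAN_MU = 25.0


def neohookean_table(mu=NEOHOOKEAN_MU):
    entry = {"model": "holzapfel",
             "parameters": {"mu": mu, "k1": 1e-8, "k2": 1.0, "rho": 0.0}}
    return {k: dict(entry) for k in
            ("lipid", "calcium", "fibrous", "media", "adventitia")}


@pytest.fixture(scope="session")
def annulus_cs():
    """Thick-walled annulus r 1.5..2.5 mm (intima 0.5 + media 0.2 + adventitia 0.3)."""
    return CrossSection(0, 0.0, Contour.circle(1.5, n=256),
                        Contour.circle(2.0, n=256), (), 0.2, 0.3)


@pytest.fixture(scope="session")
def annulus_geom(annulus_cs):
    return build_layered_geometry(annulus_cs)


@pytest.fixture(scope="session")
def annulus_mesh(annulus_geom):
    return generate_mesh(annulus_geom)


@pytest.fixture(scope="session")
def lame_case(annulus_mesh):
    """Small-strain pressurization of the uniform neo-Hookean annulus.

    Internal pressure 0.4 kPa keeps the maximal strain well below 1% so the
    linear-elastic thick-walled-cylinder solution applies.
    """
    mats = assign_materials(annulus_mesh, neohookean_table(), kappa_factor=1000.0)
    steps = solve_cycle(annulus_mesh, mats, 0.4, config=SolverConfig(n_steps=2))
    return {"mesh": annulus_mesh, "steps": steps, "pressure": 0.4,
            "G": 2 * NEOHOOKEAN_MU, "kappa": 1000.0 * (2 * NEOHOOKEAN_MU + 1e-8),
            "ri": 1.5, "ro": 2.5}


@pytest.fixture(scope="session")
def fibroatheroma_spec():
    """Eccentric lipid-rich plaque, 110 deg pool, 150 um cap."""
    return SectionSpec(lumen_radius=1.0, wall_thickness=0.8, eccentricity=0.4,
                       lipid_arc=110.0, cap_thickness=150.0, seed=3)


@pytest.fixture(scope="session")
def fibroatheroma_mesh(fibroatheroma_spec):
    return generate_mesh(build_layered_geometry(make_section(fibroatheroma_spec)))


def solve_fibroatheroma(spec: SectionSpec, peak_kpa: float = 5.0,
                        h_superficial: float = 0.045, h_bulk: float = 0.15,
                        n_steps: int = 5):
    cs = make_section(spec)
    mesh = generate_mesh(build_layered_geometry(cs),
                         h_superficial=h_superficial, h_bulk=h_bulk)
    mats = assign_materials(mesh)
    steps = solve_cycle(mesh, mats, peak_kpa, config=SolverConfig(n_steps=n_steps))
    return cs, mesh, steps


def ray_cast_inside(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Independent point-in-polygon test (even-odd ray casting), vectorized."""
    x, y = points[:, 0], points[:, 1]
    n = len(polygon)
    inside = np.zeros(len(points), bool)
    px, py = polygon[:, 0], polygon[:, 1]
    for i in range(n):
        x1, y1 = px[i], py[i]
        x2, y2 = px[(i + 1) % n], py[(i + 1) % n]
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < xint)
    return inside


def shoelace(points: np.ndarray) -> float:
    """Independent polygon area oracle."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
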