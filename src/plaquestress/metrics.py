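"""Endpoint quantities of the cyclic-stress analysis.

* dPSS — the change in plaque structural stress over the cardiac cycle: the
  maximal von Mises stress among *superficial* elements (reference-state
  centroid within 50 um of the lumen) at the step of maximal pressure load.
* LDC — lumen diameter change: maximal minus minimal effective lumen diameter
  over the cycle, where the effective diameter is the area-equivalent
  2*sqrt(A/pi) (rotation-invariant and stable, since no caliper direction is
  canonical for an irregular lumen).
* LDC% — LDC divided by the minimal diameter, in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh import FEMesh
from .solver import SolutionStep

__all__ = ["StressMetrics", "von_mises", "compute_dpss", "compute_ldc",
           "effective_diameter"]


@dataclass
class StressMetrics:
    """Per-frame result row."""

    frame_id: int
    dpss: float                 # kPa
    dpss_location: tuple        # (x, y) mm
    dpss_element: int
    ldc: float                  # mm
    ldc_percent: float          # %
    peak_load: float            # kPa
    plaque_burden: float | None = None   # %
    cap_thickness: float | None = None   # um; None when no lipid pool
    position_label: str | None = None

    def as_row(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "position_label": self.position_label or "",
            "dpss_kpa": self.dpss,
            "ldc_mm": self.ldc,
            "ldc_percent": self.ldc_percent,
            "plaque_burden_pct": (math.nan if self.plaque_burden is None
                                  else self.plaque_burden),
            "cap_thickness_um": (math.nan if self.cap_thickness is None
                                 else self.cap_thickness),
            "peak_load_kpa": self.peak_load,
        }


def von_mises(sigma: np.ndarray) -> float | np.ndarray:
    """Von Mises equivalent of a symmetric 3x3 stress tensor (kPa).

    Includes the out-of-plane sigma_zz of the plane-strain state; a
    hydrostatic tensor maps to exactly zero.
    """
    sigma = np.asarray(sigma, float)
    if sigma.shape[-2:] != (3, 3):
        raise ValueError("stress must be (..., 3, 3)")
    if np.max(np.abs(sigma - np.swapaxes(sigma, -1, -2))) > 1e-9:
        raise ValueError("stress tensor is not symmetric")
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    dev = sigma - (tr / 3.0)[..., None, None] * np.eye(3)
    out = np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
    return float(out) if out.ndim == 0 else out


def compute_dpss(steps: list[SolutionStep], superficial_set: np.ndarray,
                 mesh: FEMesh) -> tuple[float, tuple, int]:
    """Max superficial von Mises stress at the maximal-load step.

    Returns (dpss_kPa, centroid_xy, element_id).
    """
    if len(superficial_set) == 0:
        raise ValueError("empty superficial element set")
    if not steps:
        raise ValueError("no solution steps")
    peak_step = max(steps, key=lambda s: s.pressure)
    vm = peak_step.von_mises[superficial_set]
    k = int(np.argmax(vm))
    elem = int(superficial_set[k])
    xy = tuple(mesh.centroids()[elem])
    return float(vm[k]), xy, elem


def effective_diameter(contour) -> float:
    """Area-equivalent lumen diameter 2*sqrt(A/pi), mm."""
    a = contour.area
    if a <= 0:
        raise ValueError("degenerate lumen polygon")
    return 2.0 * math.sqrt(a / math.pi)


def compute_ldc(steps: list[SolutionStep]) -> tuple[float, float]:
    """(LDC mm, LDC%) from the deformed lumen contours of all steps."""
    if len(steps) < 2:
        raise ValueError("need at least the zero-load and one loaded step")
    d = np.array([effective_diameter(s.deformed_lumen) for s in steps])
    ldc = float(d.max() - d.min())
    return ldc, 100.0 * ldc / float(d.min())
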