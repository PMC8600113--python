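"""File formats: cross-section YAML, geometry WKT, legacy-ASCII VTK export.

Cross-sections travel as structured YAML (one document per frame) so a study
is fully text-based and diffable.  Meshes and per-step fields are written as
legacy ASCII VTK unstructured grids readable by ParaView and friends.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .geometry import Contour, CrossSection, LayeredGeometry, PlaqueRegion
from .mesh import FEMesh

__all__ = ["write_sections", "read_sections", "write_vtk", "export_geometry_wkt"]


def _section_doc(cs: CrossSection, label: str | None) -> dict:
    doc = {
        "frame_id": int(cs.frame_id),
        "pullback_position_mm": float(cs.pullback_position),
        "lumen": [[float(x), float(y)] for x, y in cs.lumen.points],
        "iel": [[float(x), float(y)] for x, y in cs.iel.points],
        "regions": [{"label": r.label,
                     "points": [[float(x), float(y)] for x, y in r.boundary.points]}
                    for r in cs.regions],
        "media_thickness_mm": float(cs.media_thickness),
        "adventitia_thickness_mm": float(cs.adventitia_thickness),
    }
    if label is not None:
        doc["position_label"] = label
    return doc


def write_sections(path, sections) -> None:
    """Write cross-sections to multi-document YAML.

    ``sections`` is an iterable of ``CrossSection`` or ``(CrossSection,
    position_label)`` pairs.
    """
    docs = []
    for item in sections:
        cs, label = item if isinstance(item, tuple) else (item, None)
        docs.append(_section_doc(cs, label))
    with open(path, "w") as fh:
        yaml.safe_dump_all(docs, fh, sort_keys=False)


def read_sections(path) -> list[tuple[CrossSection, str | None]]:
    """Read cross-sections (and optional position labels) from YAML."""
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    out = []
    for doc in docs:
        regions = tuple(PlaqueRegion(r["label"], Contour(np.asarray(r["points"])))
                        for r in doc.get("regions", []))
        cs = CrossSection(
            frame_id=int(doc["frame_id"]),
            pullback_position=float(doc["pullback_position_mm"]),
            lumen=Contour(np.asarray(doc["lumen"])),
            iel=Contour(np.asarray(doc["iel"])),
            regions=regions,
            media_thickness=float(doc["media_thickness_mm"]),
            adventitia_thickness=float(doc["adventitia_thickness_mm"]))
        out.append((cs, doc.get("position_label")))
    return out


def write_vtk(path, mesh: FEMesh, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Write a labelled triangle mesh as a legacy ASCII VTK unstructured grid."""
    lines = ["# vtk DataFile Version 3.0", "plaquestress cross-section mesh",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    M = mesh.n_elements
    lines.append(f"CELLS {M} {4 * M}")
    for tri in mesh.elements:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    lines.append(f"CELL_TYPES {M}")
    lines.extend(["5"] * M)

    label_ids = {lbl: i for i, lbl in enumerate(sorted(set(mesh.labels.tolist())))}
    cdata = {"region": np.array([label_ids[l] for l in mesh.labels]),
             "superficial": np.isin(np.arange(M), mesh.superficial_set).astype(int)}
    cdata.update(cell_data or {})
    lines.append(f"CELL_DATA {M}")
    for name, arr in cdata.items():
        arr = np.asarray(arr)
        typ = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {typ} 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" if typ == "double" else str(int(v)) for v in arr)

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:  # vector field
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.9g} {v[1]:.9g} 0" for v in arr)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def export_geometry_wkt(path, geom: LayeredGeometry) -> None:
    """Dump the layered faces as labelled WKT, one polygon per line."""
    with open(path, "w") as fh:
        for label, faces in geom.faces.items():
            for poly in faces:
                fh.write(f"{label}\t{poly.wkt}\n")
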