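"""Per-lesion orchestration: sections -> geometry -> load -> mesh -> solve -> metrics.

``run_lesion`` drives the full analysis for every cross-section of a study
and writes a results CSV, per-frame VTK fields and a machine-readable JSON
manifest.  Frame failures are isolated: one diverging frame is recorded in
the manifest and the remaining frames still produce rows.  Identical config
and seed give bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import build_layered_geometry, measure_cap_thickness
from .io import read_sections, write_vtk
from .materials import default_material_table
from .mesh import generate_mesh
from .metrics import StressMetrics, compute_dpss, compute_ldc
from .pressure import (OFRPullback, PressureTracing, extract_representative_beat,
                       position_pressure, relative_pressure)
from .solver import (BoundaryConditions, SolverConfig, assign_materials,
                     solve_cycle)

__all__ = ["RunConfig", "run_lesion", "summarize_cohort", "NORMAL_LABELS",
           "DISEASED_LABELS"]

log = logging.getLogger(__name__)

NORMAL_LABELS = ("PR", "DR")
DISEASED_LABELS = ("PS", "MLA", "DS")

_CSV_FLOAT_FORMAT = "%.9g"


@dataclass
class RunConfig:
    sections_file: str
    tracing_file: str
    pullback_file: str
    output_dir: str = "results"
    material_table: dict | None = None        # None -> package defaults
    h_superficial: float = 0.045              # mm
    h_bulk: float = 0.15                      # mm
    superficial_depth_um: float = 50.0
    n_steps: int = 10
    kappa_factor: float = 1000.0
    follower_load: bool = True
    write_fields: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        base = Path(path).parent
        cfg = cls(**raw)
        for name in ("sections_file", "tracing_file", "pullback_file", "output_dir"):
            p = Path(getattr(cfg, name))
            if not p.is_absolute():
                setattr(cfg, name, str(base / p))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _analyze_frame(cs, label, tracing, pullback, table, cfg: RunConfig):
    t0 = time.perf_counter()
    geom = build_layered_geometry(cs)
    mesh = generate_mesh(geom, h_superficial=cfg.h_superficial, h_bulk=cfg.h_bulk,
                         superficial_depth_um=cfg.superficial_depth_um)
    beat = extract_representative_beat(tracing)
    x = min(max(cs.pullback_position, pullback.position[0]), pullback.position[-1])
    p_t = position_pressure(beat, pullback, x)
    load = relative_pressure(p_t, beat.time)
    mats = assign_materials(mesh, table, kappa_factor=cfg.kappa_factor)
    sol_cfg = SolverConfig(n_steps=cfg.n_steps, follower_load=cfg.follower_load,
                           kappa_factor=cfg.kappa_factor)
    steps = solve_cycle(mesh, mats, load,
                        BoundaryConditions(pressure_edges=mesh.lumen_edges),
                        sol_cfg)
    dpss, xy, elem = compute_dpss(steps, mesh.superficial_set, mesh)
    ldc, ldc_pct = compute_ldc(steps)
    lipid = next((r for r in cs.regions if r.label == "lipid"), None)
    metrics = StressMetrics(
        frame_id=cs.frame_id, dpss=dpss, dpss_location=xy, dpss_element=elem,
        ldc=ldc, ldc_percent=ldc_pct, peak_load=load.peak,
        plaque_burden=cs.plaque_burden,
        cap_thickness=measure_cap_thickness(cs.lumen, lipid),
        position_label=label)
    return metrics, mesh, steps, time.perf_counter() - t0


def run_lesion(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Analyze every cross-section of a study; returns (results, manifest)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections = read_sections(config.sections_file)
    if not sections:
        raise ValueError("no cross-sections found in the study")
    tracing = PressureTracing.from_csv(config.tracing_file)
    pullback = OFRPullback.from_csv(config.pullback_file)
    table = config.material_table or default_material_table()

    rows, frames_manifest = [], []
    for cs, label in sections:
        try:
            metrics, mesh, steps, dt = _analyze_frame(
                cs, label, tracing, pullback, table, config)
            rows.append(metrics.as_row())
            if config.write_fields:
                peak = max(steps, key=lambda s: s.pressure)
                write_vtk(out_dir / f"frame_{cs.frame_id:04d}.vtk", mesh,
                          cell_data={"von_mises_kpa": peak.von_mises},
                          point_data={"displacement_mm": peak.displacements})
            frames_manifest.append({
                "frame_id": cs.frame_id, "status": "converged",
                "wall_time_s": round(dt, 3),
                "n_elements": mesh.n_elements,
                "newton_iterations_last": steps[-1].newton_iterations})
            log.info("frame %d (%s): dPSS=%.1f kPa, LDC%%=%.2f [%.1fs]",
                     cs.frame_id, label, metrics.dpss, metrics.ldc_percent, dt)
        except Exception as exc:
            frames_manifest.append({"frame_id": cs.frame_id, "status": "failed",
                                    "error": f"{type(exc).__name__}: {exc}"})
            log.warning("frame %d failed: %s", cs.frame_id, exc)

    results = pd.DataFrame(
        rows, columns=["frame_id", "position_label", "dpss_kpa", "ldc_mm",
                       "ldc_percent", "plaque_burden_pct", "cap_thickness_um",
                       "peak_load_kpa"])
    results.to_csv(out_dir / "results.csv", index=False,
                   float_format=_CSV_FLOAT_FORMAT)
    manifest = {
        "software": {"name": "plaquestress", "version": __version__},
        "config": asdict(config),
        "material_table": table,
        "frames": frames_manifest,
        "n_converged": sum(f["status"] == "converged" for f in frames_manifest),
        "n_failed": sum(f["status"] == "failed" for f in frames_manifest),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results, manifest


def summarize_cohort(results: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-position and per-group summary of the endpoint metrics.

    Positions PR/DR form the "normal" group and PS/MLA/DS the "diseased"
    group.  Quartiles use linear interpolation (type 7).
    """
    labels = set(results["position_label"].unique()) - {""}
    unknown = labels - set(NORMAL_LABELS) - set(DISEASED_LABELS)
    if unknown:
        raise ValueError(f"unknown position labels: {sorted(unknown)}")

    df = results.copy()
    df["group"] = np.where(df["position_label"].isin(NORMAL_LABELS),
                           "normal", "diseased")
    out = []
    for by in ("position_label", "group"):
        for key, sub in df.groupby(by, sort=True):
            if key == "":
                continue
            for metric in ("dpss_kpa", "ldc_mm", "ldc_percent"):
                v = sub[metric].dropna().to_numpy()
                if len(v) == 0:
                    continue
                out.append({
                    "level": by, "key": key, "metric": metric, "n": len(v),
                    "mean": float(np.mean(v)),
                    "median": float(np.median(v)),
                    "q1": float(np.quantile(v, 0.25)),
                    "q3": float(np.quantile(v, 0.75)),
                })
    return pd.DataFrame(out)
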