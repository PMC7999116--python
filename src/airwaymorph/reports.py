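"""Reference threshold table, report export, and built-in verification.

The packaged ``table3_thresholds.csv`` holds the reference displacement
threshold points (mm of AP displacement), Youden indices and ROC AUCs per
bony segment, ΔArea cutoff and pharyngeal region; it serves as the
reference for consistency checks and as a fixture for tests.  The
tabulated values are authoritative where narrative summaries of the same
analysis quote slightly different mandibular +100% cut-offs.
"""

from __future__ import annotations

import importlib.resources
import os

import numpy as np
import pandas as pd
import trimesh

from .errors import AirwayMorphError
from .mesh import make_mesh, mesh_volume
from .metrics import (
    N_SLABS,
    REGION_COUNTS,
    partition_airway,
    projected_area,
)

__all__ = ["reference_thresholds", "verify_targets", "export_analysis"]


def reference_thresholds(path: str | None = None) -> pd.DataFrame:
    """Load the packaged (or an alternative) threshold reference table."""
    if path is None:
        res = importlib.resources.files("airwaymorph.data") / "table3_thresholds.csv"
        if not res.is_file():
            raise AirwayMorphError("packaged threshold reference table is missing")
        with importlib.resources.as_file(res) as p:
            df = pd.read_csv(p)
    else:
        if not os.path.exists(path):
            raise AirwayMorphError(f"threshold table not found: {path}")
        df = pd.read_csv(path)
    expected = {"segment", "cutoff_pct", "region", "threshold_mm", "youden_j", "auc"}
    missing = expected - set(df.columns)
    if missing:
        raise AirwayMorphError(f"threshold table lacks columns: {sorted(missing)}")
    return df


def _check(name: str, value, expected, tol=0.0):
    ok = (
        abs(value - expected) <= tol
        if isinstance(expected, (int, float))
        else value == expected
    )
    return {"target": name, "value": value, "expected": expected, "pass": bool(ok)}


def verify_targets(table_path: str | None = None, seed: int = 0) -> pd.DataFrame:
    """Recompute the built-in acceptance quantities from first principles.

    * mean of the six 50 %-ΔArea threshold points (2 dp);
    * min/max of the maxillary threshold column;
    * partition structure (25 slabs; 5/9/11 per region) on a fresh
      synthetic airway;
    * geometry oracles: capped 720-gon cylinder volume and slab projected
      area against the exact n-gon prism formulas.
    """
    t3 = reference_thresholds(table_path)
    fifty = t3[t3.cutoff_pct == 50].threshold_mm
    mx = t3[t3.segment == "maxilla"].threshold_mm
    checks = [
        _check("mean_threshold_50pct_mm", round(float(fifty.mean()), 2), 5.53),
        _check("maxilla_threshold_min_mm", float(mx.min()), 4.8),
        _check("maxilla_threshold_max_mm", float(mx.max()), 7.0),
    ]
    from .synth import generate_airway

    part = partition_airway(generate_airway(seed=seed))
    checks.append(_check("n_slabs", len(part.slabs), N_SLABS))
    for region, n in REGION_COUNTS.items():
        checks.append(_check(f"n_{region}", part.region_counts[region], n))
    n_gon, r, h = 720, 10.0, 50.0
    cyl = trimesh.creation.cylinder(radius=r, height=h, sections=n_gon)
    cyl = make_mesh(cyl.vertices + [0, 0, h / 2], cyl.faces)
    exact_vol = 0.5 * n_gon * r**2 * np.sin(2 * np.pi / n_gon) * h
    vol = mesh_volume(cyl)
    checks.append(
        _check(
            "cylinder_volume_rel_err",
            abs(vol - exact_vol) / exact_vol,
            0.0,
            tol=1e-9,
        )
    )
    exact_area = 0.5 * n_gon * r**2 * np.sin(2 * np.pi / n_gon)
    part_c = partition_airway(cyl)
    areas = np.array([projected_area(cyl, s, 0.1)[0] for s in part_c])
    checks.append(
        _check(
            "cylinder_slab_area_max_rel_err",
            float(np.abs(areas - exact_area).max() / exact_area),
            0.0,
            tol=5e-3,
        )
    )
    return pd.DataFrame(checks)


def export_analysis(analysis, outdir: str, config=None) -> dict:
    """Write the report bundle of a :class:`CohortAnalysis` as CSV files."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, frame in analysis.reports.items():
        p = os.path.join(outdir, f"{name}.csv")
        frame.to_csv(p, index=False)
        paths[name] = p
    p = os.path.join(outdir, "slices.csv")
    analysis.dataset.slices.to_csv(p, index=False)
    paths["slices"] = p
    p = os.path.join(outdir, "volumes.csv")
    analysis.dataset.volumes.to_csv(p, index=False)
    paths["volumes"] = p
    p = os.path.join(outdir, "displacements.csv")
    analysis.displacement_frame.to_csv(p, index=False)
    paths["displacements"] = p
    if analysis.failures:
        p = os.path.join(outdir, "failures.csv")
        pd.DataFrame(analysis.failures).to_csv(p, index=False)
        paths["failures"] = p
    if config is not None:
        p = os.path.join(outdir, "config.json")
        config.to_json(p)
        paths["config"] = p
    return paths
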