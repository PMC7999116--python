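"""End-to-end cohort analysis: registration → slab metrics → threshold stats.

Works either in memory on :class:`airwaymorph.synth.SyntheticCase` objects
or from a manifest directory of STL meshes and landmark JSON files (the
on-disk layout written by :func:`save_cohort`).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import trimesh

from .config import PipelineConfig
from .errors import AirwayMorphError
from .landmarks import LandmarkSet
from .mesh import load_mesh, make_mesh, save_mesh
from .metrics import DeltaTable, case_metrics
from .registration import (
    CaseScan,
    DisplacementRecord,
    align_airway_models,
    compute_bone_displacement,
)
from .stats import SliceDataset, build_slice_dataset, summarize_reports, roc_threshold
from .synth import Cohort, SyntheticCase

log = logging.getLogger("airwaymorph")

__all__ = [
    "CaseResult",
    "CohortAnalysis",
    "posterior_wall_heuristic",
    "analyze_case",
    "analyze_cohort",
    "save_cohort",
    "load_cohort_manifest",
]


def posterior_wall_heuristic(mesh: trimesh.Trimesh, n_bins: int = 20) -> np.ndarray:
    """Face mask of the posterior pharyngeal wall for an arbitrary airway
    model: faces whose centroid lies behind (smaller y than) the per-level
    median of the surface, estimated in z bins."""
    v = mesh.vertices
    edges = np.linspace(v[:, 2].min(), v[:, 2].max(), n_bins + 1)
    idx = np.clip(np.digitize(v[:, 2], edges) - 1, 0, n_bins - 1)
    med = np.array(
        [np.median(v[idx == b, 1]) if (idx == b).any() else np.nan for b in range(n_bins)]
    )
    med = pd.Series(med).ffill().bfill().to_numpy()
    c = mesh.triangles_center
    cbin = np.clip(np.digitize(c[:, 2], edges) - 1, 0, n_bins - 1)
    return c[:, 1] < med[cbin]


@dataclass
class CaseResult:
    patient: str
    group: str
    records: dict  # segment -> DisplacementRecord
    delta: DeltaTable
    icp_rms: float
    icp_iterations: int


@dataclass
class CohortAnalysis:
    cases: list
    dataset: SliceDataset
    reports: dict
    failures: list = field(default_factory=list)

    @property
    def displacement_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            for rec in c.records.values():
                rows.append(
                    {
                        "patient": rec.patient,
                        "segment": rec.segment,
                        "tx": rec.tx,
                        "ty": rec.ty,
                        "tz": rec.tz,
                        "pitch": rec.pitch,
                        "roll": rec.roll,
                        "yaw": rec.yaw,
                        "rms": rec.residual_rms,
                    }
                )
        return pd.DataFrame(rows)


def analyze_case(
    pre: CaseScan,
    post: CaseScan,
    patient: str,
    group: str,
    config: PipelineConfig = PipelineConfig(),
) -> CaseResult:
    """Register one case and measure its slab metrics."""
    records = {
        seg: compute_bone_displacement(pre, post, seg, patient=patient)
        for seg in ("maxilla", "mandible")
    }
    wall = (
        posterior_wall_heuristic(post.airway_mesh) if config.use_posterior_wall else None
    )
    aligned, icp = align_airway_models(
        pre.airway_mesh,
        post.airway_mesh,
        pre.airway_landmarks,
        post.airway_landmarks,
        params=config.icp,
        posterior_wall_faces=wall,
    )
    delta = case_metrics(pre.airway_mesh, aligned, config.pixel_mm, patient=patient)
    return CaseResult(
        patient=patient,
        group=group,
        records=records,
        delta=delta,
        icp_rms=icp.rms,
        icp_iterations=icp.iterations,
    )


def analyze_cohort(
    cases: Iterable,
    config: PipelineConfig = PipelineConfig(),
    continue_on_error: bool = True,
) -> CohortAnalysis:
    """Run the full pipeline over SyntheticCase objects (or (pre, post,
    patient, group) tuples) and assemble the statistical reports."""
    results, failures = [], []
    for case in cases:
        if isinstance(case, SyntheticCase):
            args = (case.pre, case.post, case.patient, case.group)
        else:
            args = case
        try:
            results.append(analyze_case(*args, config=config))
        except AirwayMorphError as exc:
            log.warning("case %s failed: %s", args[2], exc)
            failures.append({"patient": args[2], "error": str(exc)})
            if not continue_on_error:
                raise
    deltas = {r.patient: r.delta for r in results}
    records = [rec for r in results for rec in r.records.values()]
    groups = {r.patient: r.group for r in results}
    ds = build_slice_dataset(deltas, records, groups)
    reports = summarize_reports(ds, cutoffs=config.cutoffs, cut=config.subgroup_cut_mm)
    return CohortAnalysis(cases=results, dataset=ds, reports=reports, failures=failures)


def pooled_threshold_mean(
    ds: SliceDataset, cutoff_pct: float = 50.0, peak_window: float = 0.05
) -> float:
    """Mean primary Youden threshold over the six segment x region analyses
    at one ΔArea cutoff — the headline displacement-threshold summary."""
    from .metrics import REGION_NAMES

    vals = []
    for segment in ("maxilla", "mandible"):
        for region in REGION_NAMES:
            roc = roc_threshold(ds, segment, region, cutoff_pct, peak_window=peak_window)
            vals.append(roc.primary_threshold)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# On-disk cohort layout


def save_cohort(cohort: Cohort, outdir: str) -> str:
    """Write meshes (STL), landmarks (JSON) and the manifest CSV; returns
    the manifest path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for case in cohort.cases:
        cdir = os.path.join(outdir, case.patient)
        os.makedirs(cdir, exist_ok=True)
        paths = {}
        for stage, scan in (("pre", case.pre), ("post", case.post)):
            mesh_path = os.path.join(cdir, f"{stage}_airway.stl")
            save_mesh(scan.airway_mesh, mesh_path)
            paths[f"{stage}_airway"] = mesh_path
            for bundle in ("cranial_base", "maxilla", "mandible", "airway_landmarks"):
                p = os.path.join(cdir, f"{stage}_{bundle}.json")
                getattr(scan, bundle).to_json(p)
                paths[f"{stage}_{bundle}"] = p
        rows.append(
            {
                "patient": case.patient,
                "group": case.group,
                "true_maxilla_ap_mm": case.maxilla_ap,
                "true_mandible_ap_mm": case.mandible_ap,
                **paths,
            }
        )
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cohort.ground_truth().to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
    return manifest


def _load_scan(row: pd.Series, stage: str) -> CaseScan:
    return CaseScan(
        cranial_base=LandmarkSet.from_json(row[f"{stage}_cranial_base"]),
        maxilla=LandmarkSet.from_json(row[f"{stage}_maxilla"]),
        mandible=LandmarkSet.from_json(row[f"{stage}_mandible"]),
        airway_landmarks=LandmarkSet.from_json(row[f"{stage}_airway_landmarks"]),
        airway_mesh=load_mesh(row[f"{stage}_airway"]),
    )


def load_cohort_manifest(manifest: str):
    """Yield (pre, post, patient, group) tuples from a manifest CSV.

    A case whose files are missing or unreadable is reported via an
    exception from :func:`analyze_case`'s caller; loading is lazy so one
    corrupt case does not block the rest."""
    df = pd.read_csv(manifest)
    for _, row in df.iterrows():
        yield _load_scan(row, "pre"), _load_scan(row, "post"), row.patient, row.group


def load_cohort_cases(manifest: str, continue_on_error: bool = True):
    """Eagerly load the manifest, skipping unreadable cases with a log entry."""
    df = pd.read_csv(manifest)
    out, failures = [], []
    for _, row in df.iterrows():
        try:
            out.append(
                (_load_scan(row, "pre"), _load_scan(row, "post"), row.patient, row.group)
            )
        except Exception as exc:
            log.warning("could not load case %s: %s", row.patient, exc)
            failures.append({"patient": row.patient, "error": str(exc)})
            if not continue_on_error:
                raise
    return out, failures
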