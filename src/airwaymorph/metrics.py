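"""Cross-sectional airway morphometry on 25 cranio-caudal slabs.

The cropped pharynx model is divided, along its own cranio-caudal (z)
extent, into 25 equal-height slabs ordered superior to inferior and mapped
onto the three anatomical subregions — nasopharynx (slabs 1-5), oropharynx
(6-14), hypopharynx (15-25).  Dividing each model's *own* extent into equal
fractions is what normalises the vertical measure, so slab *i* of the pre-
and post-operative models always spans the same fractional interval and
their areas are comparable even when airway height changes after surgery.

Per slab the analysis computes the *projected* cross-sectional area: the
orthographic silhouette along z of the mesh portion inside the slab,
measured on a raster (default pixel 0.1 mm, pixel-centre rule) over the
slab's axis-aligned box.  Volume is the signed divergence-theorem volume of
the watertight model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .errors import DegenerateGeometryError, NonWatertightError
from .mesh import fill_planar_boundaries, make_mesh, mesh_volume

__all__ = [
    "N_SLABS",
    "REGION_COUNTS",
    "REGION_NAMES",
    "Slab",
    "BoundingBoxPartition",
    "SliceAreaTable",
    "DeltaTable",
    "crop_airway",
    "partition_airway",
    "projected_area",
    "slice_area_table",
    "case_metrics",
]

N_SLABS = 25
REGION_NAMES = ("nasopharynx", "oropharynx", "hypopharynx")
REGION_COUNTS = {"nasopharynx": 5, "oropharynx": 9, "hypopharynx": 11}
#: region of each slab, superior (slab 1) to inferior (slab 25)
SLAB_REGIONS = (
    ("nasopharynx",) * 5 + ("oropharynx",) * 9 + ("hypopharynx",) * 11
)
DEFAULT_PIXEL_MM = 0.1


# ---------------------------------------------------------------------------
# Cropping


def _slice_keep(mesh: trimesh.Trimesh, origin, normal) -> trimesh.Trimesh:
    """Clip by a plane, keeping the half-space the normal points into, and
    cap the cut so the result stays watertight."""
    cut = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=np.asarray(normal, dtype=float),
        plane_origin=np.asarray(origin, dtype=float), cap=False
    )
    if cut is None or len(cut.faces) == 0:
        raise DegenerateGeometryError("crop plane removed the entire mesh")
    return fill_planar_boundaries(make_mesh(cut.vertices, cut.faces))


def crop_airway(
    mesh: trimesh.Trimesh,
    superior_planes: Sequence = (),
    inferior_z: Optional[float] = None,
) -> trimesh.Trimesh:
    """Crop the airway between the superior plane pair and an inferior level.

    ``superior_planes`` is an iterable of ``(origin, normal)`` pairs — in the
    anatomical protocol, the two perpendicular planes tangent to the basion
    and to the sphenoid sinus, with normals pointing into the kept side.
    ``inferior_z`` removes everything below that z (the C5 level).  Cut
    faces are capped, so a watertight input yields a watertight output.
    """
    out = mesh
    for origin, normal in superior_planes:
        out = _slice_keep(out, origin, normal)
    if inferior_z is not None:
        out = _slice_keep(out, (0.0, 0.0, float(inferior_z)), (0.0, 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# Partition


@dataclass(frozen=True)
class Slab:
    """One of the 25 bounding boxes: z-band plus the minimal axis-aligned
    box of the mesh portion inside it."""

    index: int  # 1 (superior) .. 25 (inferior)
    region: str
    z_lo: float
    z_hi: float
    box_min: tuple
    box_max: tuple
    empty: bool = False


@dataclass(frozen=True)
class BoundingBoxPartition:
    slabs: tuple

    def __post_init__(self):
        if len(self.slabs) != N_SLABS:
            raise ValueError(f"expected {N_SLABS} slabs, got {len(self.slabs)}")
        counts = {r: 0 for r in REGION_NAMES}
        for s in self.slabs:
            counts[s.region] += 1
        if counts != REGION_COUNTS:
            raise ValueError(f"bad region counts {counts}")

    def __iter__(self):
        return iter(self.slabs)

    def __getitem__(self, i: int) -> Slab:
        return self.slabs[i]

    @property
    def region_counts(self) -> dict:
        counts = {r: 0 for r in REGION_NAMES}
        for s in self.slabs:
            counts[s.region] += 1
        return counts


def _clip_polygon_z(poly: np.ndarray, z_lo: float, z_hi: float) -> np.ndarray:
    """Sutherland–Hodgman clip of a 3D polygon to the closed band z in
    [z_lo, z_hi]; returns (k, 3) vertices (k may be 0)."""
    for keep_ge, level in ((True, z_lo), (False, z_hi)):
        if len(poly) == 0:
            break
        out = []
        n = len(poly)
        for i in range(n):
            a, b = poly[i], poly[(i + 1) % n]
            in_a = (a[2] >= level) if keep_ge else (a[2] <= level)
            in_b = (b[2] >= level) if keep_ge else (b[2] <= level)
            if in_a:
                out.append(a)
            if in_a != in_b:
                t = (level - a[2]) / (b[2] - a[2])
                out.append(a + t * (b - a))
        poly = np.asarray(out)
    return poly


def _slab_polygons(mesh: trimesh.Trimesh, z_lo: float, z_hi: float) -> list:
    """Triangles of the mesh clipped to the slab band, as 3D polygons."""
    tri = mesh.vertices[mesh.faces]
    tz = tri[:, :, 2]
    touching = (tz.max(axis=1) >= z_lo) & (tz.min(axis=1) <= z_hi)
    inside = (tz.min(axis=1) >= z_lo) & (tz.max(axis=1) <= z_hi)
    polys = list(tri[inside])
    for t in tri[touching & ~inside]:
        clipped = _clip_polygon_z(t, z_lo, z_hi)
        if len(clipped) >= 3:
            polys.append(clipped)
    return polys


def partition_airway(mesh: trimesh.Trimesh, eps: float = 1e-9) -> BoundingBoxPartition:
    """Divide the model's z-extent into 25 equal-height slabs (5/9/11 by
    region, superior to inferior) and record each slab's minimal box."""
    z = mesh.vertices[:, 2]
    z_min, z_max = float(z.min()), float(z.max())
    if z_max - z_min < N_SLABS * eps:
        raise DegenerateGeometryError(
            f"z-extent {z_max - z_min:.3g} mm too small to form {N_SLABS} slabs"
        )
    edges = np.linspace(z_min, z_max, N_SLABS + 1)
    slabs = []
    for i in range(N_SLABS):
        # slab 1 is the most superior band
        z_lo, z_hi = edges[N_SLABS - 1 - i], edges[N_SLABS - i]
        polys = _slab_polygons(mesh, z_lo, z_hi)
        if polys:
            pts = np.vstack(polys)
            box_min, box_max = pts.min(axis=0), pts.max(axis=0)
            empty = False
        else:
            box_min = box_max = np.array([np.nan] * 3)
            empty = True
        slabs.append(
            Slab(
                index=i + 1,
                region=SLAB_REGIONS[i],
                z_lo=z_lo,
                z_hi=z_hi,
                box_min=tuple(box_min),
                box_max=tuple(box_max),
                empty=empty,
            )
        )
    return BoundingBoxPartition(tuple(slabs))


# ---------------------------------------------------------------------------
# Projected area


def _band_triangles_2d(mesh: trimesh.Trimesh, z_lo: float, z_hi: float):
    """xy-projected triangles of the capped solid portion in the z band.

    The band is cut out of the watertight model and capped; projecting the
    boundary of that solid (walls + caps) covers the filled silhouette —
    projecting the wall surface alone would give a zero-area ring for
    vertical walls.  Degenerate projections (vertical slivers) are dropped.
    """
    try:
        band = _slice_keep(mesh, (0.0, 0.0, z_lo), (0.0, 0.0, 1.0))
        band = _slice_keep(band, (0.0, 0.0, z_hi), (0.0, 0.0, -1.0))
    except DegenerateGeometryError:
        return None
    tri2d = band.vertices[band.faces][:, :, :2]
    e1 = tri2d[:, 1] - tri2d[:, 0]
    e2 = tri2d[:, 2] - tri2d[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    tri2d = tri2d[np.abs(det) > 2e-12]
    return tri2d if len(tri2d) else None


def _raster_union(tri2d, x_lo, y_lo, nx, ny, pixel) -> np.ndarray:
    """Boolean raster (pixel-centre rule) of the union of 2D triangles."""
    mask = np.zeros((ny, nx), dtype=bool)
    xs0 = x_lo + pixel / 2
    ys0 = y_lo + pixel / 2
    eps = 1e-12
    for a, b, c in tri2d:
        ix0 = max(int(np.ceil((min(a[0], b[0], c[0]) - xs0) / pixel)), 0)
        ix1 = min(int(np.floor((max(a[0], b[0], c[0]) - xs0) / pixel)), nx - 1)
        iy0 = max(int(np.ceil((min(a[1], b[1], c[1]) - ys0) / pixel)), 0)
        iy1 = min(int(np.floor((max(a[1], b[1], c[1]) - ys0) / pixel)), ny - 1)
        if ix1 < ix0 or iy1 < iy0:
            continue
        px = xs0 + np.arange(ix0, ix1 + 1) * pixel - a[0]
        py = ys0 + np.arange(iy0, iy1 + 1) * pixel - a[1]
        e1 = b - a
        e2 = c - a
        det = e1[0] * e2[1] - e1[1] * e2[0]
        s = (px[None, :] * e2[1] - py[:, None] * e2[0]) / det
        t = (e1[0] * py[:, None] - e1[1] * px[None, :]) / det
        inside = (s >= -eps) & (t >= -eps) & (s + t <= 1 + eps)
        mask[iy0 : iy1 + 1, ix0 : ix1 + 1] |= inside
    return mask


def projected_area(
    mesh: trimesh.Trimesh,
    slab: Slab,
    pixel_mm: float = DEFAULT_PIXEL_MM,
    axis: str = "z",
) -> tuple:
    """Raster area (mm^2) of the slab's orthographic silhouette along z.

    Returns ``(area, empty_flag)``; an empty slab yields ``(0.0, True)``.
    The raster covers the slab's xy box; a pixel counts when its centre
    falls inside the silhouette.  Only the cranio-caudal axis is
    implemented — it is the standard airway cross-section direction.
    """
    if axis != "z":
        raise NotImplementedError("only the cranio-caudal (z) projection axis is supported")
    if pixel_mm <= 0:
        raise ValueError("pixel size must be positive")
    tri2d = _band_triangles_2d(mesh, slab.z_lo, slab.z_hi)
    if tri2d is None:
        return 0.0, True
    x_lo, y_lo = slab.box_min[0], slab.box_min[1]
    x_hi, y_hi = slab.box_max[0], slab.box_max[1]
    nx = int(np.floor((x_hi - x_lo) / pixel_mm))
    ny = int(np.floor((y_hi - y_lo) / pixel_mm))
    if nx <= 0 or ny <= 0:
        return 0.0, True
    mask = _raster_union(tri2d, x_lo, y_lo, nx, ny, pixel_mm)
    return float(mask.sum()) * pixel_mm**2, False


# ---------------------------------------------------------------------------
# Tables


@dataclass(frozen=True)
class SliceAreaTable:
    """Per-slab projected areas (mm^2) plus the model's total volume (mm^3)."""

    partition: BoundingBoxPartition
    areas: tuple  # mm^2, slab order
    empty_flags: tuple
    volume: float  # mm^3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slab": [s.index for s in self.partition],
                "region": [s.region for s in self.partition],
                "area_mm2": self.areas,
                "empty": self.empty_flags,
            }
        )


def slice_area_table(
    mesh: trimesh.Trimesh, pixel_mm: float = DEFAULT_PIXEL_MM
) -> SliceAreaTable:
    """Partition a cropped airway model and measure every slab."""
    part = partition_airway(mesh)
    areas, flags = [], []
    for slab in part:
        a, empty = projected_area(mesh, slab, pixel_mm)
        areas.append(a)
        flags.append(empty)
    return SliceAreaTable(
        partition=part,
        areas=tuple(areas),
        empty_flags=tuple(flags),
        volume=mesh_volume(mesh),
    )


@dataclass(frozen=True)
class DeltaTable:
    """Per-slab percentage area change and case-level volume change."""

    patient: str
    slab_index: tuple
    region: tuple
    area_pre: tuple
    area_post: tuple
    delta_area_pct: tuple  # nan where invalid
    valid: tuple
    volume_pre: float
    volume_post: float

    @property
    def delta_volume_pct(self) -> float:
        return 100.0 * (self.volume_post - self.volume_pre) / self.volume_pre

    @property
    def n_excluded(self) -> int:
        return int(sum(not v for v in self.valid))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient": self.patient,
                "slab": self.slab_index,
                "region": self.region,
                "area_pre_mm2": self.area_pre,
                "area_post_mm2": self.area_post,
                "delta_area_pct": self.delta_area_pct,
                "valid": self.valid,
            }
        )
        df["delta_volume_pct"] = self.delta_volume_pct
        return df


def case_metrics(
    pre_mesh: trimesh.Trimesh,
    post_mesh_aligned: trimesh.Trimesh,
    pixel_mm: float = DEFAULT_PIXEL_MM,
    patient: str = "",
) -> DeltaTable:
    """ΔArea% per slab and ΔVolume% for one registered case.

    Both models are partitioned independently into their own 25 slabs
    (vertical normalisation) and paired by slab index.  Slabs with zero
    pre-operative area are flagged invalid rather than dropped.
    """
    pre = slice_area_table(pre_mesh, pixel_mm)
    post = slice_area_table(post_mesh_aligned, pixel_mm)
    delta, valid = [], []
    for a_pre, a_post in zip(pre.areas, post.areas):
        if a_pre > 0:
            delta.append(100.0 * (a_post - a_pre) / a_pre)
            valid.append(True)
        else:
            delta.append(float("nan"))
            valid.append(False)
    return DeltaTable(
        patient=patient,
        slab_index=tuple(s.index for s in pre.partition),
        region=tuple(s.region for s in pre.partition),
        area_pre=pre.areas,
        area_post=post.areas,
        delta_area_pct=tuple(delta),
        valid=tuple(valid),
        volume_pre=pre.volume,
        volume_post=post.volume,
    )
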