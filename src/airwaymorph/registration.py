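"""Pre- to post-operative registration and signed bone-displacement extraction.

The workflow mirrors routine cranio-maxillofacial superimposition practice:

1. rigid least-squares (Kabsch) alignment of cranial-base landmarks, which
   surgery leaves untouched, to put both scans in a common frame;
2. per-segment landmark alignment (molar and canine cusps) optionally
   refined by iterative closest point (ICP) against the segment surfaces;
3. Euler decomposition of the resulting rigid motion into signed
   translations (mm) and rotations (deg) — the antero-posterior component
   ``ty`` is the predictor analysed downstream;
4. airway-model alignment on landmarks of the posterior pharyngeal wall
   (pharyngeal recesses, interarytenoid notch), ICP-refined, because the
   posterior wall is essentially unaffected by jaw repositioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .errors import ConvergenceError, DegenerateGeometryError, LandmarkError
from .landmarks import (
    AIRWAY_LABELS,
    CRANIAL_BASE_LABELS,
    MANDIBLE_LABELS,
    MAXILLA_LABELS,
    LandmarkSet,
)
from .mesh import SurfaceIndex, make_mesh, transform_mesh
from .transforms import RigidTransform, euler_decompose

__all__ = [
    "FitResult",
    "ICPParams",
    "ICPResult",
    "DisplacementRecord",
    "CaseScan",
    "rigid_fit_landmarks",
    "icp_refine",
    "compute_bone_displacement",
    "align_airway_models",
]

SEGMENT_LABELS = {"maxilla": MAXILLA_LABELS, "mandible": MANDIBLE_LABELS}


@dataclass(frozen=True)
class FitResult:
    transform: RigidTransform
    residuals: dict  # label -> residual (mm) after alignment
    rms: float


@dataclass(frozen=True)
class ICPParams:
    """Point-to-surface ICP settings (defaults sized for ~mm-scale anatomy).

    ``method`` selects the pose update: ``point_to_plane`` (linearised
    distance-to-tangent-plane, fast rotational convergence; default) or
    ``point_to_point`` (rigid Kabsch step on the correspondences).
    """

    max_iterations: int = 50
    tolerance: float = 1e-6  # mm change in RMS taken as convergence
    rejection_distance: float = 10.0  # mm; correspondences beyond are dropped
    sample_size: int = 5000
    seed: int = 0
    method: str = "point_to_plane"

    def __post_init__(self):
        if min(self.max_iterations, self.sample_size) <= 0:
            raise ValueError("max_iterations and sample_size must be positive")
        if not 0 < self.tolerance < self.rejection_distance:
            raise ValueError("need 0 < tolerance < rejection_distance")
        if self.method not in ("point_to_plane", "point_to_point"):
            raise ValueError(f"unknown ICP method {self.method!r}")


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    rms: float
    iterations: int
    n_correspondences: int
    converged: bool
    rms_history: tuple = ()


@dataclass
class CaseScan:
    """One timepoint of one patient: landmark bundles plus (optional) meshes."""

    cranial_base: LandmarkSet
    maxilla: LandmarkSet
    mandible: LandmarkSet
    airway_landmarks: Optional[LandmarkSet] = None
    airway_mesh: Optional[trimesh.Trimesh] = None
    segment_meshes: dict = field(default_factory=dict)

    def segment_landmarks(self, segment: str) -> LandmarkSet:
        if segment not in SEGMENT_LABELS:
            raise ValueError(f"segment must be 'maxilla' or 'mandible', got {segment!r}")
        return getattr(self, segment)


@dataclass(frozen=True)
class DisplacementRecord:
    """Signed six-DOF displacement of one bony segment (pre -> post)."""

    patient: str
    segment: str
    tx: float
    ty: float
    tz: float
    pitch: float
    roll: float
    yaw: float
    residual_rms: float = 0.0
    icp_iterations: int = 0

    def __post_init__(self):
        if self.segment not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.residual_rms < 0:
            raise ValueError("residual RMS must be non-negative")

    @property
    def ap(self) -> float:
        """Antero-posterior displacement (mm): alias of ``ty``."""
        return self.ty


# ---------------------------------------------------------------------------
# Landmark (Kabsch) fit


def _kabsch(moving: np.ndarray, fixed: np.ndarray):
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    a, b = moving - mc, fixed - fc
    s = np.linalg.svd(a, compute_uv=False)
    if len(moving) < 3 or s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "landmark configuration is collinear or has fewer than 3 points"
        )
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fc - rot @ mc
    return rot, trans


def rigid_fit_landmarks(moving: LandmarkSet, fixed: LandmarkSet) -> FitResult:
    """Least-squares rigid fit (no scaling, no reflection) of matched landmarks.

    Correspondence is by shared label.  Requires >= 3 non-collinear pairs.
    """
    labels = [lb for lb in moving.labels if lb in fixed]
    if len(labels) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 matched landmark pairs, found {len(labels)}"
        )
    mov, fix = moving.array(labels), fixed.array(labels)
    rot, trans = _kabsch(mov, fix)
    m = np.eye(4)
    m[:3, :3], m[:3, 3] = rot, trans
    transform = euler_decompose(m)
    moved = transform.apply(mov)
    res = np.linalg.norm(moved - fix, axis=1)
    return FitResult(
        transform=transform,
        residuals=dict(zip(labels, res.tolist())),
        rms=float(np.sqrt(np.mean(res**2))),
    )


# ---------------------------------------------------------------------------
# ICP


def _rodrigues(omega: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(omega))
    if angle < 1e-15:
        return np.eye(3)
    k = omega / angle
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def _icp_step(method: str, pts, closest, normals) -> np.ndarray:
    """One rigid pose update as a 4x4 matrix."""
    m = np.eye(4)
    if method == "point_to_point":
        try:
            rot, trans = _kabsch(pts, closest)
        except DegenerateGeometryError as exc:
            raise ConvergenceError(f"degenerate ICP correspondence set: {exc}")
        m[:3, :3], m[:3, 3] = rot, trans
        return m
    # point-to-plane: minimise sum ((R p + t - q) . n)^2 for small rotations
    a = np.hstack([np.cross(pts, normals), normals])
    b = np.einsum("ij,ij->i", normals, closest - pts)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    m[:3, :3] = _rodrigues(x[:3])
    m[:3, 3] = x[3:]
    return m


def icp_refine(
    moving: trimesh.Trimesh,
    fixed: trimesh.Trimesh,
    init: RigidTransform = RigidTransform(),
    params: ICPParams = ICPParams(),
) -> ICPResult:
    """Point-to-surface ICP refinement of an initial rigid alignment.

    Surface samples of ``moving`` are matched to their closest points on
    ``fixed``; pairs farther than the rejection distance are dropped; the
    pose is updated by a rigid Kabsch step.  RMS over accepted pairs is
    non-increasing across accepted iterations (an increasing step stops the
    loop instead of being applied).
    """
    samples, _ = trimesh.sample.sample_surface(
        moving, params.sample_size, seed=params.seed
    )
    index = SurfaceIndex(fixed)
    face_normals = np.asarray(fixed.face_normals)
    transform = init
    prev_transform = init
    history = []
    rms_prev = np.inf
    n_corr = 0
    converged = False
    for _ in range(params.max_iterations):
        pts = transform.apply(samples)
        closest, dist, tid = index.query(pts)
        keep = dist < params.rejection_distance
        n_corr = int(keep.sum())
        if n_corr < 3:
            raise ConvergenceError(
                f"ICP found only {n_corr} correspondences under the "
                f"{params.rejection_distance} mm rejection distance "
                f"(closest sample at {dist.min():.2f} mm)"
            )
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if rms > rms_prev + 1e-12:  # step increased error: revert and stop
            transform = prev_transform
            break
        history.append(rms)
        if rms_prev - rms < params.tolerance:
            converged = True
            rms_prev = rms
            break
        rms_prev = rms
        prev_transform = transform
        step = _icp_step(
            params.method, pts[keep], closest[keep], face_normals[tid[keep]]
        )
        transform = euler_decompose(step @ transform.matrix)
    return ICPResult(
        transform=transform,
        rms=float(history[-1]) if history else float(rms_prev),
        iterations=len(history),
        n_correspondences=n_corr,
        converged=converged,
        rms_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# Bone displacement


def compute_bone_displacement(
    pre: CaseScan,
    post: CaseScan,
    segment: str,
    patient: str = "",
    use_icp: bool = False,
    icp_params: ICPParams = ICPParams(),
) -> DisplacementRecord:
    """Signed six-DOF displacement of a bony segment between two scans.

    Steps: cranial-base fit of post onto pre; segment landmarks of the post
    scan re-expressed in the pre frame; rigid segment fit; optional ICP
    against segment meshes; Euler decomposition with translations reported
    as the motion of the landmark centroid (rotation taken about it).
    """
    labels = SEGMENT_LABELS.get(segment)
    if labels is None:
        raise ValueError(f"segment must be 'maxilla' or 'mandible', got {segment!r}")
    missing = [
        lb
        for lb in labels
        if lb not in pre.segment_landmarks(segment)
        or lb not in post.segment_landmarks(segment)
    ]
    if missing:
        raise LandmarkError(
            f"missing segment landmarks: {', '.join(missing)}", missing=missing
        )
    base = rigid_fit_landmarks(post.cranial_base, pre.cranial_base)
    post_seg = post.segment_landmarks(segment).transformed(base.transform)
    pre_seg = pre.segment_landmarks(segment)
    fit = rigid_fit_landmarks(pre_seg, post_seg)
    transform, rms, icp_iter = fit.transform, fit.rms, 0
    if use_icp and segment in pre.segment_meshes and segment in post.segment_meshes:
        post_mesh = transform_mesh(post.segment_meshes[segment], base.transform)
        res = icp_refine(pre.segment_meshes[segment], post_mesh, transform, icp_params)
        transform, rms, icp_iter = res.transform, res.rms, res.iterations
    # translation = centroid motion; rotation about the pre centroid
    pre_pts = pre_seg.array(labels)
    centroid_delta = transform.apply(pre_pts).mean(axis=0) - pre_pts.mean(axis=0)
    return DisplacementRecord(
        patient=patient,
        segment=segment,
        tx=float(centroid_delta[0]),
        ty=float(centroid_delta[1]),
        tz=float(centroid_delta[2]),
        pitch=transform.pitch,
        roll=transform.roll,
        yaw=transform.yaw,
        residual_rms=rms,
        icp_iterations=icp_iter,
    )


# ---------------------------------------------------------------------------
# Airway model alignment


def align_airway_models(
    pre_ua: trimesh.Trimesh,
    post_ua: trimesh.Trimesh,
    pre_lm: LandmarkSet,
    post_lm: LandmarkSet,
    params: ICPParams = ICPParams(),
    posterior_wall_faces: Optional[np.ndarray] = None,
):
    """Express the post-operative airway model in the pre-operative frame.

    Landmark seed: pharyngeal recesses + interarytenoid notch (posterior
    pharyngeal wall, unaltered by surgery), then ICP refinement.  When a
    boolean face mask ``posterior_wall_faces`` over ``post_ua`` is given,
    ICP samples only that region, so anterior-wall remodelling cannot drag
    the alignment.

    Returns ``(aligned_post_mesh, ICPResult)``.
    """
    missing = [lb for lb in AIRWAY_LABELS if lb not in pre_lm or lb not in post_lm]
    if missing:
        raise LandmarkError(
            f"missing airway landmarks: {', '.join(missing)}", missing=missing
        )
    seed_fit = rigid_fit_landmarks(post_lm.subset(AIRWAY_LABELS),
                                   pre_lm.subset(AIRWAY_LABELS))
    source = post_ua
    if posterior_wall_faces is not None:
        wall = np.asarray(posterior_wall_faces, dtype=bool)
        if wall.shape != (len(post_ua.faces),):
            raise ValueError("posterior_wall_faces must be a boolean face mask")
        source = make_mesh(post_ua.vertices, post_ua.faces[wall])
    res = icp_refine(source, pre_ua, seed_fit.transform, params)
    return transform_mesh(post_ua, res.transform), res
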