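"""Synthetic cohorts of paired pre/post-operative airway models.

Real inputs to this pipeline are CBCT-derived surface meshes, which cannot
be shipped; this module generates anatomically plausible stand-ins so every
stage is testable end to end with known ground truth:

* **airway** — a watertight elliptical tube along z, ~60-80 mm long, with a
  narrower oropharyngeal waist and a gentle anterior bow;
* **landmarks** — cranial-base (frontozygomatic sutures, zygomatic arches),
  maxillary and mandibular cusp points, and posterior-pharyngeal-wall
  airway landmarks, left/right symmetric up to picking jitter;
* **response model** — per-slab ΔArea% is pure noise while the effective
  antero-posterior displacement stays below a threshold θ, and grows
  linearly with slope β above it; each pharyngeal region mixes maxillary
  and mandibular displacement with its own weight (the maxilla drives the
  nasopharynx, the mandible the hypopharynx);
* **cohort** — MMA (bimaxillary advancement) and MAMS (maxillary
  advancement + mandibular setback) groups with displacement distributions
  calibrated to typical surgical practice (medians ≈ +3.8/+4.6 mm for
  MMA maxilla/mandible, +3.9/−2.5 mm for MAMS).

The post-operative airway is built by deforming the pre-operative rings
(shared topology), so the drawn ΔArea% values are true by construction,
then moved by a random scan pose that the registration stage must undo.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so cases are reproducible
individually and as a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .errors import DegenerateGeometryError
from .landmarks import (
    AIRWAY_LABELS,
    CRANIAL_BASE_LABELS,
    MANDIBLE_LABELS,
    MAXILLA_LABELS,
    LandmarkSet,
)
from .mesh import make_mesh
from .metrics import N_SLABS, SLAB_REGIONS
from .registration import CaseScan
from .transforms import RigidTransform

__all__ = [
    "AirwayProfile",
    "ResponseModel",
    "SyntheticCase",
    "Cohort",
    "generate_airway",
    "generate_skull_landmarks",
    "simulate_case",
    "generate_cohort",
    "posterior_wall_mask",
    "DISPLACEMENT_CALIBRATION",
]


# ---------------------------------------------------------------------------
# Airway tube


@dataclass(frozen=True)
class AirwayProfile:
    """Parametric pharynx: length (mm) and smooth elliptical semi-axes.

    Control points are fractions of the length measured from the inferior
    end; ``a`` is the lateral (x) semi-axis, ``b`` the antero-posterior (y)
    one.  The default waist around 60 % of the height models the narrower
    oropharynx.  ``bow`` bends the tube axis anteriorly at mid-height.
    """

    length: float = 70.0
    n_theta: int = 96
    n_z: int = 71
    control_fractions: tuple = (0.0, 0.25, 0.62, 0.85, 1.0)
    control_a: tuple = (11.0, 12.0, 8.5, 11.0, 13.0)
    control_b: tuple = (9.0, 10.0, 6.5, 9.0, 11.0)
    bow: float = 3.0

    def __post_init__(self):
        if min(self.control_a) <= 0 or min(self.control_b) <= 0:
            raise DegenerateGeometryError("semi-axes must be positive")
        if self.length <= 0:
            raise DegenerateGeometryError("length must be positive")

    def semi_axes(self, z: np.ndarray):
        f = np.asarray(z, dtype=float) / self.length
        a = PchipInterpolator(self.control_fractions, self.control_a)(f)
        b = PchipInterpolator(self.control_fractions, self.control_b)(f)
        return a, b

    def centre_y(self, z: np.ndarray) -> np.ndarray:
        f = np.asarray(z, dtype=float) / self.length
        return self.bow * np.sin(np.pi * np.clip(f, 0, 1))

    def jittered(self, rng: np.random.Generator, rel_sigma: float = 0.05) -> "AirwayProfile":
        """Per-case anatomy: multiplicative jitter on semi-axes and length."""
        ja = tuple(a * (1 + rng.normal(0, rel_sigma)) for a in self.control_a)
        jb = tuple(b * (1 + rng.normal(0, rel_sigma)) for b in self.control_b)
        jl = float(self.length * (1 + rng.normal(0, rel_sigma)))
        return replace(self, control_a=ja, control_b=jb, length=jl)


def _tube_mesh(profile: AirwayProfile, radial_scale: Optional[np.ndarray] = None):
    """Watertight capped tube; optional per-level radial scale factors."""
    zs = np.linspace(0.0, profile.length, profile.n_z)
    a, b = profile.semi_axes(zs)
    if radial_scale is not None:
        a = a * radial_scale
        b = b * radial_scale
    cy = profile.centre_y(zs)
    theta = np.linspace(0, 2 * np.pi, profile.n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    nt, nz = profile.n_theta, profile.n_z
    verts = np.empty((nz * nt, 3))
    for i, z in enumerate(zs):
        verts[i * nt : (i + 1) * nt, 0] = a[i] * cos_t
        verts[i * nt : (i + 1) * nt, 1] = cy[i] + b[i] * sin_t
        verts[i * nt : (i + 1) * nt, 2] = z
    faces = []
    for i in range(nz - 1):
        base, nxt = i * nt, (i + 1) * nt
        j = np.arange(nt)
        k = (j + 1) % nt
        quad_a = np.column_stack([base + j, base + k, nxt + k])
        quad_b = np.column_stack([base + j, nxt + k, nxt + j])
        faces.append(quad_a)
        faces.append(quad_b)
    # end caps: fans around the ring centres, wound outward
    lo_c = len(verts)
    hi_c = lo_c + 1
    verts = np.vstack([verts, [0.0, cy[0], zs[0]], [0.0, cy[-1], zs[-1]]])
    j = np.arange(nt)
    k = (j + 1) % nt
    faces.append(np.column_stack([np.full(nt, lo_c), k, j]))  # bottom, normal -z
    top = (nz - 1) * nt
    faces.append(np.column_stack([np.full(nt, hi_c), top + j, top + k]))  # top, +z
    return make_mesh(verts, np.vstack(faces))


def generate_airway(profile: AirwayProfile = AirwayProfile(), seed: int = 0) -> trimesh.Trimesh:
    """Seeded watertight pharynx-like tube (per-case anatomy jitter applied)."""
    rng = np.random.default_rng(seed)
    return _tube_mesh(profile.jittered(rng))


def posterior_wall_mask(mesh: trimesh.Trimesh, profile: AirwayProfile) -> np.ndarray:
    """Boolean face mask of the posterior pharyngeal wall (y below the tube
    axis), the region conventionally used to align airway models."""
    centroids = mesh.triangles_center
    return centroids[:, 1] < profile.centre_y(centroids[:, 2])


# ---------------------------------------------------------------------------
# Landmarks


def generate_skull_landmarks(
    profile: AirwayProfile = AirwayProfile(),
    seed: int = 0,
    jitter: float = 1.0,
):
    """Plausible cranial-base / maxillary / mandibular / airway landmarks.

    Returns a dict of :class:`LandmarkSet` keyed ``cranial_base``,
    ``maxilla``, ``mandible``, ``airway``.  With ``jitter=0`` bilateral
    pairs mirror exactly across the midsagittal (x = 0) plane.
    """
    rng = np.random.default_rng(seed)
    L = profile.length

    def sym(label_l, label_r, x, y, z):
        jl = rng.normal(0, jitter, 3)
        jr = rng.normal(0, jitter, 3)
        return {label_l: np.array([-x, y, z]) + jl, label_r: np.array([x, y, z]) + jr}

    base = {}
    base.update(sym("frontozygomatic-L", "frontozygomatic-R", 48.0, 30.0, L + 18.0))
    # the arch points sit well below and behind the frontozygomatic sutures
    base.update(sym("zygomatic-arch-L", "zygomatic-arch-R", 55.0, 5.0, L - 10.0))
    maxilla = {}
    maxilla.update(sym("mx-molar-cusp-L", "mx-molar-cusp-R", 24.0, 38.0, 0.78 * L))
    maxilla.update(sym("mx-canine-cusp-L", "mx-canine-cusp-R", 14.0, 48.0, 0.78 * L))
    mandible = {}
    mandible.update(sym("md-molar-cusp-L", "md-molar-cusp-R", 24.0, 36.0, 0.55 * L))
    mandible.update(sym("md-canine-cusp-L", "md-canine-cusp-R", 13.0, 45.0, 0.55 * L))
    a_top, b_top = profile.semi_axes(np.array([0.92 * L]))
    _, b_lo = profile.semi_axes(np.array([0.08 * L]))
    airway = {}
    airway.update(
        sym(
            "pharyngeal-recess-L",
            "pharyngeal-recess-R",
            0.75 * float(a_top[0]),
            profile.centre_y(0.92 * L) - 0.6 * float(b_top[0]),
            0.92 * L,
        )
    )
    airway["interarytenoid-notch"] = np.array(
        [0.0, profile.centre_y(0.08 * L) - float(b_lo[0]), 0.08 * L]
    ) + rng.normal(0, jitter, 3)
    return {
        "cranial_base": LandmarkSet(base),
        "maxilla": LandmarkSet(maxilla),
        "mandible": LandmarkSet(mandible),
        "airway": LandmarkSet(airway),
    }


# ---------------------------------------------------------------------------
# Response model


@dataclass(frozen=True)
class ResponseModel:
    """Neutral-interval / linear-above-threshold ΔArea% response.

    Below the displacement threshold ``theta`` (mm of effective AP motion)
    per-slab ΔArea% is pure noise; above it the expected response grows as
    ``slope`` %/mm.  ``maxilla_weight`` mixes maxillary vs mandibular AP
    into the effective displacement of each pharyngeal region.
    """

    theta: float = 5.5  # mm
    slope: float = 25.0  # ΔArea% per mm above theta
    noise_sd: float = 15.0  # ΔArea%
    maxilla_weight: dict = field(
        default_factory=lambda: {
            "nasopharynx": 0.8,
            "oropharynx": 0.5,
            "hypopharynx": 0.2,
        }
    )

    def __post_init__(self):
        if self.theta < 0 or self.slope < 0 or self.noise_sd < 0:
            raise ValueError("theta, slope and noise_sd must be non-negative")
        if any(not 0 <= w <= 1 for w in self.maxilla_weight.values()):
            raise ValueError("region weights must lie in [0, 1]")

    def effective_displacement(self, region: str, maxilla_ap: float, mandible_ap: float) -> float:
        w = self.maxilla_weight[region]
        return w * maxilla_ap + (1 - w) * mandible_ap

    def expected_delta(self, d_eff: float) -> float:
        return self.slope * max(0.0, d_eff - self.theta)

    def draw_slab_deltas(
        self, maxilla_ap: float, mandible_ap: float, rng: np.random.Generator
    ) -> np.ndarray:
        """One ΔArea% per slab (superior to inferior), truncated at -95 %."""
        means = np.array(
            [
                self.expected_delta(
                    self.effective_displacement(region, maxilla_ap, mandible_ap)
                )
                for region in SLAB_REGIONS
            ]
        )
        deltas = means + rng.normal(0.0, self.noise_sd, N_SLABS)
        if (deltas <= -100).any():
            warnings.warn("ΔArea% draw at or below -100 truncated to -95")
            deltas = np.maximum(deltas, -95.0)
        return deltas


# ---------------------------------------------------------------------------
# Case simulation


@dataclass
class SyntheticCase:
    patient: str
    group: str  # MMA | MAMS
    maxilla_ap: float
    mandible_ap: float
    pre: CaseScan
    post: CaseScan
    true_maxilla: RigidTransform
    true_mandible: RigidTransform
    scan_pose: RigidTransform
    true_delta_area: tuple  # per slab, superior to inferior
    profile: AirwayProfile


def _segment_transform(ap: float, landmarks: LandmarkSet, rng, max_rot_deg: float) -> RigidTransform:
    """Pure AP translation plus an optional small rotation about the
    landmark centroid (so the true AP stays exactly ``ap``)."""
    if max_rot_deg > 0:
        angles = rng.uniform(-max_rot_deg, max_rot_deg, 3)
    else:
        angles = np.zeros(3)
    rot = RigidTransform(*angles, 0.0, 0.0, 0.0)
    centroid = landmarks.array().mean(axis=0)
    shift = centroid - rot.apply(centroid) + np.array([0.0, ap, 0.0])
    return RigidTransform(
        *angles, float(shift[0]), float(shift[1]), float(shift[2]),
    )


def simulate_case(
    maxilla_ap: float,
    mandible_ap: float,
    response: ResponseModel = ResponseModel(),
    noise: float = 0.3,
    seed: int = 0,
    patient: str = "case",
    group: str = "MMA",
    profile: AirwayProfile = AirwayProfile(),
    max_rot_deg: float = 0.5,
    scan_misalignment: float = 2.0,
) -> SyntheticCase:
    """One paired pre/post case with full ground truth.

    ``noise`` is the landmark picking SD (mm); ``scan_misalignment`` sizes
    the random rigid pose separating the two scans (mm and degrees), which
    the cranial-base registration must recover.
    """
    if not -10.0 <= maxilla_ap <= 16.0 or not -10.0 <= mandible_ap <= 16.0:
        raise ValueError("AP displacements outside the plausible surgical range")
    ss = np.random.SeedSequence(seed)
    r_anat, r_resp, r_pick, r_pose = [np.random.default_rng(s) for s in ss.spawn(4)]

    case_profile = profile.jittered(r_anat)
    lm = generate_skull_landmarks(case_profile, seed=r_anat.integers(2**31), jitter=1.0)
    pre_mesh = _tube_mesh(case_profile)

    true_mx = _segment_transform(maxilla_ap, lm["maxilla"], r_resp, max_rot_deg)
    true_md = _segment_transform(mandible_ap, lm["mandible"], r_resp, max_rot_deg)

    deltas = response.draw_slab_deltas(maxilla_ap, mandible_ap, r_resp)
    # slab i (superior) covers fractions [1-i/25, 1-(i-1)/25] of the height;
    # radial scale interpolated through slab-centre heights
    zs = np.linspace(0.0, case_profile.length, case_profile.n_z)
    centre_frac = 1.0 - (np.arange(N_SLABS) + 0.5) / N_SLABS  # superior slab first
    scale_at_centre = np.sqrt(1.0 + deltas / 100.0)
    order = np.argsort(centre_frac)
    interp = PchipInterpolator(
        centre_frac[order] * case_profile.length, scale_at_centre[order]
    )
    z_clip = np.clip(
        zs, centre_frac.min() * case_profile.length, centre_frac.max() * case_profile.length
    )
    post_mesh_anat = _tube_mesh(case_profile, radial_scale=interp(z_clip))

    scan_pose = (
        RigidTransform(
            *r_pose.uniform(-scan_misalignment, scan_misalignment, 3),
            *r_pose.uniform(-scan_misalignment, scan_misalignment, 3),
        )
        if scan_misalignment > 0
        else RigidTransform()
    )

    def picked(ls: LandmarkSet, transform=None) -> LandmarkSet:
        out = ls if transform is None else ls.transformed(transform)
        out = out.transformed(scan_pose)
        return out.jittered(r_pick, noise) if noise > 0 else out

    pre = CaseScan(
        cranial_base=lm["cranial_base"] if noise == 0 else lm["cranial_base"].jittered(r_pick, noise),
        maxilla=lm["maxilla"] if noise == 0 else lm["maxilla"].jittered(r_pick, noise),
        mandible=lm["mandible"] if noise == 0 else lm["mandible"].jittered(r_pick, noise),
        airway_landmarks=lm["airway"] if noise == 0 else lm["airway"].jittered(r_pick, noise),
        airway_mesh=pre_mesh,
    )
    post = CaseScan(
        cranial_base=picked(lm["cranial_base"]),
        maxilla=picked(lm["maxilla"], true_mx),
        mandible=picked(lm["mandible"], true_md),
        airway_landmarks=picked(lm["airway"]),
        airway_mesh=make_mesh(scan_pose.apply(post_mesh_anat.vertices), post_mesh_anat.faces),
    )
    return SyntheticCase(
        patient=patient,
        group=group,
        maxilla_ap=maxilla_ap,
        mandible_ap=mandible_ap,
        pre=pre,
        post=post,
        true_maxilla=true_mx,
        true_mandible=true_md,
        scan_pose=scan_pose,
        true_delta_area=tuple(deltas),
        profile=case_profile,
    )


# ---------------------------------------------------------------------------
# Cohort


#: truncated-normal calibration of AP displacement (mm) per group/segment:
#: (median, IQR, min, max) — matches the descriptive statistics of the two
#: surgical procedures (MMA advances both jaws; MAMS sets the mandible back)
DISPLACEMENT_CALIBRATION = {
    ("MMA", "maxilla"): (3.8, 3.5, 0.0, 15.1),
    ("MMA", "mandible"): (4.6, 4.55, 0.5, 13.7),
    ("MAMS", "maxilla"): (3.9, 2.4, 0.9, 7.2),
    ("MAMS", "mandible"): (-2.5, 3.0, -5.8, 0.0),
}


def draw_displacement(group: str, segment: str, rng: np.random.Generator) -> float:
    median, iqr, lo, hi = DISPLACEMENT_CALIBRATION[(group, segment)]
    scale = iqr / 1.349  # normal IQR -> SD
    a, b = (lo - median) / scale, (hi - median) / scale
    return float(truncnorm.rvs(a, b, loc=median, scale=scale, random_state=rng))


@dataclass
class Cohort:
    cases: list
    response: ResponseModel
    seed: int

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient": [c.patient for c in self.cases],
                "group": [c.group for c in self.cases],
                "true_maxilla_ap_mm": [c.maxilla_ap for c in self.cases],
                "true_mandible_ap_mm": [c.mandible_ap for c in self.cases],
            }
        )

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            for i, (region, d) in enumerate(zip(SLAB_REGIONS, c.true_delta_area)):
                rows.append(
                    {
                        "patient": c.patient,
                        "group": c.group,
                        "slab": i + 1,
                        "region": region,
                        "true_delta_area_pct": d,
                    }
                )
        return pd.DataFrame(rows)


def generate_cohort(
    n_mma: int = 29,
    n_mams: int = 16,
    response: ResponseModel = ResponseModel(),
    seed: int = 0,
    noise: float = 0.3,
    profile: AirwayProfile = AirwayProfile(),
) -> Cohort:
    """Simulate a surgical cohort (default 29 MMA + 16 MAMS = 45 patients)."""
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    case_seeds = ss.generate_state(n_mma + n_mams) % (2**31)
    cases = []
    idx = 0
    for group, n in (("MMA", n_mma), ("MAMS", n_mams)):
        for _ in range(n):
            mx = draw_displacement(group, "maxilla", draw_rng)
            md = draw_displacement(group, "mandible", draw_rng)
            cases.append(
                simulate_case(
                    mx,
                    md,
                    response=response,
                    noise=noise,
                    seed=int(case_seeds[idx]),
                    patient=f"P{idx + 1:03d}",
                    group=group,
                    profile=profile,
                )
            )
            idx += 1
    return Cohort(cases=cases, response=response, seed=seed)
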