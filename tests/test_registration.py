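import numpy as np
import pytest

from airwaymorph.errors import ConvergenceError, DegenerateGeometryError, LandmarkError
from airwaymorph.landmarks import LandmarkSet
from airwaymorph.mesh import make_mesh
from airwaymorph.registration import (
    ICPParams,
    align_airway_models,
    compute_bone_displacement,
    icp_refine,
    rigid_fit_landmarks,
)
from airwaymorph.synth import ResponseModel, simulate_case, posterior_wall_mask
from airwaymorph.transforms import RigidTransform, random_pose

QUIET = ResponseModel(noise_sd=0.0)


def _square_landmarks(offset=(0.0, 0.0, 0.0)):
    pts = np.array(
        [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 5]], dtype=float
    ) + np.asarray(offset)
    return LandmarkSet({f"p{i}": p for i, p in enumerate(pts)})


class TestLandmarkFit:
    def test_identity(self):
        lm = _square_landmarks()
        fit = rigid_fit_landmarks(lm, lm)
        assert np.abs(fit.transform.matrix - np.eye(4)).max() < 1e-12
        assert fit.rms < 1e-12

    def test_pure_translation(self):
        fit = rigid_fit_landmarks(_square_landmarks(), _square_landmarks((1, 2, 3)))
        t = fit.transform
        assert (t.tx, t.ty, t.tz) == pytest.approx((1, 2, 3), abs=1e-12)
        assert (t.pitch, t.roll, t.yaw) == pytest.approx((0, 0, 0), abs=1e-10)

    def test_monte_carlo_noise(self):
        # 4 landmarks under a known pose + sigma=0.3 mm picking noise
        rng = np.random.default_rng(5)
        errors = []
        for _ in range(200):
            lm = _square_landmarks()
            pose = random_pose(rng, 20.0, 5.0)
            noisy = LandmarkSet(
                {k: pose.apply(v) + rng.normal(0, 0.3, 3) for k, v in lm.points.items()}
            )
            fit = rigid_fit_landmarks(lm, noisy)
            t = fit.transform
            errors.append(
                np.linalg.norm(
                    [t.tx - pose.tx, t.ty - pose.ty, t.tz - pose.tz]
                )
            )
        assert np.median(errors) < 0.5

    def test_rotation_equivariance(self):
        # pre-rotating both point sets by Q conjugates the recovered rotation
        rng = np.random.default_rng(9)
        lm = _square_landmarks()
        pose = random_pose(rng, 25.0, 4.0)
        moved = lm.transformed(pose)
        q = random_pose(rng, 60.0, 0.0)
        fit = rigid_fit_landmarks(lm.transformed(q), moved.transformed(q))
        expected = q.matrix[:3, :3] @ pose.matrix[:3, :3] @ q.matrix[:3, :3].T
        assert np.abs(fit.transform.matrix[:3, :3] - expected).max() < 1e-9

    def test_too_few_pairs(self):
        lm = LandmarkSet({"a": [0, 0, 0], "b": [1, 0, 0]})
        with pytest.raises(DegenerateGeometryError):
            rigid_fit_landmarks(lm, lm)

    def test_collinear_rejected(self):
        lm = LandmarkSet({f"p{i}": [i, 0.0, 0.0] for i in range(4)})
        with pytest.raises(DegenerateGeometryError):
            rigid_fit_landmarks(lm, lm)

    def test_label_matching_not_order(self):
        lm = _square_landmarks()
        shuffled = LandmarkSet(
            {k: lm.points[k] + np.array([1.0, 0, 0]) for k in reversed(lm.labels)}
        )
        fit = rigid_fit_landmarks(lm, shuffled)
        assert fit.transform.tx == pytest.approx(1.0, abs=1e-12)


class TestICP:
    def test_prealigned_meshes_stay_put(self, fine_tube):
        res = icp_refine(fine_tube, fine_tube, RigidTransform(), ICPParams(sample_size=500))
        assert res.rms < 1e-9
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-6

    def test_recovers_small_displacement(self, fine_tube):
        true = RigidTransform(pitch=2.0, yaw=-1.0, tx=0.4, ty=1.0, tz=-0.6)
        moved = make_mesh(true.inverse().apply(fine_tube.vertices), fine_tube.faces)
        res = icp_refine(moved, fine_tube, RigidTransform(), ICPParams(sample_size=1500))
        t = res.transform
        assert np.allclose(
            [t.tx, t.ty, t.tz], [true.tx, true.ty, true.tz], atol=0.1
        )
        assert np.allclose(
            [t.pitch, t.roll, t.yaw], [true.pitch, true.roll, true.yaw], atol=0.1
        )

    def test_rms_monotone_over_random_perturbations(self, fine_tube):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pert = random_pose(rng, 2.0, 1.5)
            moved = make_mesh(pert.apply(fine_tube.vertices), fine_tube.faces)
            res = icp_refine(
                moved, fine_tube, RigidTransform(), ICPParams(sample_size=300, seed=1)
            )
            hist = np.asarray(res.rms_history)
            assert (np.diff(hist) <= 1e-12).all()

    def test_no_correspondences_raises(self, fine_tube):
        far = make_mesh(np.asarray(fine_tube.vertices) + [500.0, 0, 0], fine_tube.faces)
        with pytest.raises(ConvergenceError):
            icp_refine(far, fine_tube, RigidTransform(), ICPParams(sample_size=100))


class TestBoneDisplacement:
    def test_no_surgery_is_zero(self):
        case = simulate_case(0.0, 0.0, response=QUIET, noise=0.0, seed=2, max_rot_deg=0.0)
        for segment in ("maxilla", "mandible"):
            rec = compute_bone_displacement(case.pre, case.post, segment)
            assert abs(rec.ap) < 1e-9
            assert np.allclose(
                [rec.tx, rec.ty, rec.tz, rec.pitch, rec.roll, rec.yaw], 0, atol=1e-9
            )

    def test_noise_free_advancement_exact(self):
        case = simulate_case(5.0, 0.0, response=QUIET, noise=0.0, seed=4)
        rec = compute_bone_displacement(case.pre, case.post, "maxilla")
        assert rec.ap == pytest.approx(5.0, abs=0.05)

    def test_setback_with_noise_monte_carlo(self):
        errors = []
        for s in range(100):
            case = simulate_case(0.0, -3.0, response=QUIET, noise=0.3, seed=1000 + s)
            rec = compute_bone_displacement(case.pre, case.post, "mandible")
            errors.append(abs(rec.ap - (-3.0)))
        assert np.median(errors) < 0.5

    def test_missing_landmarks_listed(self):
        case = simulate_case(2.0, 1.0, response=QUIET, noise=0.0, seed=6)
        broken = dict(case.post.maxilla.points)
        broken.pop("mx-molar-cusp-L")
        broken.pop("mx-molar-cusp-R")
        case.post.maxilla = LandmarkSet(broken)
        with pytest.raises(LandmarkError) as err:
            compute_bone_displacement(case.pre, case.post, "maxilla")
        assert "mx-molar-cusp-L" in str(err.value)

    def test_unknown_segment(self):
        case = simulate_case(1.0, 1.0, response=QUIET, noise=0.0, seed=8)
        with pytest.raises(ValueError):
            compute_bone_displacement(case.pre, case.post, "zygoma")


class TestAirwayAlignment:
    def test_identity_when_post_equals_pre(self):
        case = simulate_case(0.0, 0.0, response=QUIET, noise=0.0, seed=3,
                             max_rot_deg=0.0, scan_misalignment=0.0)
        aligned, res = align_airway_models(
            case.pre.airway_mesh, case.post.airway_mesh,
            case.pre.airway_landmarks, case.post.airway_landmarks,
            params=ICPParams(sample_size=500),
        )
        assert np.abs(np.asarray(aligned.vertices) - case.pre.airway_mesh.vertices).max() < 1e-6

    def test_recovers_rigid_scan_pose(self):
        case = simulate_case(0.0, 0.0, response=QUIET, noise=0.0, seed=5, max_rot_deg=0.0)
        aligned, _ = align_airway_models(
            case.pre.airway_mesh, case.post.airway_mesh,
            case.pre.airway_landmarks, case.post.airway_landmarks,
            params=ICPParams(sample_size=1000),
        )
        err = np.abs(np.asarray(aligned.vertices) - case.pre.airway_mesh.vertices).max()
        assert err < 0.1

    def test_posterior_wall_restriction_survives_anterior_deformation(self):
        # anterior wall bulges outward, posterior wall untouched
        case = simulate_case(0.0, 0.0, response=QUIET, noise=0.0, seed=7, max_rot_deg=0.0)
        pre = case.pre.airway_mesh
        v = np.asarray(case.post.airway_mesh.vertices).copy()
        anat = case.scan_pose.inverse().apply(v)
        anterior = anat[:, 1] > case.profile.centre_y(anat[:, 2])
        anat[anterior, 1] += 3.0  # 3 mm anterior bulge
        post = make_mesh(case.scan_pose.apply(anat), case.post.airway_mesh.faces)
        mask = posterior_wall_mask(post, case.profile)
        aligned, res = align_airway_models(
            pre, post,
            case.pre.airway_landmarks, case.post.airway_landmarks,
            params=ICPParams(sample_size=1500),
            posterior_wall_faces=mask,
        )
        from airwaymorph.mesh import SurfaceIndex

        averts = np.asarray(aligned.vertices)
        anat_aligned = averts  # aligned is in the pre frame
        posterior_pts = anat_aligned[~anterior]
        _, d_post, _ = SurfaceIndex(pre).query(posterior_pts)
        rms_posterior = float(np.sqrt(np.mean(d_post**2)))
        _, d_all, _ = SurfaceIndex(pre).query(averts)
        rms_global = float(np.sqrt(np.mean(d_all**2)))
        assert rms_posterior < 0.2
        assert rms_global > rms_posterior

    def test_missing_airway_landmark(self):
        case = simulate_case(0.0, 0.0, response=QUIET, noise=0.0, seed=9)
        bad = LandmarkSet({"pharyngeal-recess-L": [0, 0, 0], "pharyngeal-recess-R": [1, 0, 0]})
        with pytest.raises(LandmarkError):
            align_airway_models(
                case.pre.airway_mesh, case.post.airway_mesh,
                case.pre.airway_landmarks, bad,
            )
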