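"""Generator <-> measurement round trips and anatomical invariants."""

import math

import numpy as np
import pytest

import hipimpinge as hi
from hipimpinge.anatomy import (
    ALPHA_TOL,
    AnatomyParams,
    CohortSpec,
    GenerationError,
    measure_all,
    sample_cohort,
)

RES = 2.0  # generation pitch for the bulk round-trip tests (speed)


class TestGenerateHip:
    def test_mean_anatomy_round_trip(self, mean_hip):
        """Requested cohort-mean parameters are recovered from the mesh
        within 2 degrees each."""
        p = mean_hip.params
        meas = measure_all(mean_hip)
        for key in ("alpha_angle", "lcea", "acetabular_version", "femoral_version"):
            assert abs(meas[key] - getattr(p, key)) < 2.0, key

    @pytest.mark.parametrize("seed", range(8))
    def test_random_feasible_round_trip(self, seed):
        """Random draws across the clinical range round-trip within 2 deg."""
        rng = np.random.default_rng(seed)
        p = AnatomyParams(
            alpha_angle=rng.uniform(38, 90),
            lcea=rng.uniform(18, 45),
            acetabular_version=rng.uniform(5, 32),
            femoral_version=rng.uniform(-10, 40),
            aiis_type=["I", "II", "III"][seed % 3],
        )
        m = hi.generate_hip(p, resolution=RES)
        meas = measure_all(m)
        for key in ("alpha_angle", "lcea", "acetabular_version", "femoral_version"):
            assert abs(meas[key] - getattr(p, key)) < 2.0, (key, meas[key])

    def test_watertight_and_landmarks(self, mean_hip):
        assert mean_hip.pelvis.mesh.is_watertight
        assert mean_hip.femur.mesh.is_watertight
        assert len(mean_hip.pelvis.rim_samples) >= 12

    def test_no_cam_head_stays_spherical(self, no_cam_hip):
        """Below the cam threshold the head deviates < 0.5 mm from its
        best-fit sphere over the whole spherical arc."""
        femur = no_cam_hip.femur
        head = femur.landmarks["head_center"]
        r = no_cam_hip.params.head_radius
        d = np.linalg.norm(femur.vertices - head, axis=1)
        rel = femur.vertices - head
        axis = femur.landmarks["neck_base"] - head
        axis = axis / np.linalg.norm(axis)
        polar = np.degrees(np.arccos(np.clip(rel @ axis / np.maximum(d, 1e-9), -1, 1)))
        arc = (polar > no_cam_hip.params.alpha_angle + 3) & (d < 1.3 * r)
        assert np.abs(d[arc] - r).max() < 0.5

    def test_mirror_symmetry(self):
        """Left generation equals the reflected right generation exactly."""
        pr = AnatomyParams(side="right")
        pl = AnatomyParams(side="left")
        mr = hi.generate_hip(pr, resolution=RES)
        ml = hi.generate_hip(pl, resolution=RES)
        for bone in ("pelvis", "femur"):
            vr = getattr(mr, bone).vertices.copy()
            vr[:, 1] *= -1.0
            vl = getattr(ml, bone).vertices
            assert np.abs(np.sort(vr, axis=0) - np.sort(vl, axis=0)).max() < 1e-6

    def test_monotone_cam_volume(self):
        """Increasing alpha strictly increases femoral material outside
        the head sphere (cam volume)."""
        vols = []
        for alpha in (50.0, 60.0, 70.0, 80.0):
            m = hi.generate_hip(AnatomyParams(alpha_angle=alpha), resolution=RES)
            head = m.femur.landmarks["head_center"]
            r = m.params.head_radius
            v = m.femur.vertices
            d = np.linalg.norm(v - head, axis=1)
            near = d < 1.6 * r
            # proxy for cam volume: integrated radial excess of vertices
            # beyond the tolerance sphere in the junction zone
            excess = np.clip(d[near] - ALPHA_TOL * r, 0.0, None)
            vols.append(excess.sum())
        assert all(b > a for a, b in zip(vols, vols[1:])), vols

    def test_infeasible_parameters_raise(self):
        with pytest.raises(GenerationError, match="lcea"):
            hi.generate_hip(AnatomyParams(lcea=60.0, acetabular_version=-5.0),
                            resolution=RES)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AnatomyParams(alpha_angle=120.0)
        with pytest.raises(ValueError):
            AnatomyParams(head_radius=-1.0)
        with pytest.raises(ValueError):
            AnatomyParams(aiis_type="IV")


class TestAlphaMeasurement:
    def test_sphere_cylinder_closed_form(self):
        """For a spherical head with a plain cylindrical neck the alpha
        angle has the closed form asin(r_neck / (1.02 r_head))."""
        for alpha_req in (35.0, 40.0, 44.0):
            p = AnatomyParams(alpha_angle=alpha_req)
            m = hi.generate_hip(p, resolution=1.5)
            r_neck = ALPHA_TOL * p.head_radius * math.sin(math.radians(alpha_req))
            expected = math.degrees(math.asin(r_neck / (ALPHA_TOL * p.head_radius)))
            assert abs(hi.measure_alpha_angle(m) - expected) < 1.5

    @pytest.mark.parametrize("alpha", [55.0, 80.0])
    def test_generator_round_trip(self, alpha):
        m = hi.generate_hip(AnatomyParams(alpha_angle=alpha), resolution=RES)
        assert abs(hi.measure_alpha_angle(m) - alpha) < 2.0


class TestAIISTypes:
    def test_prominence_extent_orders_with_type(self):
        """Hetsroni types order the AIIS apex height relative to the rim
        plane: I above, II at, III below."""
        heights = {}
        for t in ("I", "II", "III"):
            m = hi.generate_hip(AnatomyParams(aiis_type=t), resolution=RES)
            pole = m.extras["pole"]
            rim = m.pelvis.rim_samples
            rim_level = float(np.mean(rim @ pole))
            apex = m.pelvis.landmarks["AIIS_apex"]
            heights[t] = float(apex @ pole) - rim_level
        assert heights["I"] > heights["II"] > heights["III"]
        assert heights["I"] > 2.0
        assert abs(heights["II"]) < 3.0
        assert heights["III"] < -2.0


class TestCohortSampling:
    def test_degenerate_spec_returns_means(self):
        spec = CohortSpec(
            n_patients=1,
            distributions={k: (mu, 0.0) for k, (mu, _) in
                           CohortSpec().distributions.items()},
            aiis_type_probs={"I": 0.0, "II": 1.0, "III": 0.0},
            resolution=RES,
            seed=1,
        )
        [(model, rec)] = sample_cohort(spec)
        assert rec["requested_femoral_version"] == pytest.approx(14.19)
        assert rec["aiis_type"] == "II"
        assert abs(rec["femoral_version"] - 14.19) < 2.0

    def test_sampling_deterministic_and_calibrated(self):
        """Same seed -> identical covariates; sample moments track the
        requested distribution within 3 standard errors."""
        spec = CohortSpec(n_patients=12, resolution=3.0, seed=7)
        recs1 = [r for _, r in sample_cohort(spec)]
        recs2 = [r for _, r in sample_cohort(spec)]
        assert recs1 == recs2
        fv = np.array([r["requested_femoral_version"] for r in recs1])
        mu, sd = spec.distributions["femoral_version"]
        assert abs(fv.mean() - mu) < 3 * sd / math.sqrt(len(fv))

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CohortSpec(aiis_type_probs={"I": 0.5, "II": 0.2})
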