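import numpy as np
import pytest

from jetflow.io import VelocityField4D
from jetflow.phantom import JetSpec, PhantomConfig, generate_jet_phantom
from jetflow.tracking import (
    JetTrackingError,
    MPRPlane,
    PlaneSample,
    TrackingParams,
    compute_flow_rate,
    detect_regurgitant_frames,
    integrate_regurgitant_curve,
    locate_jet_peak,
    sample_throughplane,
    segment_jet_cross_section,
    track_mitral_regurgitation,
)


def _uniform_field(vz=100.0, shape=(12, 12, 12), spacing=2.0):
    v = np.zeros((1, *shape, 3))
    v[..., 2] = vz
    return VelocityField4D(v, np.full(3, spacing), np.array([0.0]), 150.0)


class TestMPRPlane:
    def test_basis_is_orthonormal_and_right_handed(self):
        plane = MPRPlane.from_normal(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        u, v, n = plane.in_plane_u, plane.in_plane_v, plane.normal
        np.testing.assert_allclose(np.cross(u, v), n, atol=1e-12)
        np.testing.assert_allclose([u @ v, u @ n, v @ n], 0.0, atol=1e-12)

    def test_non_orthonormal_basis_rejected(self):
        with pytest.raises(ValueError):
            MPRPlane(np.zeros(3), np.array([0.0, 0, 1]), np.array([1.0, 0, 0]),
                     np.array([1.0, 0, 0]), 40.0, 1.0)

    def test_left_handed_basis_rejected(self):
        with pytest.raises(ValueError, match="right-handed"):
            MPRPlane(np.zeros(3), np.array([0.0, 0, 1]), np.array([0.0, 1, 0]),
                     np.array([1.0, 0, 0]), 40.0, 1.0)

    def test_extent_must_be_integer_pixels(self):
        with pytest.raises(ValueError, match="integer"):
            MPRPlane.from_normal(np.zeros(3), np.array([0.0, 0, 1]), 40.5, 1.0)


class TestSampleThroughplane:
    def test_uniform_field_along_normal(self):
        field = _uniform_field(100.0)
        plane = MPRPlane.from_normal(np.full(3, 11.0), np.array([0.0, 0, 1]), 10, 1)
        s = sample_throughplane(field, 0, plane)
        np.testing.assert_allclose(s.through_plane_velocity[~s.out_of_bounds_mask], 100.0)

    def test_sign_convention_flips_with_normal(self):
        field = _uniform_field(100.0)
        plane = MPRPlane.from_normal(np.full(3, 11.0), np.array([0.0, 0, -1]), 10, 1)
        s = sample_throughplane(field, 0, plane)
        np.testing.assert_allclose(s.through_plane_velocity[~s.out_of_bounds_mask], -100.0)

    def test_oblique_normal_projects_by_cosine(self):
        field = _uniform_field(100.0)
        normal = np.array([np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3)])  # 60 deg to flow
        plane = MPRPlane.from_normal(np.full(3, 11.0), normal, 8, 1)
        s = sample_throughplane(field, 0, plane)
        np.testing.assert_allclose(
            s.through_plane_velocity[~s.out_of_bounds_mask], 50.0, atol=1e-9
        )

    def test_plane_outside_volume_rejected(self):
        field = _uniform_field()
        plane = MPRPlane.from_normal(np.full(3, 500.0), np.array([0.0, 0, 1]), 10, 1)
        with pytest.raises(JetTrackingError, match="outside"):
            sample_throughplane(field, 0, plane)


def _disk_sample(radius=5.0, value=150.0, n=40, background=0.0):
    offs = np.arange(n) + 0.5 - n / 2
    a, b = np.meshgrid(offs, offs, indexing="ij")
    v = np.where(a**2 + b**2 <= radius**2, value, background)
    return PlaneSample(
        through_plane_velocity=v,
        jet_mask=np.zeros((n, n), bool),
        pixel_area=1.0,
        frame_index=0,
        out_of_bounds_mask=np.zeros((n, n), bool),
    )


class TestSegmentation:
    def test_tophat_disk_area_matches_analytic(self):
        s = _disk_sample(radius=5.0)
        mask = segment_jet_cross_section(s)
        assert mask.sum() == pytest.approx(np.pi * 25.0, rel=0.10)

    def test_all_zero_plane_gives_empty_mask(self):
        s = _disk_sample(value=0.0)
        assert segment_jet_cross_section(s).sum() == 0

    def test_connectivity_keeps_only_origin_blob(self):
        s = _disk_sample(radius=4.0)
        # second positive blob far from the origin
        s.through_plane_velocity[2:6, 2:6] = 120.0
        mask = segment_jet_cross_section(s)
        assert mask.sum() == pytest.approx(np.pi * 16.0, rel=0.15)
        assert not mask[2:6, 2:6].any()


class TestFlowRate:
    def test_uniform_velocity_times_area(self):
        s = _disk_sample(radius=7.0, value=100.0)
        s.jet_mask[:10, :20] = True  # 200 pixels of 1 mm^2
        s.through_plane_velocity[:] = 100.0
        assert compute_flow_rate(s) == pytest.approx(200.0)

    def test_empty_mask_is_zero(self):
        s = _disk_sample()
        assert compute_flow_rate(s) == 0.0

    def test_negative_pixels_counted_signed(self):
        s = _disk_sample()
        s.through_plane_velocity[:] = 0.0
        s.through_plane_velocity[0, 0] = 100.0
        s.through_plane_velocity[0, 1] = -40.0
        s.jet_mask[0, :2] = True
        assert compute_flow_rate(s) == pytest.approx(0.6)


class TestIntegration:
    def test_half_sine_matches_closed_form(self):
        t = np.arange(0.0, 201.0, 40.0)
        q = 100.0 * np.sin(np.pi * t / 200.0)
        vol = integrate_regurgitant_curve(t, q)
        assert vol == pytest.approx(2 * 100 * 0.2 / np.pi, rel=0.02)

    def test_single_frame_zero_flow(self):
        assert integrate_regurgitant_curve(np.array([100.0]), np.array([0.0])) == 0.0

    def test_single_frame_triangular_pulse(self):
        vol = integrate_regurgitant_curve(np.array([100.0]), np.array([50.0]), 40.0)
        assert vol == pytest.approx(50.0 * 40.0 / 2.0 / 1000.0)

    def test_constant_curve_close_to_trapezoid_oracle(self):
        # same anchor convention applied to a trapezoidal rule:
        # ramps 0->50 and 50->0 over 20 ms contribute 0.5 mL each,
        # the plateau 4 * 40 ms * 50 mL/s = 8 mL
        t = np.arange(0.0, 200.0, 40.0)
        q = np.full(5, 50.0)
        vol = integrate_regurgitant_curve(t, q)
        assert vol == pytest.approx(9.0, rel=0.10)

    def test_negative_net_curve_clamped_at_zero(self):
        t = np.array([0.0, 40.0, 80.0])
        q = np.array([-30.0, -50.0, -30.0])
        assert integrate_regurgitant_curve(t, q) == 0.0

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            integrate_regurgitant_curve(np.array([40.0, 0.0]), np.array([1.0, 1.0]))


class TestDetection:
    def test_default_phantom_one_jet_active_frames(self, default_phantom):
        _, field, truth = default_phantom
        jets = detect_regurgitant_frames(field, truth.atrial_roi_mask)
        assert len(jets) == 1
        assert jets[0].frames == truth.active_frames

    def test_pure_noise_phantom_detects_nothing(self, no_jet_phantom):
        _, field, truth = no_jet_phantom
        assert detect_regurgitant_frames(field, truth.atrial_roi_mask) == []

    def test_two_jets_detected_separately(self, two_jet_phantom):
        _, field, truth = two_jet_phantom
        jets = detect_regurgitant_frames(field, truth.atrial_roi_mask)
        assert len(jets) == 2

    def test_empty_roi_rejected(self, default_phantom):
        _, field, _ = default_phantom
        with pytest.raises(ValueError, match="ROI"):
            detect_regurgitant_frames(field, np.zeros(field.grid_shape, bool))


class TestLocateJetPeak:
    def test_peak_on_axis_direction_matches_truth(self):
        # Gaussian profile: the speed maximum is unique and on the axis
        cfg = PhantomConfig(jet=JetSpec(profile="gaussian"), noise_sd=0.0, seed=0)
        field, truth = generate_jet_phantom(cfg)
        jets = detect_regurgitant_frames(field, truth.atrial_roi_mask)
        frame = 9
        loc, direction, speed = locate_jet_peak(field, frame, jets[0].masks[frame])
        axis = truth.jet_axis_per_frame[frame]
        d = loc - truth.orifice_center
        radial = np.linalg.norm(d - (d @ axis) * axis)
        assert radial <= 2.5 + 1e-9  # within one voxel of the jet axis
        assert direction @ axis > 0.98

    def test_single_voxel_component(self):
        field = _uniform_field(0.0)
        field.velocities[0, 5, 5, 5] = [0.0, 30.0, 40.0]
        mask = np.zeros(field.grid_shape, bool)
        mask[5, 5, 5] = True
        loc, direction, speed = locate_jet_peak(field, 0, mask)
        np.testing.assert_allclose(loc, [10.0, 10.0, 10.0])
        np.testing.assert_allclose(direction, [0.0, 0.6, 0.8])
        assert speed == pytest.approx(50.0)

    def test_flagged_maximum_skipped_for_unflagged_secondary(self):
        field = _uniform_field(0.0)
        field.velocities[0, 5, 5, 5] = [0.0, 0.0, 140.0]  # global max, aliased
        field.velocities[0, 5, 5, 7] = [0.0, 0.0, 120.0]  # secondary, downstream
        flags = np.zeros((1, *field.grid_shape), bool)
        flags[0, 5, 5, 5] = True
        field.alias_flags = flags
        mask = np.zeros(field.grid_shape, bool)
        mask[5, 5, 5:8] = True
        loc, _, speed = locate_jet_peak(field, 0, mask)
        np.testing.assert_allclose(loc, [10.0, 10.0, 14.0])
        assert speed == pytest.approx(120.0)

    def test_all_flagged_component_raises(self):
        field = _uniform_field(100.0)
        field.alias_flags = np.ones((1, *field.grid_shape), bool)
        mask = np.zeros(field.grid_shape, bool)
        mask[5, 5, 5] = True
        with pytest.raises(JetTrackingError, match="alias"):
            locate_jet_peak(field, 0, mask)


class TestEndToEnd:
    def test_default_phantom_recovery(self, default_phantom):
        _, field, truth = default_phantom
        res = track_mitral_regurgitation(field, truth.atrial_roi_mask)
        assert res.n_jets == 1
        assert res.total_mr_volume == pytest.approx(truth.true_volume, rel=0.10)

    def test_total_is_sum_of_jets_exactly(self, two_jet_phantom):
        _, field, truth = two_jet_phantom
        res = track_mitral_regurgitation(field, truth.atrial_roi_mask)
        assert res.total_mr_volume == sum(j.volume for j in res.jets)

    def test_no_jet_gives_zero_volume_and_zero_jets(self, no_jet_phantom):
        _, field, truth = no_jet_phantom
        res = track_mitral_regurgitation(field, truth.atrial_roi_mask)
        assert res.n_jets == 0
        assert res.total_mr_volume == 0.0
        assert res.mr_start_frame is None
        assert res.mr_duration_frames == 0

    def test_duration_matches_phantom_within_one_frame(self, default_phantom):
        _, field, truth = default_phantom
        res = track_mitral_regurgitation(field, truth.atrial_roi_mask)
        assert abs(res.mr_duration_frames - len(truth.active_frames)) <= 1

    def test_translation_invariance(self):
        base = dict(noise_sd=0.0, seed=3)
        res = []
        for center in [(30.0, 30.0, 22.0), (35.0, 32.5, 19.5)]:  # 2,1,-1 voxel shift
            cfg = PhantomConfig(jet=JetSpec(orifice_center=center), **base)
            field, truth = generate_jet_phantom(cfg)
            r = track_mitral_regurgitation(field, truth.atrial_roi_mask)
            res.append(r.total_mr_volume)
        assert res[1] == pytest.approx(res[0], rel=0.01)

    def test_flow_scales_linearly_with_velocity_scale(self, clean_phantom):
        _, field, truth = clean_phantom
        res1 = track_mitral_regurgitation(field, truth.atrial_roi_mask)
        scaled = field.copy()
        scaled.velocities = scaled.velocities * 1.2
        res2 = track_mitral_regurgitation(scaled, truth.atrial_roi_mask)
        assert res2.total_mr_volume == pytest.approx(1.2 * res1.total_mr_volume, rel=0.02)

    def test_core_pixels_positive_when_normal_along_jet(self, clean_phantom):
        _, field, truth = clean_phantom
        jets = detect_regurgitant_frames(field, truth.atrial_roi_mask)
        frame = 9
        loc, direction, _ = locate_jet_peak(field, frame, jets[0].masks[frame])
        plane = MPRPlane.from_normal(loc, direction)
        s = sample_throughplane(field, frame, plane)
        mask = segment_jet_cross_section(s)
        assert (s.through_plane_velocity[mask] > 0).all()

    def test_result_serializes(self, default_phantom):
        import json

        _, field, truth = default_phantom
        res = track_mitral_regurgitation(field, truth.atrial_roi_mask)
        payload = json.dumps(res.to_dict())
        assert "total_mr_volume_ml" in payload
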