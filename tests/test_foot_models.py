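import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import itwgait as g
from itwgait.foot_models import MONO_FOREFOOT_MARKER
from itwgait.gaitdata_io import MarkerError

TIBIA_CLOUD = {
    "MMAL": np.array([0.0, 40.0, 100.0]),
    "LMAL": np.array([0.0, -40.0, 100.0]),
    "KNE": np.array([0.0, -50.0, 500.0]),
    "KNEM": np.array([0.0, 50.0, 500.0]),
}

CALC_TRIAD = {
    "CA": np.array([0.0, 0.0, 40.0]),
    "MCA": np.array([30.0, 25.0, 25.0]),
    "LCA": np.array([30.0, -25.0, 25.0]),
}


def rotate_cloud(markers, rot: Rotation):
    return {k: rot.apply(v) for k, v in markers.items()}


class TestTibiaFrame:
    def test_axis_aligned_construction(self):
        frame = g.build_tibia_frame(TIBIA_CLOUD, g.Side.RIGHT)
        np.testing.assert_allclose(frame.origin, [0.0, 0.0, 100.0], atol=1e-12)
        # longitudinal axis points to the knee centre (+Z here)
        np.testing.assert_allclose(-frame.z_axis, [0.0, 0.0, 1.0], atol=1e-12)
        # flexion axis lies along the malleolar line, oriented so that
        # dorsiflexion (toe-up) is a positive rotation
        assert abs(abs(frame.y_axis[1]) - 1.0) < 1e-12
        np.testing.assert_allclose(np.cross(frame.x_axis, frame.y_axis),
                                   frame.z_axis, atol=1e-12)

    def test_rigid_rotation_rotates_axes_exactly(self):
        rot = Rotation.from_euler("z", 30, degrees=True)
        base = g.build_tibia_frame(TIBIA_CLOUD, g.Side.RIGHT)
        moved = g.build_tibia_frame(rotate_cloud(TIBIA_CLOUD, rot), g.Side.RIGHT)
        np.testing.assert_allclose(moved.rotation, rot.as_matrix() @ base.rotation,
                                   atol=1e-9)

    def test_collinear_markers_are_degenerate(self):
        cloud = {
            "MMAL": np.array([0.0, 0.0, 90.0]),
            "LMAL": np.array([0.0, 0.0, 110.0]),
            "KNE": np.array([0.0, 0.0, 500.0]),
            "KNEM": np.array([0.0, 0.0, 520.0]),
        }
        with pytest.raises(MarkerError):
            g.build_tibia_frame(cloud, g.Side.RIGHT)

    def test_missing_marker_error_names_label(self):
        cloud = dict(TIBIA_CLOUD)
        del cloud["KNEM"]
        with pytest.raises(MarkerError, match="KNEM"):
            g.build_tibia_frame(cloud, g.Side.RIGHT)


class TestMonoFootFrame:
    def test_longitudinal_axis_from_ca_to_forefoot(self):
        markers = {"CA": np.array([0.0, 0.0, 50.0]),
                   "TOE": np.array([150.0, 0.0, 20.0])}
        frame = g.build_foot_frame_mono(markers, g.FootModel.DAV)
        expect = np.array([150.0, 0.0, -30.0])
        np.testing.assert_allclose(frame.x_axis, expect / np.linalg.norm(expect),
                                   atol=1e-12)
        np.testing.assert_allclose(frame.origin, markers["CA"], atol=1e-12)

    def test_pitch_oracle(self):
        markers = {"CA": np.array([0.0, 0.0, 50.0]),
                   "MT": np.array([150.0, 0.0, 50.0])}
        rot = Rotation.from_rotvec(np.deg2rad(10) * np.array([0.0, -1.0, 0.0]))
        nose_down = {k: markers["CA"] + rot.apply(v - markers["CA"])
                     for k, v in markers.items()}
        base = g.build_foot_frame_mono(markers, g.FootModel.PIG)
        pitched = g.build_foot_frame_mono(nose_down, g.FootModel.PIG)
        ang = np.degrees(np.arccos(np.clip(pitched.x_axis @ base.x_axis, -1, 1)))
        assert abs(ang - 10.0) < 1e-9

    def test_only_ca_and_forefoot_enter_the_construction(self):
        markers = {"CA": np.array([0.0, 0.0, 50.0]),
                   "MT": np.array([150.0, 5.0, 20.0]),
                   "MCA": np.array([20.0, 20.0, 30.0])}
        base = g.build_foot_frame_mono(markers, g.FootModel.PIG)
        moved = dict(markers, MCA=markers["MCA"] + 50.0)
        same = g.build_foot_frame_mono(moved, g.FootModel.PIG)
        np.testing.assert_array_equal(base.rotation, same.rotation)
        raised = dict(markers, CA=markers["CA"] + [0.0, 0.0, 10.0])
        changed = g.build_foot_frame_mono(raised, g.FootModel.PIG)
        assert not np.allclose(changed.x_axis, base.x_axis)

    def test_coincident_markers_are_degenerate(self):
        markers = {"CA": np.zeros(3), "TOE": np.array([0.5, 0.0, 0.0])}
        with pytest.raises(MarkerError):
            g.build_foot_frame_mono(markers, g.FootModel.DAV)


class TestHindfootFrame:
    def test_symmetric_triad_has_mediolateral_normal(self):
        frame = g.build_hindfoot_frame_ofm(CALC_TRIAD, g.Side.RIGHT)
        # sagittal-plane normal = flexion axis, along +-Y for this triad
        assert abs(abs(frame.y_axis[1]) - 1.0) < 1e-12
        # longitudinal axis lies in the XZ plane
        assert abs(frame.x_axis[1]) < 1e-12

    def test_forefoot_markers_never_enter(self):
        markers = dict(CALC_TRIAD,
                       MT=np.array([100.0, 5.0, 20.0]),
                       TOE=np.array([150.0, 0.0, 20.0]))
        base = g.build_hindfoot_frame_ofm(markers, g.Side.RIGHT)
        moved = dict(markers, MT=markers["MT"] + 50.0, TOE=markers["TOE"] - 30.0)
        same = g.build_hindfoot_frame_ofm(moved, g.Side.RIGHT)
        np.testing.assert_array_equal(base.rotation, same.rotation)

    def test_rotation_oracle_about_y(self):
        rot = Rotation.from_euler("y", 15, degrees=True)
        base = g.build_hindfoot_frame_ofm(CALC_TRIAD, g.Side.RIGHT)
        # rigid reconstruction: freeze the virtual point before rotating
        vloc = _virtual_local(CALC_TRIAD)
        base_r = g.build_hindfoot_frame_ofm(CALC_TRIAD, g.Side.RIGHT,
                                            virtual_local=vloc)
        moved = g.build_hindfoot_frame_ofm(rotate_cloud(CALC_TRIAD, rot),
                                           g.Side.RIGHT, virtual_local=vloc)
        np.testing.assert_allclose(moved.rotation,
                                   rot.as_matrix() @ base_r.rotation, atol=1e-9)
        np.testing.assert_allclose(base.rotation, base_r.rotation, atol=1e-9)

    def test_collinear_triad_is_degenerate(self):
        bad = {"CA": np.zeros(3), "MCA": np.array([10.0, 0.0, 0.0]),
               "LCA": np.array([20.0, 0.0, 0.0])}
        with pytest.raises(MarkerError):
            g.build_hindfoot_frame_ofm(bad, g.Side.RIGHT)


def _virtual_local(triad):
    from itwgait.foot_models import _calcaneus_technical, _ofm_virtual_default

    ca, mca, lca = triad["CA"], triad["MCA"], triad["LCA"]
    _, T = _calcaneus_technical(ca[None], mca[None], lca[None], g.Side.RIGHT)
    v = _ofm_virtual_default(ca[None], mca[None], lca[None], g.Side.RIGHT)[0]
    return T[0].T @ (v - ca)


class TestSagittalAngle:
    def _tibia(self):
        return g.build_tibia_frame(TIBIA_CLOUD, g.Side.RIGHT)

    def test_identity_is_zero(self):
        t = self._tibia()
        assert abs(g.sagittal_angle(t, t)) < 1e-12

    def test_pure_flexion_rotation_recovered(self):
        t = self._tibia()
        rot = Rotation.from_rotvec(np.deg2rad(20) * t.y_axis)
        foot = g.SegmentFrame(t.origin, rot.apply(t.x_axis), rot.apply(t.y_axis),
                              rot.apply(t.z_axis))
        assert abs(g.sagittal_angle(t, foot) - 20.0) < 1e-9

    @given(st.floats(-60, 60), st.floats(-40, 40), st.floats(-40, 40))
    def test_leading_angle_matches_composed_rotation(self, alpha, beta, gamma):
        """Composing rotations (alpha, beta, gamma) about the ordered local
        axes and decomposing recovers alpha (matrix-construction oracle)."""
        t = self._tibia()
        R_local = (
            Rotation.from_euler("Y", alpha, degrees=True)
            * Rotation.from_euler("X", beta, degrees=True)
            * Rotation.from_euler("Z", gamma, degrees=True)
        ).as_matrix()
        Rf = t.rotation @ R_local
        foot = g.SegmentFrame(t.origin, Rf[:, 0], Rf[:, 1], Rf[:, 2])
        assert abs(g.sagittal_angle(t, foot) - alpha) < 1e-6

    def test_static_offset_subtracted(self):
        t = self._tibia()
        rot = Rotation.from_rotvec(np.deg2rad(23) * t.y_axis)
        Rf = rot.as_matrix() @ t.rotation
        foot = g.SegmentFrame(t.origin, Rf[:, 0], Rf[:, 1], Rf[:, 2])
        off = g.CalibrationOffsets(model=g.FootModel.PIG, side=g.Side.RIGHT,
                                   neutral_angle_deg=23.0)
        assert abs(g.sagittal_angle(t, foot, off)) < 1e-9


class TestStaticCalibration:
    def _static_with_angle(self, angles_deg, model=g.FootModel.PIG):
        """Standing trial whose raw sagittal angle equals angles_deg[i] at
        frame i, built by rotating the whole foot about the flexion axis."""
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0)
        static = g.synthesize_static(cfg)
        n = static.n_frames
        angles = np.resize(np.asarray(angles_deg, float), n)
        rot = Rotation.from_rotvec(
            np.deg2rad(angles)[:, None] * np.array([0.0, -1.0, 0.0])[None, :]
        )
        ankle = np.array([0.0, 0.0, 0.3 * cfg.foot_length_mm])
        markers = dict(static.markers)
        for lab in ("CA", "MCA", "LCA", "MT", "TOE"):
            markers[lab] = ankle + rot.apply(static.markers[lab] - ankle)
        return replace(static, markers=markers)

    def test_constant_static_angle_becomes_neutral(self):
        trial = self._static_with_angle([3.2])
        off = g.static_calibration(trial, g.FootModel.PIG)
        raw = g.compute_ankle_trace(trial, g.FootModel.PIG).values
        assert np.ptp(raw) < 1e-9  # pose is constant, so the raw angle is too
        assert abs(off.neutral_angle_deg - raw.mean()) < 1e-9
        base = g.static_calibration(self._static_with_angle([0.0]), g.FootModel.PIG)
        # rotating the foot 3.2 deg about the flexion axis moves the raw
        # sagittal angle by ~3.2 deg (small cross-axis coupling aside)
        assert abs((off.neutral_angle_deg - base.neutral_angle_deg) - 3.2) < 0.02

    def test_offset_zeroes_the_static_trial_itself(self):
        trial = self._static_with_angle([3.2])
        for model in g.FootModel:
            off = g.static_calibration(trial, model, apply_offset=True)
            trace = g.compute_ankle_trace(trial, model, off)
            np.testing.assert_allclose(trace.values, 0.0, atol=1e-6)

    def test_alternating_static_angle_averages(self):
        trial = self._static_with_angle([3.0, 3.4])
        off = g.static_calibration(trial, g.FootModel.PIG)
        raw = g.compute_ankle_trace(trial, g.FootModel.PIG).values
        assert abs(off.neutral_angle_deg - raw.mean()) < 1e-9
        off_const = g.static_calibration(self._static_with_angle([3.2]),
                                         g.FootModel.PIG)
        assert abs(off.neutral_angle_deg - off_const.neutral_angle_deg) < 1e-4

    def test_insufficient_static_data_raises(self):
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0)
        static = g.synthesize_static(cfg, duration_s=0.5)
        with pytest.raises(g.gaitdata_io.CalibrationError):
            g.static_calibration(static, g.FootModel.PIG)


class TestComputeAnkleTrace:
    def test_constant_waveform_round_trip(self):
        wave = g.WaveformParams.toe_walking(harmonics=0)  # flat at -10 deg
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0, bf_waveform=wave,
                                       midfoot_amplitude_bf=0.0)
        trial, _ = g.synthesize_trial(cfg, g.Condition.BF, n_cycles=2)
        offsets = g.calibrate_subject(g.synthesize_static(cfg))
        trace = g.compute_ankle_trace(trial, g.FootModel.OFM,
                                      offsets[g.FootModel.OFM])
        np.testing.assert_allclose(trace.values, -10.0, atol=0.1)

    def test_midfoot_motion_shifts_mono_models_toward_plantarflexion(self):
        wave = g.WaveformParams.toe_walking(harmonics=0)
        base_cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0, bf_waveform=wave,
                                            midfoot_amplitude_bf=0.0)
        mid_cfg = replace(base_cfg, midfoot_amplitude_bf=15.0)
        offsets = g.calibrate_subject(g.synthesize_static(base_cfg))
        t0, _ = g.synthesize_trial(base_cfg, g.Condition.BF, n_cycles=2)
        t15, _ = g.synthesize_trial(mid_cfg, g.Condition.BF, n_cycles=2)
        ofm0 = g.compute_ankle_trace(t0, g.FootModel.OFM, offsets[g.FootModel.OFM])
        ofm15 = g.compute_ankle_trace(t15, g.FootModel.OFM, offsets[g.FootModel.OFM])
        np.testing.assert_allclose(ofm0.values, ofm15.values, atol=1e-9)
        for model in (g.FootModel.PIG, g.FootModel.DAV):
            m0 = g.compute_ankle_trace(t0, model, offsets[model])
            m15 = g.compute_ankle_trace(t15, model, offsets[model])
            assert np.mean(m15.values - m0.values) < -2.0  # plantarward shift

    def test_missing_ca_error_names_the_label(self, clean_trial):
        trial, _ = clean_trial
        markers = {k: v for k, v in trial.markers.items() if k != "CA"}
        broken = replace(trial, markers=markers)
        with pytest.raises(MarkerError, match="CA"):
            g.compute_ankle_trace(broken, g.FootModel.OFM)


class TestInvariances:
    @given(st.floats(-180, 180), st.floats(-500, 500), st.floats(-500, 500))
    def test_vertical_axis_rigid_motion_leaves_angles_unchanged(
        self, yaw, tx, ty
    ):
        """Rotating the whole lab about the vertical and translating leaves
        every model's sagittal angle unchanged."""
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0)
        trial, _ = g.synthesize_trial(cfg, g.Condition.BF, n_cycles=1)
        rot = Rotation.from_euler("z", yaw, degrees=True)
        shift = np.array([tx, ty, 0.0])
        moved = replace(
            trial,
            markers={k: rot.apply(v) + shift for k, v in trial.markers.items()},
        )
        for model in g.FootModel:
            a = g.compute_ankle_trace(trial, model).values
            b = g.compute_ankle_trace(moved, model).values
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_ofm_fully_rigid_motion_invariant_with_calibrated_virtual_point(self):
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0)
        trial, _ = g.synthesize_trial(cfg, g.Condition.BF, n_cycles=1)
        off = g.calibrate_subject(g.synthesize_static(cfg))[g.FootModel.OFM]
        rot = Rotation.from_euler("zxy", [40, 25, -15], degrees=True)
        moved = replace(
            trial,
            markers={k: rot.apply(v) + 100.0 for k, v in trial.markers.items()},
        )
        a = g.compute_ankle_trace(trial, g.FootModel.OFM, off).values
        b = g.compute_ankle_trace(moved, g.FootModel.OFM, off).values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_mirrored_left_trial_reproduces_the_angle_trace(self):
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0)
        trial, _ = g.synthesize_trial(cfg, g.Condition.BF, n_cycles=1)
        flip = np.array([1.0, -1.0, 1.0])
        mirrored = replace(
            trial,
            side=g.Side.LEFT,
            markers={k: v * flip for k, v in trial.markers.items()},
        )
        for model in g.FootModel:
            a = g.compute_ankle_trace(trial, model).values
            b = g.compute_ankle_trace(mirrored, model).values
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_mono_minus_ofm_grows_with_midfoot_amplitude(self):
        cfg = g.SyntheticSubjectConfig(noise_sd_mm=0.0)
        offsets = g.calibrate_subject(g.synthesize_static(cfg))
        gaps = []
        for amp in (0.0, 5.0, 10.0, 15.0):
            c = replace(cfg, midfoot_amplitude_bf=amp)
            trial, truth = g.synthesize_trial(c, g.Condition.BF, n_cycles=1)
            res = g.process_trial(trial, offsets, events=truth.events)
            gap = np.sqrt(np.mean(
                (res[g.FootModel.PIG].cycles[0].samples
                 - res[g.FootModel.OFM].cycles[0].samples) ** 2
            ))
            gaps.append(gap)
        assert all(b > a for a, b in zip(gaps, gaps[1:]))
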