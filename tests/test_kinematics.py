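"""Movement definition, range checks, .mot I/O and the MSK surrogate."""

import numpy as np
import pytest

from emgforge import (load_pose_library, resolve_pose, define_movement,
                      check_joint_ranges, read_mot, write_mot, fibre_length,
                      torque_demand, static_optimization_activations,
                      MuscleModel, JointTrajectory)
from emgforge.config import DEFAULT_DOF_RANGES, DEFAULT_DOF_NAMES
from emgforge.kinematics import _force_length


class TestPoseLibrary:
    def test_eight_poses_plus_neutral(self):
        lib = load_pose_library()
        assert len(lib) == 9  # 8 named poses + neutral "default"
        assert lib["default"].angle_map == {}

    def test_all_pose_dofs_valid(self):
        lib = load_pose_library()
        for pose in lib.values():
            for dof in pose.angle_map:
                assert dof in DEFAULT_DOF_RANGES

    def test_combination_sums_keywise(self):
        lib = load_pose_library()
        combo = resolve_pose("open+flex", lib)
        expected = dict(lib["open"].angle_map)
        for dof, ang in lib["flex"].angle_map.items():
            expected[dof] = expected.get(dof, 0.0) + ang
        assert combo.angle_map == expected

    def test_unknown_pose_raises(self):
        with pytest.raises(KeyError):
            resolve_pose("nonexistent")


class TestDefineMovement:
    def test_flex_and_back(self):
        traj = define_movement(["default", "flex", "default"], [1.0, 1.0], 50)
        assert traj.time.size == 101
        wf = traj.dof("wrist_flexion")
        assert wf[0] == 0.0 and wf[50] == 60.0 and wf[100] == 0.0
        assert wf[:51].max() == 60.0 and np.all(np.diff(wf[:51]) >= 0)

    def test_constant_identity(self):
        traj = define_movement(["default", "default"], [2.0], 50)
        assert np.all(traj.angles == 0.0)

    def test_open_to_grasp_interpolant(self):
        lib = load_pose_library()
        traj = define_movement(["open", "grasp"], [1.0], 50)
        # direct evaluation of the cosine interpolant at an interior sample
        i = 20
        s = 0.5 - 0.5 * np.cos(np.pi * traj.time[i] / 1.0)
        d = traj.dof_names.index("index_mcp_flexion")
        a0 = lib["open"].angle_map["index_mcp_flexion"]
        a1 = lib["grasp"].angle_map["index_mcp_flexion"]
        assert traj.angles[i, d] == pytest.approx(a0 * (1 - s) + a1 * s)
        assert np.all(traj.dof("wrist_flexion") == 0.0)

    def test_endpoints_exact(self):
        traj = define_movement(["open", "grasp", "ext"], [0.7, 1.3], 50)
        lib = load_pose_library()
        for t_idx, pose in ((0, "open"), (35, "grasp"), (100, "ext")):
            for dof, ang in lib[pose].angle_map.items():
                d = traj.dof_names.index(dof)
                assert traj.angles[t_idx, d] == ang

    def test_linear_mode(self):
        traj = define_movement(["default", "flex"], [1.0], 50,
                               interpolation="linear")
        wf = traj.dof("wrist_flexion")
        assert np.allclose(np.diff(wf), np.diff(wf)[0])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            define_movement(["default", "flex"], [1.0, 1.0], 50)
        with pytest.raises(ValueError):
            define_movement(["default", "flex"], [-1.0], 50)
        with pytest.raises(KeyError):
            define_movement(["default", "nope"], [1.0], 50)


class TestRangeCheck:
    def test_compliant_trajectory_empty_report(self):
        traj = define_movement(["default", "flex", "default"], [1.0, 1.0], 50)
        assert check_joint_ranges(traj) == []

    def test_single_violation_located(self):
        traj = define_movement(["default", "default"], [1.0], 50)
        d = traj.dof_names.index("wrist_flexion")
        traj.angles[17, d] = 999.0
        report = check_joint_ranges(traj)
        assert len(report) == 1
        assert (report[0].dof, report[0].sample) == ("wrist_flexion", 17)

    def test_boundary_is_inclusive(self):
        traj = define_movement(["default", "default"], [1.0], 50)
        d = traj.dof_names.index("wrist_flexion")
        traj.angles[5, d] = DEFAULT_DOF_RANGES["wrist_flexion"][1]
        assert check_joint_ranges(traj) == []


class TestMotFiles:
    def test_roundtrip_lossless(self, tmp_path):
        traj = define_movement(["default", "open+flex", "grasp"],
                               [0.9, 1.1], 64)
        path = tmp_path / "movement.mot"
        write_mot(traj, path)
        back = read_mot(path)
        assert back.dof_names == traj.dof_names
        assert np.allclose(back.time, traj.time, atol=1e-9)
        assert np.allclose(back.angles, traj.angles, atol=1e-9)

    def test_header_format(self, tmp_path):
        traj = define_movement(["default", "flex"], [1.0], 10)
        path = tmp_path / "m.mot"
        write_mot(traj, path, name="wristflex")
        lines = path.read_text().splitlines()
        assert lines[0] == "name wristflex"
        assert lines[1] == f"datacolumns {len(DEFAULT_DOF_NAMES) + 1}"
        assert lines[2] == "datarows 11"
        assert lines[3] == "inDegrees=yes"
        assert lines[4] == "endheader"
        assert lines[5].split("\t")[0] == "time"


class TestFibreLength:
    def test_neutral_movement_constant(self, cfg):
        traj = define_movement(["default", "default"], [1.0], 50)
        mt = fibre_length(cfg.muscles["FCR"], traj)
        assert np.all(mt.fibre_length_norm == mt.fibre_length_norm[0])
        assert mt.fibre_length_norm[0] == pytest.approx(1.0)

    def test_flexor_shortens_in_flexion(self, cfg):
        traj = define_movement(["default", "flex"], [1.0], 50)
        mt = fibre_length(cfg.muscles["FCR"], traj)
        assert np.all(np.diff(mt.fibre_length_norm) <= 0)
        assert mt.fibre_length_norm[-1] < 1.0
        ext = fibre_length(cfg.muscles["ECRB"], traj)
        assert ext.fibre_length_norm[-1] > 1.0

    def test_moment_arm_linearity(self):
        traj = define_movement(["default", "flex"], [1.0], 50)
        m1 = MuscleModel("a", 0.06, 0.2, 100.0, {"wrist_flexion": 0.01})
        m2 = MuscleModel("b", 0.06, 0.2, 100.0, {"wrist_flexion": 0.02})
        d1 = 1.0 - fibre_length(m1, traj).fibre_length_norm
        d2 = 1.0 - fibre_length(m2, traj).fibre_length_norm
        assert np.allclose(d2, 2 * d1, atol=1e-12)

    def test_superposition_over_dofs(self):
        both = MuscleModel("ab", 0.06, 0.2, 100.0,
                           {"wrist_flexion": 0.012, "wrist_deviation": 0.007})
        only_f = MuscleModel("f", 0.06, 0.2, 100.0, {"wrist_flexion": 0.012})
        only_d = MuscleModel("d", 0.06, 0.2, 100.0, {"wrist_deviation": 0.007})
        traj = define_movement(["default", "flex+udev"], [1.0], 50)
        dev_both = 1.0 - fibre_length(both, traj).fibre_length_norm
        dev_sum = ((1.0 - fibre_length(only_f, traj).fibre_length_norm)
                   + (1.0 - fibre_length(only_d, traj).fibre_length_norm))
        assert np.allclose(dev_both, dev_sum, atol=1e-12)

    def test_band_clipping_and_warning(self):
        huge = MuscleModel("huge", 0.02, 0.2, 100.0, {"wrist_flexion": 0.08})
        traj = define_movement(["default", "flex"], [1.0], 50)
        mt = fibre_length(huge, traj)
        assert mt.fibre_length_norm.min() == 0.5
        assert mt.warnings


class TestStaticOptimization:
    def test_zero_torque_zero_activation(self, cfg):
        traj = define_movement(["default", "flex", "default"], [1.0, 1.0], 40)
        muscles = [cfg.muscles[n] for n in ("FCR", "ECRB")]
        tq = {"wrist_flexion": np.zeros(traj.time.size)}
        act, infeasible = static_optimization_activations(muscles, traj, tq)
        assert np.all(act == 0.0)
        assert not infeasible.any()

    def test_single_muscle_closed_form(self):
        mus = MuscleModel("solo", 0.06, 0.2, 200.0, {"wrist_flexion": 0.015})
        traj = define_movement(["default", "flex"], [1.0], 20)
        tau = np.full(traj.time.size, 0.8)
        act, infeasible = static_optimization_activations(
            [mus], traj, {"wrist_flexion": tau})
        lnorm = fibre_length(mus, traj).fibre_length_norm
        expected = tau / (200.0 * _force_length(lnorm, 0.45) * 0.015)
        assert not infeasible.any()
        assert np.allclose(act[:, 0], expected, atol=1e-6)

    def test_identical_muscles_share_equally(self):
        m1 = MuscleModel("m1", 0.06, 0.2, 200.0, {"wrist_flexion": 0.015})
        m2 = MuscleModel("m2", 0.06, 0.2, 200.0, {"wrist_flexion": 0.015})
        traj = define_movement(["default", "default"], [0.5], 20)
        tau = np.full(traj.time.size, 1.0)
        act, _ = static_optimization_activations(
            [m1, m2], traj, {"wrist_flexion": tau})
        assert np.allclose(act[:, 0], act[:, 1], atol=1e-6)

    def test_beats_grid_search(self):
        """Objective never exceeds a dense grid search on a 2-muscle problem."""
        m1 = MuscleModel("m1", 0.06, 0.2, 150.0, {"wrist_flexion": 0.012})
        m2 = MuscleModel("m2", 0.07, 0.2, 250.0, {"wrist_flexion": 0.018})
        traj = define_movement(["default", "default"], [0.1], 20)
        tau = np.full(traj.time.size, 1.4)
        act, _ = static_optimization_activations(
            [m1, m2], traj, {"wrist_flexion": tau})
        l1 = fibre_length(m1, traj).fibre_length_norm[0]
        l2 = fibre_length(m2, traj).fibre_length_norm[0]
        c1 = 150.0 * _force_length(np.array([l1]), 0.45)[0] * 0.012
        c2 = 250.0 * _force_length(np.array([l2]), 0.45)[0] * 0.018
        best = np.inf
        for a1 in np.linspace(0, 1, 2001):
            a2 = (1.4 - c1 * a1) / c2
            if 0 <= a2 <= 1:
                best = min(best, a1 ** 2 + a2 ** 2)
        assert act[0, 0] ** 2 + act[0, 1] ** 2 <= best + 1e-6

    def test_infeasible_flagged_and_bounded(self):
        weak = MuscleModel("weak", 0.06, 0.2, 10.0, {"wrist_flexion": 0.01})
        traj = define_movement(["default", "default"], [0.1], 20)
        tau = np.full(traj.time.size, 5.0)  # far beyond capacity
        act, infeasible = static_optimization_activations(
            [weak], traj, {"wrist_flexion": tau})
        assert infeasible.all()
        assert np.all((act >= 0) & (act <= 1))

    def test_unspanned_dof_raises(self, cfg):
        traj = define_movement(["default", "default"], [0.1], 20)
        with pytest.raises(ValueError):
            static_optimization_activations(
                [cfg.muscles["FCR"]], traj,
                {"thumb_ip_flexion": np.ones(traj.time.size)})


def test_torque_demand_elastic_term():
    traj = define_movement(["default", "flex"], [1.0], 100)
    tau_free = torque_demand(traj, "wrist_flexion", 0.05, 0.0, 0.0)
    tau_spring = torque_demand(traj, "wrist_flexion", 0.05, 0.0, 2.0)
    q = np.deg2rad(traj.dof("wrist_flexion"))
    assert np.allclose(tau_spring - tau_free, 2.0 * q, atol=1e-9)
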