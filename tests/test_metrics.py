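"""Evaluation metrics: angle/position errors, APCK, SPARC, losses,
aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import handkin as hk

from conftest import make_angle_traj, single_joint_traj
from oracles import pooled_mean_std, sparc_bruteforce

HALF_NORMAL_MEAN = math.sqrt(2 / math.pi)  # E|N(0,1)|


class TestMpjae:
    def test_identical_trajectories_score_zero(self, rng):
        traj = make_angle_traj(rng.uniform(100, 170, (20, 15)))
        res = hk.mpjae(traj, traj)
        assert res.mean == 0.0 and res.std == 0.0
        assert res.n == 20 * 15

    def test_two_sample_mean(self):
        gt = single_joint_traj([150.0, 150.0])
        pred = single_joint_traj([153.0, 144.0])
        assert hk.mpjae(pred, gt).mean == pytest.approx(4.5)

    def test_gaussian_noise_recovers_half_normal_mean(self, rng):
        sigma = 5.0
        gt = make_angle_traj(np.full((7000, 15), 140.0))
        pred = make_angle_traj(gt.angles + rng.normal(0, sigma, (7000, 15)))
        res = hk.mpjae(pred, gt)
        assert res.n == 105000
        assert res.mean == pytest.approx(sigma * HALF_NORMAL_MEAN, rel=0.02)

    def test_missing_samples_are_excluded_pairwise(self):
        gt = single_joint_traj([150.0, 150.0, 150.0])
        p = np.array([[154.0], [np.nan], [146.0]])
        pred = single_joint_traj(p[:, 0])
        res = hk.mpjae(pred, gt)
        assert res.mean == pytest.approx(4.0) and res.n == 2

    def test_misaligned_inputs_raise_alignment_error(self):
        with pytest.raises(hk.AlignmentError, match="[Rr]esample"):
            hk.mpjae(single_joint_traj(np.full(10, 150.0), fps=30.0),
                     single_joint_traj(np.full(10, 150.0), fps=60.0))

    def test_permutation_of_joints_applied_to_both_is_invariant(self, rng):
        a = rng.uniform(100, 170, (30, 15))
        b = a + rng.normal(0, 3, a.shape)
        perm = rng.permutation(15)
        labs = tuple(hk.ANGLE_LABELS[i] for i in perm)
        r0 = hk.mpjae(make_angle_traj(b), make_angle_traj(a))
        r1 = hk.mpjae(make_angle_traj(b[:, perm], joints=labs),
                      make_angle_traj(a[:, perm], joints=labs))
        assert r0.mean == pytest.approx(r1.mean)
        assert r0.std == pytest.approx(r1.std)


class TestApck:
    def test_direct_count(self):
        gt = single_joint_traj([150.0, 150.0])
        pred = single_joint_traj([153.0, 156.0])  # errors 3 and 6
        assert hk.apck(pred, gt, 5.0) == 0.5

    def test_saturates_at_one_above_max_error(self):
        gt = single_joint_traj([150.0, 150.0])
        pred = single_joint_traj([153.0, 156.0])
        assert hk.apck(pred, gt, 7.0) == 1.0

    def test_threshold_inequality_is_strict(self):
        gt = single_joint_traj([150.0, 150.0])
        pred = single_joint_traj([154.0, 154.0])  # both errors exactly 4
        assert hk.apck(pred, gt, 4.0) == 0.0
        assert hk.apck(pred, gt, 4.0 + 1e-9) == 1.0

    @pytest.mark.parametrize("tau", [2.5, 5.0, 10.0])
    def test_gaussian_noise_matches_half_normal_cdf(self, rng, tau):
        sigma = 5.0
        gt = make_angle_traj(np.full((7000, 15), 140.0))
        pred = make_angle_traj(gt.angles + rng.normal(0, sigma, (7000, 15)))
        expected = math.erf(tau / (sigma * math.sqrt(2)))
        assert hk.apck(pred, gt, tau) == pytest.approx(expected, abs=0.01)

    def test_curve_is_monotone_with_normalised_auc(self, rng):
        gt = make_angle_traj(np.full((500, 15), 140.0))
        pred = make_angle_traj(gt.angles + rng.normal(0, 5, (500, 15)))
        curve = hk.apck_curve(pred, gt)
        assert np.all(np.diff(curve.scores) >= 0)
        assert 0.0 <= curve.auc <= 1.0
        # identical inputs give AUC exactly 1 minus nothing: all errors 0
        ident = hk.apck_curve(gt, gt)
        assert ident.auc == pytest.approx(1.0, abs=1e-2)
        assert ident.scores[1] == 1.0

    def test_empty_threshold_grid_rejected(self, rng):
        traj = make_angle_traj(rng.uniform(100, 170, (5, 15)))
        with pytest.raises(hk.ValidationError):
            hk.apck_curve(traj, traj, thresholds=[])


class TestMpjpe:
    def _kp(self, pos, fps=30.0):
        return hk.KeypointTrajectory(pos, fps=fps)

    def test_identity_scores_zero(self, skeleton, rng):
        kp = hk.forward_kinematics_trajectory(
            make_angle_traj(rng.uniform(100, 170, (10, 15))), skeleton)
        assert hk.mpjpe(kp, kp).mean == 0.0

    def test_three_four_five_displacement(self, skeleton):
        kp = hk.forward_kinematics_trajectory(
            make_angle_traj(np.full((1, 15), 160.0)), skeleton)
        pos = kp.positions.copy()
        pos[0, 3] += np.array([3.0, 4.0, 0.0])
        kp2 = self._kp(pos)
        d = np.linalg.norm(pos[0] - kp.positions[0], axis=1)
        assert d[3] == pytest.approx(5.0)
        res = hk.mpjpe(kp2, kp)
        assert res.mean == pytest.approx(5.0 / 21)

    def test_isotropic_noise_recovers_chi3_mean(self, rng):
        sigma = 2.0
        pos = rng.uniform(-50, 50, (5000, 21, 3))
        noisy = pos + rng.normal(0, sigma, pos.shape)
        res = hk.mpjpe(self._kp(noisy), self._kp(pos))
        assert res.n == 105000
        assert res.mean == pytest.approx(2 * sigma * HALF_NORMAL_MEAN,
                                         rel=0.02)

    def test_invariant_under_common_rigid_transform(self, rng):
        pos = rng.uniform(-50, 50, (20, 21, 3))
        noisy = pos + rng.normal(0, 2, pos.shape)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = np.array([10.0, -4.0, 2.0])
        r0 = hk.mpjpe(self._kp(noisy), self._kp(pos))
        r1 = hk.mpjpe(self._kp(noisy @ Q.T + shift),
                      self._kp(pos @ Q.T + shift))
        assert r0.mean == pytest.approx(r1.mean, abs=1e-9)

    def test_procrustes_alignment_removes_global_offset(self, rng):
        pos = rng.uniform(-50, 50, (10, 21, 3))
        shifted = pos + np.array([25.0, 0.0, 0.0])
        assert hk.mpjpe(self._kp(shifted), self._kp(pos)).mean \
            == pytest.approx(25.0)
        aligned = hk.mpjpe(self._kp(shifted), self._kp(pos),
                           alignment="procrustes")
        assert aligned.mean == pytest.approx(0.0, abs=1e-9)


class TestMpjave:
    def test_identity_and_constant_bias_score_zero(self, rng):
        a = rng.uniform(100, 170, (40, 15))
        gt = make_angle_traj(a)
        assert hk.mpjave(gt, gt).mean == 0.0
        biased = make_angle_traj(a + 7.0)
        assert hk.mpjave(biased, gt).mean == pytest.approx(0.0, abs=1e-9)

    def test_linear_drift_gives_30_dps(self):
        base = 100.0 + np.zeros(60)
        gt = single_joint_traj(base)
        pred = single_joint_traj(base + 1.0 * np.arange(60))
        res = hk.mpjave(pred, gt)
        assert res.mean == pytest.approx(30.0, abs=1e-9)
        assert res.std == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_frame_loop_oracle(self, rng):
        a = rng.uniform(100, 170, (25, 3))
        b = a + rng.normal(0, 2, a.shape)
        labs = (("index", "mcp"), ("index", "pip"), ("index", "dip"))
        gt, pred = make_angle_traj(a, joints=labs), make_angle_traj(b, joints=labs)
        diffs = []
        for j in range(3):
            for i in range(25):
                if i == 0:
                    vg = (a[1, j] - a[0, j]) * 30.0
                    vp = (b[1, j] - b[0, j]) * 30.0
                elif i == 24:
                    vg = (a[24, j] - a[23, j]) * 30.0
                    vp = (b[24, j] - b[23, j]) * 30.0
                else:
                    vg = (a[i + 1, j] - a[i - 1, j]) * 15.0
                    vp = (b[i + 1, j] - b[i - 1, j]) * 15.0
                diffs.append(abs(vp - vg))
        res = hk.mpjave(pred, gt)
        assert res.mean == pytest.approx(np.mean(diffs), abs=1e-9)
        assert res.std == pytest.approx(np.std(diffs, ddof=1), abs=1e-9)


class TestSparc:
    def _smooth(self, f=0.5, n=300, fps=30.0, amp=20.0):
        t = np.arange(n) / fps
        return 150.0 + amp * np.sin(2 * np.pi * f * t)

    def test_amplitude_scale_invariance(self):
        x = self._smooth()
        base = 150.0 + (x - 150.0)
        scaled = 150.0 + 3.0 * (x - 150.0)
        assert hk.sparc(base, 30.0) == pytest.approx(
            hk.sparc(scaled, 30.0), abs=1e-9)

    def test_high_frequency_ripple_strictly_decreases_sparc(self):
        t = np.arange(300) / 30.0
        smooth = self._smooth()
        rippled = smooth + 2.0 * np.sin(2 * np.pi * 5.0 * t)
        assert hk.sparc(rippled, 30.0) < hk.sparc(smooth, 30.0)

    def test_agrees_with_bruteforce_dft_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(60, 400))
            t = np.arange(n) / 30.0
            x = (150.0 + rng.uniform(5, 25) * np.sin(2 * np.pi * rng.uniform(0.2, 2.0) * t)
                 + rng.normal(0, 0.5, n))
            assert hk.sparc(x, 30.0) == pytest.approx(
                sparc_bruteforce(x, 30.0), abs=1e-6)

    def test_constant_series_returns_flagged_sentinel(self):
        assert math.isnan(hk.sparc(np.full(64, 150.0), 30.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(hk.ValidationError):
            hk.sparc(np.full(8, 150.0), 30.0)

    def test_angular_sparc_error_zero_and_symmetric(self, rng):
        t = np.arange(300) / 30.0
        a = np.column_stack([150.0 + 20 * np.sin(2 * np.pi * 0.5 * t + p)
                             for p in (0.0, 0.7, 1.4)])
        labs = (("middle", "mcp"), ("middle", "pip"), ("middle", "dip"))
        gt = make_angle_traj(a, joints=labs)
        pred = make_angle_traj(a + rng.normal(0, 1.0, a.shape), joints=labs)
        assert hk.angular_sparc_error(gt, gt).mean == 0.0
        r1 = hk.angular_sparc_error(pred, gt)
        r2 = hk.angular_sparc_error(gt, pred)
        assert r1.mean == pytest.approx(r2.mean, abs=1e-12)

    def test_angular_sparc_error_matches_oracle_on_rippled_motion(self):
        t = np.arange(300) / 30.0
        smooth = 150.0 + 20 * np.sin(2 * np.pi * 0.5 * t)
        rippled = smooth + 2.0 * np.sin(2 * np.pi * 5.0 * t)
        lab = (("middle", "mcp"),)
        gt = make_angle_traj(smooth[:, None], joints=lab)
        pred = make_angle_traj(rippled[:, None], joints=lab)
        expected = abs(sparc_bruteforce(rippled, 30.0)
                       - sparc_bruteforce(smooth, 30.0))
        assert hk.angular_sparc_error(pred, gt).mean == pytest.approx(
            expected, abs=1e-6)

    def test_degenerate_joint_is_excluded(self):
        t = np.arange(300) / 30.0
        labs = (("middle", "mcp"), ("middle", "pip"))
        a = np.column_stack([150.0 + 20 * np.sin(2 * np.pi * 0.5 * t),
                             np.full(300, 160.0)])  # second joint constant
        gt = make_angle_traj(a, joints=labs)
        pred = make_angle_traj(a + 0.5, joints=labs)
        res = hk.angular_sparc_error(pred, gt)
        assert res.n == 1


class TestLosses:
    def test_zero_at_ground_truth(self, rng):
        X = rng.normal(size=(21, 3))
        x2 = rng.normal(size=(21, 2))
        th, be = rng.normal(size=48), rng.normal(size=10)
        assert hk.training_loss(X, X, x2, x2, th, th, be, be) == 0.0
        assert hk.finetune_loss(X, X) == 0.0

    def test_default_weights(self):
        w = hk.LossWeights()
        assert (w.w3d, w.w2d, w.wmano) == (0.05, 0.01, 0.0005)

    @pytest.mark.parametrize("norm", ["l1", "l2"])
    def test_hand_built_two_joint_case(self, norm):
        X_gt = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        X = X_gt + np.array([[1.0, -2.0, 2.0], [0.0, 4.0, -2.0]])
        x2_gt = np.array([[5.0, 5.0], [8.0, 2.0]])
        x2 = x2_gt + np.array([[3.0, 0.0], [0.0, -3.0]])
        th_gt, th = np.zeros(4), np.array([1.0, -1.0, 2.0, 0.0])
        be_gt, be = np.zeros(2), np.array([0.5, -0.5])
        if norm == "l1":
            l3d = (1 + 2 + 2 + 0 + 4 + 2) / 6
            l2d = (3 + 0 + 0 + 3) / 4
            lmano = (1 + 1 + 2 + 0) / 4 + (0.5 + 0.5) / 2
        else:
            l3d = math.sqrt((1 + 4 + 4 + 0 + 16 + 4) / 6)
            l2d = math.sqrt((9 + 0 + 0 + 9) / 4)
            lmano = math.sqrt((1 + 1 + 4 + 0) / 4) + math.sqrt(0.25)
        expected = 0.05 * l3d + 0.01 * l2d + 0.0005 * lmano
        got = hk.training_loss(X, X_gt, x2, x2_gt, th, th_gt, be, be_gt,
                               norm=norm)
        assert got == pytest.approx(expected, abs=1e-12)
        assert hk.finetune_loss(X, X_gt, norm=norm) == pytest.approx(
            l3d, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(hk.ValidationError):
            hk.finetune_loss(np.zeros((2, 3)), np.zeros((3, 3)))

    def test_negative_weights_rejected(self):
        with pytest.raises(hk.ValidationError):
            hk.LossWeights(w3d=-0.1)


class TestAggregation:
    def _samples(self, triples):
        return pd.DataFrame(triples,
                            columns=["metric", "finger", "joint", "frame",
                                     "value"])

    def test_one_sample_per_class_pools_to_5(self):
        df = self._samples([("mpjae", "index", "mcp", 0, 9.0),
                            ("mpjae", "index", "pip", 0, 3.0),
                            ("mpjae", "index", "dip", 0, 3.0)])
        rep = hk.aggregate_report(df)
        assert rep.cells["mpjae"]["Overall"].mean == pytest.approx(5.0)
        assert rep.cells["mpjae"]["Overall"].n == 3

    def test_unequal_counts_match_pooled_bruteforce(self, rng):
        rows = []
        groups = {"mcp": rng.normal(9, 2, 50), "pip": rng.normal(3, 1, 20),
                  "dip": rng.normal(3, 1, 7)}
        for joint, vals in groups.items():
            rows += [("mpjae", "index", joint, i, float(v))
                     for i, v in enumerate(vals)]
        rep = hk.aggregate_report(self._samples(rows))
        m, s, n = pooled_mean_std(list(groups.values()))
        ov = rep.cells["mpjae"]["Overall"]
        assert ov.mean == pytest.approx(m, abs=1e-9)
        assert ov.std == pytest.approx(s, abs=1e-9)
        assert ov.n == n == sum(rep.cells["mpjae"][c].n
                                for c in ("MCP", "PIP", "DIP"))

    def test_wrist_and_tip_velocity_cells_are_na(self):
        rows = [("mpjave", "index", "mcp", 0, 10.0),
                ("mpjpe", "wrist", "wrist", 0, 20.0),
                ("mpjpe", "index", "tip", 0, 12.0),
                ("mpjpe", "index", "mcp", 0, 15.0)]
        rep = hk.aggregate_report(self._samples(rows))
        assert rep.cells["mpjave"]["Wrist"] is None
        assert rep.cells["mpjave"]["Tip"] is None
        assert rep.cells["mpjpe"]["Wrist"].mean == 20.0
        tsv = hk.report_to_tsv(rep)
        wrist_row = [l for l in tsv.splitlines() if l.startswith("Wrist")][0]
        assert "N/A" in wrist_row

    def test_empty_class_yields_na_not_error(self):
        rows = [("mpjae", "index", "mcp", 0, 5.0)]
        rep = hk.aggregate_report(self._samples(rows),
                                  classes=("MCP", "PIP"))
        assert rep.cells["mpjae"]["PIP"] is None
        assert rep.cells["mpjae"]["Overall"].n == 1
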