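"""The four recovery models and the reference-triplet iteration."""

import numpy as np
import pytest

from mocapfill import (
    Gap,
    GlobalLinearRegression,
    LocalGRNN,
    LocalInterpolation,
    LocalPolynomialRegression,
    MotionSequence,
    build_local_frame,
    find_gaps,
    from_local,
    make_models,
    rank_references,
    recover_candidates,
)
from conftest import mask_gap


def _seq(positions, fps=100.0):
    positions = np.asarray(positions, float)
    return MotionSequence(positions=positions,
                          mask=np.all(np.isfinite(positions), axis=2), fps=fps)


def _rigid_cloud_seq(n=200, extra=0.0, seed=0, n_free=1):
    """A rigid 5-marker cloud under random smooth rigid motion.

    Marker 0 is rigid in the cloud, so its local coordinates in any triad
    of the others are constant; ``extra`` adds a wobble to marker 0 only.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    t = np.linspace(0, 4 * np.pi, n)
    angles = np.column_stack([
        0.8 * np.sin(t + rng.uniform(0, 6)),
        0.6 * np.sin(0.7 * t + rng.uniform(0, 6)),
        0.5 * np.sin(1.3 * t + rng.uniform(0, 6)),
    ])
    R = Rotation.from_euler("xyz", angles)
    path = np.column_stack([300 * np.sin(0.3 * t), 200 * np.cos(0.2 * t), 50 * t])
    local = np.array([
        [50.0, 20.0, 10.0],      # target
        [0.0, 0.0, 0.0],
        [100.0, 0.0, 0.0],
        [0.0, 80.0, 0.0],
        [30.0, 30.0, 90.0],
    ])
    pos = np.stack([path + R.apply(np.tile(p, (n, 1))) for p in local], axis=1)
    if extra:
        pos[:, 0, :] += extra * np.column_stack(
            [np.sin(2 * t), np.cos(3 * t), np.sin(5 * t)])
    return _seq(pos)


class TestGLR:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(1)
        n = 120
        p1 = np.cumsum(rng.normal(0, 3, (n, 3)), axis=0)
        p2 = np.cumsum(rng.normal(0, 3, (n, 3)), axis=0) + 200
        target = 0.4 * p1 - 0.7 * p2 + np.array([10.0, -5.0, 3.0])
        seq = _seq(np.stack([target, p1, p2], axis=1))
        seq = mask_gap(seq, 0, 40, 70)
        gap = find_gaps(seq)[0]
        ranking = rank_references(seq, 0)
        cand = GlobalLinearRegression(theta=1e9).recover_gap(seq, gap, ranking)
        np.testing.assert_allclose(cand.interior_values, target[40:70], atol=1e-6)

    def test_constant_target_reproduced_by_intercept(self):
        rng = np.random.default_rng(2)
        n = 80
        p1 = np.cumsum(rng.normal(0, 3, (n, 3)), axis=0)
        target = np.tile([50.0, 60.0, 70.0], (n, 1))
        seq = mask_gap(_seq(np.stack([target, p1], axis=1)), 0, 30, 50)
        gap = find_gaps(seq)[0]
        cand = GlobalLinearRegression(theta=1e9).recover_gap(
            seq, gap, rank_references(seq, 0))
        np.testing.assert_allclose(cand.interior_values, target[30:50], atol=1e-6)

    def test_coefficients_match_normal_equations_oracle(self):
        seq = _rigid_cloud_seq(extra=5.0, seed=3)
        seq.positions += np.random.default_rng(4).normal(0, 1.0, seq.positions.shape)
        seq = _seq(seq.positions)
        seq = mask_gap(seq, 0, 80, 120)
        gap = find_gaps(seq)[0]
        ranking = rank_references(seq, 0)
        cand = GlobalLinearRegression(theta=1e9).recover_gap(seq, gap, ranking)
        # oracle: (X^T X)^{-1} X^T y on the same training rows
        rows = np.r_[np.arange(0, 80), np.arange(120, seq.n_frames)]
        X = np.column_stack([seq.positions[rows][:, [1, 2, 3, 4], :].reshape(rows.size, -1),
                             np.ones(rows.size)])
        pred_frames = np.arange(79, 121)
        Xp = np.column_stack([seq.positions[pred_frames][:, [1, 2, 3, 4], :]
                              .reshape(pred_frames.size, -1), np.ones(pred_frames.size)])
        for axis in range(3):
            y = seq.positions[rows, 0, axis]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(cand.values[:, axis], Xp @ beta, rtol=1e-8,
                                       atol=1e-8)

    def test_inapplicable_when_no_gap_complete_marker(self):
        seq = _rigid_cloud_seq(seed=5)
        seq = mask_gap(seq, 0, 50, 90)
        for j in range(1, 5):  # every reference broken inside the gap
            seq = mask_gap(seq, j, 60, 62)
        gap = [g for g in find_gaps(seq) if g.marker == 0][0]
        cand = GlobalLinearRegression().recover_gap(seq, gap, rank_references(seq, 0))
        assert cand is None


class TestLocalInterpolation:
    def test_rigid_marker_exact_recovery(self):
        seq = mask_gap(_rigid_cloud_seq(), 0, 60, 140)
        gap = find_gaps(seq)[0]
        cand = LocalInterpolation().recover_gap(seq, gap, rank_references(seq, 0))
        truth = _rigid_cloud_seq().positions[60:140, 0, :]
        np.testing.assert_allclose(cand.interior_values, truth, atol=1e-6)
        assert cand.skip_ramp

    def test_constant_local_velocity_exact(self):
        base = _rigid_cloud_seq(n=100)
        pos = base.positions.copy()
        # target drifts linearly in the triad frame of markers 1,2,3
        f = build_local_frame(pos[:, 1], pos[:, 2], pos[:, 3])
        drift = np.linspace(0, 30, 100)[:, None] * np.array([[1.0, 0.5, -0.25]])
        pos[:, 0, :] = from_local(drift, f)
        seq = mask_gap(_seq(pos), 0, 30, 70)
        gap = find_gaps(seq)[0]
        cand = LocalInterpolation().recover_gap(seq, gap, rank_references(seq, 0))
        np.testing.assert_allclose(cand.interior_values, pos[30:70, 0, :], atol=1e-6)

    def test_reference_missing_mid_gap_triggers_triplet_iteration(self):
        seq = mask_gap(_rigid_cloud_seq(), 0, 60, 140)
        seq = mask_gap(seq, rank_references(seq, 0).markers[2], 90, 110)
        gap = [g for g in find_gaps(seq) if g.marker == 0][0]
        ranking = rank_references(seq, 0)
        cand = LocalInterpolation().recover_gap(seq, gap, ranking)
        assert cand.complete
        assert len(cand.triplets_used) >= 2
        truth = _rigid_cloud_seq().positions[60:140, 0, :]
        np.testing.assert_allclose(cand.interior_values, truth, atol=1e-6)

    def test_matches_two_independent_projections(self):
        """Frames recoverable with the best triad match a single-triad run;
        the residual matches a run forced onto the substitute triad."""
        seq = mask_gap(_rigid_cloud_seq(), 0, 60, 140)
        ranking = rank_references(seq, 0)
        third = ranking.markers[2]
        seq2 = mask_gap(seq, third, 90, 110)
        gap = [g for g in find_gaps(seq2) if g.marker == 0][0]
        cand = LocalInterpolation().recover_gap(seq2, gap, rank_references(seq2, 0))
        full = LocalInterpolation().recover_gap(seq, find_gaps(seq)[0], ranking)
        ok = np.array([n for n in range(61, 140) if seq2.mask[n, third]])
        a = cand.values[np.searchsorted(cand.frames, ok)]
        b = full.values[np.searchsorted(full.frames, ok)]
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestLPR:
    def test_constant_local_position_exact(self):
        seq = mask_gap(_rigid_cloud_seq(), 0, 60, 140)
        gap = find_gaps(seq)[0]
        cand = LocalPolynomialRegression().recover_gap(seq, gap, rank_references(seq, 0))
        truth = _rigid_cloud_seq().positions[60:140, 0, :]
        np.testing.assert_allclose(cand.interior_values, truth, atol=1e-6)

    def test_pure_quadratic_relation_recovered(self):
        """Target local x equals the square of a varying triad feature."""
        from mocapfill import ReferenceRanking

        n = 150
        p1 = np.zeros((n, 3))
        x2 = 100 + 20 * np.sin(np.linspace(0, 8 * np.pi, n))
        p2 = np.column_stack([x2, np.zeros(n), np.zeros(n)])
        p3 = np.tile([50.0, 0.0, 80.0], (n, 1))
        tgt = np.column_stack([1e-3 * x2 ** 2, 0.05 * x2, np.full(n, 30.0)])
        seq = mask_gap(_seq(np.stack([tgt, p1, p2, p3], axis=1)), 0, 50, 100)
        gap = find_gaps(seq)[0]
        ranking = ReferenceRanking(target=0, markers=(1, 2, 3),
                                   sigmas=(1.0, 2.0, 3.0), overlaps=(n, n, n))
        cand = LocalPolynomialRegression().recover_gap(seq, gap, ranking)
        np.testing.assert_allclose(cand.interior_values, tgt[50:100], atol=1e-5)

    def test_matches_ten_column_design_oracle(self):
        seq = _rigid_cloud_seq(extra=8.0, seed=7)
        seq = mask_gap(seq, 0, 80, 120)
        gap = find_gaps(seq)[0]
        ranking = rank_references(seq, 0)
        cand = LocalPolynomialRegression().recover_gap(seq, gap, ranking)
        # oracle: explicit local projection + quadratic design on the same rows
        from mocapfill import quadratic_expansion, to_local, triad_features

        j1, j2, j3 = ranking.markers[:3]
        f = build_local_frame(seq.positions[:, j1], seq.positions[:, j2],
                              seq.positions[:, j3])
        rows = np.r_[np.arange(0, 80), np.arange(120, seq.n_frames)]
        Xq = quadratic_expansion(triad_features(seq.positions[:, j2],
                                                seq.positions[:, j3], f))
        X = np.column_stack([Xq[rows], np.ones(rows.size)])
        y = to_local(seq.positions[:, 0], f)[rows]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        pred_frames = cand.frames
        Xp = np.column_stack([Xq[pred_frames], np.ones(pred_frames.size)])
        oracle = from_local(Xp @ beta, _sub(f, pred_frames))
        np.testing.assert_allclose(cand.values, oracle, rtol=1e-8, atol=1e-8)


def _sub(frame, idx):
    from mocapfill.models import _frame_subset

    return _frame_subset(frame, idx)


class TestLGRNN:
    def test_single_training_frame_returns_its_target(self):
        # every frame but the first is missing: the kernel mean over one
        # training sample is that sample's local coordinates, for any query
        from mocapfill import ReferenceRanking

        seq = mask_gap(_rigid_cloud_seq(n=60), 0, 1, 60)
        gap = find_gaps(seq)[0]
        ranking = ReferenceRanking(target=0, markers=(1, 2, 3, 4),
                                   sigmas=(1.0, 2.0, 3.0, 4.0), overlaps=(1,) * 4)
        cand = LocalGRNN().recover_gap(seq, gap, ranking)
        assert cand is not None and cand.complete
        truth = _rigid_cloud_seq(n=60).positions[1:60, 0, :]
        np.testing.assert_allclose(cand.interior_values, truth, atol=1e-6)

    def test_equidistant_query_averages_training_targets(self):
        """A query midway between two training feature values gets the mean
        of their targets (Gaussian weights are equal by symmetry)."""
        from mocapfill import ReferenceRanking

        n = 5
        x2 = np.array([90.0, 110.0, 100.0, 90.0, 110.0])
        p1 = np.zeros((n, 3))
        p2 = np.column_stack([x2, np.zeros(n), np.zeros(n)])
        p3 = np.tile([50.0, 0.0, 80.0], (n, 1))
        tgt = np.column_stack([x2 / 2, np.full(n, 40.0), np.full(n, 50.0)])
        seq = mask_gap(_seq(np.stack([tgt, p1, p2, p3], axis=1)), 0, 2, 3)
        gap = find_gaps(seq)[0]
        ranking = ReferenceRanking(target=0, markers=(1, 2, 3),
                                   sigmas=(1.0, 2.0, 3.0), overlaps=(n, n, n))
        cand = LocalGRNN(s=0.5).recover_gap(seq, gap, ranking)
        # training targets: two at T(90), two at T(110); query x2=100 is the
        # standardized midpoint, so the prediction is their mean, T(100)
        np.testing.assert_allclose(cand.interior_values[0], [50.0, 40.0, 50.0],
                                   atol=1e-9)

    def test_matches_double_loop_oracle(self):
        seq = _rigid_cloud_seq(n=120, extra=10.0, seed=8)
        seq = mask_gap(seq, 0, 50, 70)
        gap = find_gaps(seq)[0]
        ranking = rank_references(seq, 0)
        s = 0.3
        cand = LocalGRNN(s=s).recover_gap(seq, gap, ranking)
        from mocapfill import to_local, triad_features

        j1, j2, j3 = ranking.markers[:3]
        f = build_local_frame(seq.positions[:, j1], seq.positions[:, j2],
                              seq.positions[:, j3])
        rows = np.r_[np.arange(0, 50), np.arange(70, seq.n_frames)]
        feats = triad_features(seq.positions[:, j2], seq.positions[:, j3], f)
        mu, sd = feats[rows].mean(0), feats[rows].std(0)
        Xt = (feats[rows] - mu) / sd
        y = to_local(seq.positions[:, 0], f)[rows]
        oracle_local = []
        for n in cand.frames:
            xq = (feats[n] - mu) / sd
            num = np.zeros(3)
            den = 0.0
            for k in range(rows.size):
                w = np.exp(-np.sum((xq - Xt[k]) ** 2) / (2 * s ** 2))
                num += w * y[k]
                den += w
            oracle_local.append(num / den)
        oracle = from_local(np.array(oracle_local), _sub(f, cand.frames))
        np.testing.assert_allclose(cand.values, oracle, rtol=1e-10, atol=1e-10)


class TestModelContracts:
    def test_candidate_count_and_untouched_observations(self, short_seq):
        seq = mask_gap(short_seq, 20, 300, 420)
        gaps = find_gaps(seq)
        rankings = {20: rank_references(seq, 20)}
        cands = recover_candidates(make_models(), seq, gaps, rankings)
        assert len(cands[gaps[0]]) == 4
        for c in cands[gaps[0]]:
            assert c.frames.min() >= gaps[0].n1
            assert c.frames.max() <= gaps[0].n2

    def test_glr_inapplicable_leaves_three_candidates(self):
        seq = mask_gap(_rigid_cloud_seq(), 0, 50, 90)
        for j in range(1, 5):
            seq = mask_gap(seq, j, 60 + j, 62 + j)  # every ref broken in-gap
        gaps = [g for g in find_gaps(seq) if g.marker == 0]
        rankings = {0: rank_references(seq, 0)}
        cands = recover_candidates(make_models(), seq, gaps, rankings)
        names = {c.model for c in cands[gaps[0]]}
        assert "glr" not in names
        assert {"li", "lpr", "lgrnn"} <= names

    def test_rigid_marker_all_local_models_submillimetre(self):
        seq = mask_gap(_rigid_cloud_seq(), 0, 60, 140)
        gap = find_gaps(seq)[0]
        ranking = rank_references(seq, 0)
        truth = _rigid_cloud_seq().positions[60:140, 0, :]
        for model in make_models(("li", "lpr", "lgrnn")):
            cand = model.recover_gap(seq, gap, ranking)
            err = np.linalg.norm(cand.interior_values - truth, axis=1).max()
            assert err < 1e-3, model.name

    def test_glr_translation_equivariance(self):
        seq = mask_gap(_rigid_cloud_seq(extra=5.0, seed=9), 0, 60, 100)
        gap = find_gaps(seq)[0]
        ranking = rank_references(seq, 0)
        c0 = GlobalLinearRegression(theta=1e9).recover_gap(seq, gap, ranking)
        shifted = _seq(seq.positions + np.array([1000.0, -500.0, 250.0]))
        c1 = GlobalLinearRegression(theta=1e9).recover_gap(
            shifted, gap, rank_references(shifted, 0))
        np.testing.assert_allclose(c1.values - c0.values,
                                   np.tile([1000.0, -500.0, 250.0],
                                           (c0.frames.size, 1)), atol=1e-6)
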