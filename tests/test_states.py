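"""State labelling, meta-states, heat maps and decoding metrics."""

import numpy as np
import pytest

from telemeg import states as st
from telemeg.hmm import HmmParams, StateDecoding
from telemeg.telemetry import SpeedMatrix


def decoding_from_path(path, k):
    """Wrap an explicit Viterbi path in a StateDecoding (posteriors one-hot)."""
    path = np.asarray(path, dtype=int)
    post = np.eye(k)[path]
    d = path.max() + 1
    params = HmmParams(np.full(k, 1 / k), np.full((k, k), 1 / k),
                       np.zeros((k, 1)), np.stack([np.eye(1)] * k))
    return StateDecoding(post, path, 0.0, params)


class TestJaccard:
    def test_identity_disjoint_and_partial(self):
        assert st.jaccard([1, 1, 0], [1, 1, 0]) == 1.0
        assert st.jaccard([1, 0, 0], [0, 1, 1]) == 0.0
        assert st.jaccard([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_both_empty_is_zero(self):
        assert st.jaccard([0, 0], [0, 0]) == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            j = st.jaccard(a, b)
            assert j == st.jaccard(b, a)
            assert 0.0 <= j <= 1.0
            if j == 1.0:
                assert a.any() and (a == b).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            st.jaccard([1, 0], [1, 0, 1])


class TestLabelStates:
    def test_perfect_copy_labels_and_rest(self):
        """4 conditions copied into 4 of 15 states; 11 states rest."""
        rng = np.random.default_rng(1)
        T = 600
        box = np.zeros((T, 4), dtype=int)
        for c in range(4):
            box[c * 120:(c * 120) + 60, c] = 1
        path = np.full(T, 4 + rng.integers(0, 11, size=T))  # rest states 4..14
        for c in range(4):
            path[box[:, c] == 1] = c
        dec = decoding_from_path(path, 15)
        tl = st.ConditionTimeline([f"c{c}" for c in range(4)], box, 30.0)
        lm = st.label_states(dec, tl)
        assert lm.mapping == {f"c{c}": {c} for c in range(4)}
        assert lm.rest_states == set(range(4, 15))
        for c in range(4):
            assert lm.jaccard_scores[c, c] == 1.0

    def test_greater_overlap_wins(self):
        T = 100
        box = np.zeros((T, 1), dtype=int)
        box[:50, 0] = 1
        path = np.zeros(T, dtype=int)
        path[:35] = 0      # overlap 35 frames of the condition
        path[35:] = 1      # overlap 15 frames + 50 outside
        dec = decoding_from_path(path, 2)
        lm = st.label_states(dec, st.ConditionTimeline(["m"], box, 30.0))
        assert lm.mapping["m"] == {0}

    def test_duplicate_winner_resolved_greedily(self):
        T = 90
        box = np.zeros((T, 2), dtype=int)
        box[:30, 0] = 1
        box[30:60, 1] = 1
        path = np.zeros(T, dtype=int)
        path[55:] = 1
        # state 0 overlaps condition a fully (J=1/2) and b mostly
        dec = decoding_from_path(path, 2)
        lm = st.label_states(dec, st.ConditionTimeline(["a", "b"], box, 30.0))
        assert lm.mapping["a"] == {0} and lm.mapping["b"] == {1}

    def test_frame_count_mismatch(self):
        dec = decoding_from_path(np.zeros(10, dtype=int), 2)
        tl = st.ConditionTimeline(["a"], np.zeros((12, 1), dtype=int), 30.0)
        with pytest.raises(ValueError, match="frame"):
            st.label_states(dec, tl)


class TestPoolMetaState:
    def test_singleton_equals_binarize(self):
        dec = decoding_from_path([0, 1, 2, 1, 0], 3)
        np.testing.assert_array_equal(st.pool_meta_state(dec, {1}),
                                      [0, 1, 0, 1, 0])

    def test_all_states_gives_ones_and_disjoint_sum(self):
        dec = decoding_from_path([0, 1, 2, 1, 0], 3)
        np.testing.assert_array_equal(st.pool_meta_state(dec, {0, 1, 2}), 1)
        both = st.pool_meta_state(dec, {0, 2})
        np.testing.assert_array_equal(
            both, st.pool_meta_state(dec, {0}) | st.pool_meta_state(dec, {2}))

    def test_empty_set_errors(self):
        dec = decoding_from_path([0, 1], 2)
        with pytest.raises(ValueError, match="empty"):
            st.pool_meta_state(dec, set())


class TestStateHeatmap:
    def test_group_mean_difference(self):
        T = 200
        path = np.zeros(T, dtype=int)
        path[50:100] = 1
        speeds = np.zeros((T, 3))
        speeds[path == 1, 0] = 2.0       # kp0 moves at +2 during the state
        speeds[:, 2] = 1.3               # constant kp2
        hm = st.state_heatmap(path, speeds)
        assert hm.coefficients[0] == pytest.approx(2.0)
        assert hm.coefficients[1] == pytest.approx(0.0)
        assert hm.coefficients[2] == pytest.approx(0.0)

    def test_independent_keypoint_near_zero(self):
        rng = np.random.default_rng(5)
        T = 5000
        path = (rng.random(T) < 0.3).astype(int)
        speeds = rng.normal(size=(T, 1))
        hm = st.state_heatmap(path, speeds)
        # standard error of a two-group mean difference
        se = np.sqrt(1 / (path == 1).sum() + 1 / (path == 0).sum())
        assert abs(hm.coefficients[0]) < 3 * se

    def test_degenerate_state_errors(self):
        with pytest.raises(ValueError, match="never"):
            st.state_heatmap(np.ones(10, dtype=int), np.zeros((10, 2)))


class TestFractionalOccupancy:
    def test_single_and_identical_sessions(self):
        p = np.array([[0, 1, 1, 0]])
        fo = st.fractional_occupancy([p])
        np.testing.assert_array_equal(fo[:, 0], p[0])
        fo3 = st.fractional_occupancy([np.vstack([p, p, p])])
        np.testing.assert_array_equal(fo3[:, 0], p[0])

    def test_bounded_and_subpartition(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=(5, 40))
        b = (1 - a) * rng.integers(0, 2, size=(5, 40))   # disjoint per session
        fo, names = st.fractional_occupancy({"a": a, "b": b})
        assert names == ["a", "b"]
        assert (fo >= 0).all() and (fo <= 1).all()
        assert (fo.sum(axis=1) <= 1 + 1e-12).all()


class TestConfusionAndF1:
    def test_perfect_prediction(self):
        truth = np.array([0, 0, 1, 1, 2])
        rep = st.confusion_and_f1(truth, truth, ["a", "b", "c"])
        assert rep.f1_macro == 1.0
        assert np.trace(rep.confusion) == 5

    def test_complement_prediction_zero(self):
        truth = np.array([0, 0, 1, 1])
        rep = st.confusion_and_f1(truth, 1 - truth, ["a", "b"])
        assert rep.f1_macro == 0.0

    def test_hand_counted_dice(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        rep = st.confusion_and_f1(truth, pred, ["A", "B"])
        assert rep.per_class_dice[0] == pytest.approx(2 / 3)
        assert rep.per_class_dice[1] == pytest.approx(4 / 5)
        assert rep.f1_macro == pytest.approx(11 / 15)

    def test_confusion_total_and_class_order_invariance(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 3, size=100)
        pred = rng.integers(0, 3, size=100)
        rep = st.confusion_and_f1(truth, pred, ["a", "b", "c"])
        assert rep.confusion.sum() == 100
        perm = np.array([2, 0, 1])
        rep_p = st.confusion_and_f1(perm[truth], perm[pred], ["c", "a", "b"])
        assert rep_p.f1_macro == pytest.approx(rep.f1_macro)

    def test_absent_class_excluded_with_warning(self):
        truth = np.array([0, 0, 0])
        pred = np.array([0, 1, 0])
        with pytest.warns(UserWarning, match="absent"):
            rep = st.confusion_and_f1(truth, pred, ["a", "b"])
        assert np.isnan(rep.per_class_dice[1])


class TestRocAuc:
    def test_perfect_and_reversed(self):
        truth = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        aucs, macro = st.roc_auc(scores, truth)
        np.testing.assert_allclose(aucs, 1.0)
        aucs_r, _ = st.roc_auc(scores[:, ::-1], truth)
        np.testing.assert_allclose(aucs_r, 0.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(0, 2, size=10000)
        scores = rng.random((10000, 2))
        _, macro = st.roc_auc(scores, truth)
        assert abs(macro - 0.5) < 0.03

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        truth = rng.integers(0, 2, size=500)
        s = rng.random((500, 2))
        a1, _ = st.roc_auc(s, truth)
        a2, _ = st.roc_auc(np.exp(3 * s), truth)
        np.testing.assert_allclose(a1, a2)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        truth = rng.integers(0, 2, size=300)
        s = rng.random(300)
        s[truth == 1] += 0.3
        ours, _ = st.roc_auc(np.column_stack([1 - s, s]), truth)
        assert ours[1] == pytest.approx(roc_auc_score(truth, s))

    def test_single_class_excluded(self):
        with pytest.warns(UserWarning, match="no positives"):
            aucs, _ = st.roc_auc(np.random.rand(10, 2), np.zeros(10, dtype=int))
        assert np.isnan(aucs[1])


class TestPermutationNull:
    def test_perfect_alignment_floor_p(self):
        truth = np.zeros(1000, dtype=int)
        truth[100:200] = 1
        p = st.permutation_null(st.jaccard, truth, truth.copy(),
                                n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_p_bounded(self):
        rng = np.random.default_rng(12)
        truth = rng.integers(0, 2, size=300)
        path = rng.integers(0, 2, size=300)
        p = st.permutation_null(st.jaccard, truth, path, n_perm=99, seed=1)
        assert 0 < p <= 1

    def test_null_calibration_uniform(self):
        """Independent decoding: p-values roughly uniform over seeds."""
        from scipy.ndimage import gaussian_filter1d
        rng = np.random.default_rng(13)
        truth = np.zeros(400)
        truth[120:200] = 1
        overlap = lambda t, x: float(t @ x)
        ps = []
        for rep in range(60):
            path = gaussian_filter1d(rng.normal(size=400), 5.0)
            ps.append(st.permutation_null(overlap, truth, path,
                                          n_perm=99, seed=rep))
        ps = np.asarray(ps)
        # mean of a uniform sample of 60 p-values: CI ~ 0.5 +- 3*0.29/sqrt(60)
        assert abs(ps.mean() - 0.5) < 0.12
        assert (ps < 0.2).mean() < 0.45 and (ps > 0.8).mean() < 0.45

    def test_too_few_permutations(self):
        with pytest.raises(ValueError, match="99"):
            st.permutation_null(st.jaccard, np.ones(10), np.ones(10), n_perm=50)


class TestMovementDurations:
    def test_recovers_run_lengths(self):
        fr = 10.0
        path = np.zeros(300, dtype=int)
        path[20:70] = 1     # 5 s run at trial onset 2 s
        path[150:210] = 1   # 6 s run at trial onset 15 s
        durs = st.movement_durations(path, [2.0, 15.0], fr)
        np.testing.assert_allclose(durs, [5.0, 6.0])

    def test_ignores_spurious_runs(self):
        fr = 10.0
        path = np.zeros(300, dtype=int)
        path[20:60] = 1
        path[250:260] = 1   # spurious, no trial nearby
        durs = st.movement_durations(path, [2.0], fr)
        np.testing.assert_allclose(durs, [4.0])


class TestSplitHalfCV:
    def make_sessions(self, rng, n_sessions=2, trials=4):
        from telemeg import synth, telemetry
        truth = synth.GroundTruth(n_trials_per_block=trials, n_blocks=1)
        sessions, timelines = [], []
        for s in range(n_sessions):
            sess = synth.gen_block_telemetry(truth, seed=int(rng.integers(1e6)))
            sp = telemetry.znormalize(telemetry.to_speed(sess.series))
            sessions.append(sp)
            timelines.append(sess.movement)
        return sessions, timelines

    def test_heldout_performance_close_to_train(self):
        rng = np.random.default_rng(21)
        sessions, timelines = self.make_sessions(rng)
        train, test = st.split_half_cv(sessions, timelines, k=8, seed=0,
                                       n_restarts=2, max_iter=60)
        assert train.f1_macro > 0.8
        assert abs(train.f1_macro - test.f1_macro) < 0.1

    def test_noise_speeds_near_chance(self):
        rng = np.random.default_rng(22)
        sessions, timelines = self.make_sessions(rng)
        noise = [SpeedMatrix(rng.normal(size=s.values.shape), 30.0,
                             normalised=True) for s in sessions]
        train, test = st.split_half_cv(noise, timelines, k=8, seed=0,
                                       n_restarts=1, max_iter=30)
        # 5 classes; heavily imbalanced truth -> chance macro F1 well below 0.5
        assert test.f1_macro < 0.45

    def test_single_session_errors(self):
        rng = np.random.default_rng(23)
        sessions, timelines = self.make_sessions(rng, n_sessions=2)
        with pytest.raises(ValueError, match="2 sessions"):
            st.split_half_cv(sessions[:1], timelines[:1], k=4)


class TestEventsRoundTrip:
    def test_timeline_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(30)
        box = np.zeros((200, 2), dtype=int)
        box[10:50, 0] = 1
        box[100:140, 1] = 1
        tl = st.ConditionTimeline(["arm", "leg"], box, 20.0)
        p = tmp_path / "events.tsv"
        tl.to_events(p)
        back = st.ConditionTimeline.from_events(p, 20.0, 200)
        np.testing.assert_array_equal(back.boxcars, tl.boxcars)
        assert back.conditions == tl.conditions
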