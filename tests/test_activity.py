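"""Activity-count discretization, transition matrices and filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locoage.activity import (
    ActivityTrack,
    BIN_EDGES,
    MINUTES_PER_DAY,
    N_STATES,
    TransitionMatrixFeaturizer,
    activity_covariates,
    describe_track,
    discretize_counts,
    filter_track,
    log_scale_descriptor,
    transition_matrix,
    valid_day_mask,
)


def make_track(counts, sid="T0"):
    return ActivityTrack(subject_id=sid, counts=np.asarray(counts))


class TestDiscretize:
    @pytest.mark.parametrize("count,state", [
        (0, 0),                 # 0 < e - 1
        (1, 0),
        (2, 1),                 # e - 1 <= 2 < e^2 - 1
        (6, 1),
        (7, 2),
        (1095, 6),              # just below e^7 - 1
        (1096, 7),              # 1096 >= e^7 - 1
        (100000, 7),
    ])
    def test_bin_assignment(self, count, state):
        assert discretize_counts([count])[0] == state

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5000, size=2000)
        states = discretize_counts(counts)
        for a, s in zip(counts, states):
            expected = sum(a >= b for b in BIN_EDGES)
            assert s == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            discretize_counts([-1])

    def test_efold_scaling_shifts_states_up_one(self):
        # counts well inside a bin move up exactly one state when scaled by e
        inner = np.array([3, 10, 25, 70, 190, 520])   # states 1..6 interiors
        s0 = discretize_counts(inner)
        s1 = discretize_counts(np.e * inner)
        assert np.array_equal(s1, s0 + 1)


class TestTransitionMatrix:
    def test_hand_counted_sequence(self):
        tm = transition_matrix(np.array([0, 0, 1, 0]))
        expected = np.zeros((8, 8))
        expected[0, 0] = 0.5   # 0->0 once of two exits from 0
        expected[1, 0] = 0.5   # 0->1
        expected[0, 1] = 1.0   # 1->0
        assert np.allclose(tm, expected)

    def test_constant_sequence_is_identity_column(self):
        tm = transition_matrix(np.array([3, 3, 3, 3]))
        assert tm[3, 3] == 1.0
        assert tm.sum() == 1.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 7), min_size=2, max_size=300))
    def test_visited_columns_stochastic(self, seq):
        seq = np.array(seq)
        tm = transition_matrix(seq)
        # brute-force transition counting oracle
        counts = np.zeros((8, 8))
        for a, b in zip(seq[:-1], seq[1:]):
            counts[b, a] += 1
        visited = counts.sum(axis=0) > 0
        assert np.allclose(tm[:, visited].sum(axis=0), 1.0)
        assert np.allclose(tm[:, ~visited], 0.0)
        out = counts.sum(axis=0)
        assert np.allclose(tm[:, visited],
                           counts[:, visited] / out[visited])

    def test_excluded_day_junctions_not_counted(self):
        # three days: valid, excluded, valid
        day = np.ones(MINUTES_PER_DAY, dtype=int)
        states = np.concatenate([day * 1, day * 5, day * 2])
        tm = transition_matrix(states, day_mask=[True, False, True])
        # no transition 1->5 nor 5->2; state 5 never a valid source
        assert tm[5, 1] == 0
        assert tm[2, 5] == 0
        assert np.all(tm[:, 5] == 0)
        # within-day self transitions survive
        assert tm[1, 1] == 1.0
        assert tm[2, 2] == 1.0

    def test_permuting_identical_days_leaves_tm_unchanged(self):
        rng = np.random.default_rng(3)
        day = rng.integers(0, 8, MINUTES_PER_DAY)
        a = np.concatenate([day, day])
        tm1 = transition_matrix(a)
        tm2 = transition_matrix(np.concatenate([day, day]))  # swapped = same
        assert np.array_equal(tm1, tm2)

    def test_no_valid_transitions_errors(self):
        states = np.zeros(2 * MINUTES_PER_DAY, dtype=int)
        with pytest.raises(ValueError):
            transition_matrix(states, day_mask=[False, False])


class TestLogScaleDescriptor:
    def test_spot_values(self):
        tm = np.zeros((8, 8))
        tm[0, 0] = 1.0
        tm[1, 0] = 0.0
        tm[2, 3] = 0.5
        d = log_scale_descriptor(tm)
        assert d.shape == (64,)
        assert d[0] == 0.0                              # ln 1
        assert np.isclose(d[8], np.log(1e-3))           # imputed zero
        assert np.isclose(d[2 * 8 + 3], np.log(0.5))
        assert np.all(d >= np.log(1e-3))

    def test_row_major_flattening(self):
        tm = np.zeros((8, 8))
        tm[1, 2] = 0.25
        d = log_scale_descriptor(tm)
        assert np.isclose(d[1 * 8 + 2], np.log(0.25))

    def test_out_of_range_rejected(self):
        tm = np.zeros((8, 8))
        tm[0, 0] = 1.5
        with pytest.raises(ValueError):
            log_scale_descriptor(tm)


class TestFilter:
    def test_low_constant_count_fails_mean_rule(self):
        rep = filter_track(make_track(np.full(7 * MINUTES_PER_DAY, 40)),
                           age=30)
        assert not rep.passed
        assert rep.reasons == ["mean_count<50"]

    def test_200_active_minutes_is_enough(self):
        # 200 minutes at count 10 per day; rest high enough to lift the mean
        day = np.zeros(MINUTES_PER_DAY, dtype=int)
        day[:200] = 10
        day[200:500] = 300     # keeps overall mean >= 50
        track = make_track(np.tile(day, 7))
        rep = filter_track(track, age=30)
        assert rep.n_valid_days == 7
        assert rep.passed

    def test_three_valid_days_fail(self):
        active = np.zeros(MINUTES_PER_DAY, dtype=int)
        active[:400] = 200
        quiet = np.zeros(MINUTES_PER_DAY, dtype=int)
        track = make_track(np.concatenate([np.tile(active, 3),
                                           np.tile(quiet, 4)]))
        rep = filter_track(track, age=30)
        assert rep.n_valid_days == 3
        assert "valid_days<4" in rep.reasons

    def test_age_cap(self):
        day = np.full(MINUTES_PER_DAY, 100)
        rep = filter_track(make_track(np.tile(day, 7)), age=85)
        assert rep.reasons == ["age>=85"]

    def test_passed_iff_no_reasons(self):
        day = np.full(MINUTES_PER_DAY, 100)
        rep = filter_track(make_track(np.tile(day, 7)), age=30)
        assert rep.passed and rep.reasons == []

    def test_partial_days_rejected(self):
        with pytest.raises(ValueError):
            make_track(np.zeros(100))


class TestActivityCovariates:
    def test_constant_counts(self):
        track = make_track(np.full(7 * MINUTES_PER_DAY, 100))
        mean_daily, neg_log = activity_covariates(track)
        assert mean_daily == 100 * MINUTES_PER_DAY == 144000
        assert np.isclose(neg_log, -np.log(144000))

    def test_neg_log_of_e5(self):
        per_min = np.e ** 5 / MINUTES_PER_DAY
        track = ActivityTrack("T0", np.full(MINUTES_PER_DAY, per_min))
        mean_daily, neg_log = activity_covariates(track)
        assert np.isclose(neg_log, -5.0)

    def test_excluding_a_day_recomputes_mean(self):
        rng = np.random.default_rng(1)
        days = rng.integers(0, 300, size=(7, MINUTES_PER_DAY))
        days[2] = 0
        track = make_track(days.reshape(-1))
        mask = np.ones(7, bool)
        mask[2] = False
        mean_daily, _ = activity_covariates(track, mask)
        assert np.isclose(mean_daily, days[mask].sum(axis=1).mean())

    def test_zero_activity_errors(self):
        track = make_track(np.zeros(MINUTES_PER_DAY, dtype=int))
        with pytest.raises(ValueError):
            activity_covariates(track)


class TestDescriptorPipeline:
    def test_single_bin_track_is_degenerate_but_valid(self):
        # all counts strictly inside state 3: one-state track
        track = make_track(np.full(7 * MINUTES_PER_DAY, 30))
        desc = describe_track(track, day_mask=np.ones(7, bool))
        assert desc.tm[3, 3] == 1.0
        assert desc.descriptor.shape == (64,)
        assert np.isclose(desc.descriptor.min(), np.log(1e-3))

    def test_featurizer_shape_and_valid_day_use(self):
        rng = np.random.default_rng(5)
        tracks = [make_track(rng.integers(0, 400, 7 * MINUTES_PER_DAY),
                             sid=f"S{i}") for i in range(5)]
        feat = TransitionMatrixFeaturizer().fit(tracks)
        D = feat.transform(tracks)
        assert D.shape == (5, 64)
        _, extras = feat.describe(tracks)
        assert list(extras["subject_id"]) == [t.subject_id for t in tracks]
        assert (extras["mean_daily_activity"] > 0).all()

    def test_valid_day_mask_rule(self):
        active = np.zeros(MINUTES_PER_DAY, dtype=int)
        active[:199] = 50
        low = make_track(np.tile(active, 7))
        assert not valid_day_mask(low).any()
        active[:200] = 50
        high = make_track(np.tile(active, 7))
        assert valid_day_mask(high).all()
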