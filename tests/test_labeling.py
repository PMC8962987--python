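"""Label equations and the five strategies, against hand arithmetic."""

import numpy as np
import pytest

import emglabel as el
from emglabel.labeling import DOF_SIGN
from conftest import SMALL_STRATEGY_KW, small_strategy


class TestStrategyDefinitions:
    def test_catalog_matches_study_design(self):
        for name, kind, rule in [
            ("A", "binary", "include-rising"),
            ("B", "continuous", "include-rising"),
            ("C", "binary", "steady-only"),
            ("D", "continuous", "steady-only"),
            ("E", "continuous", "rising-and-falling"),
        ]:
            s = el.strategy(name)
            assert (s.label_kind, s.segment_rule) == (kind, rule)
            assert s.samples_per_segment == 2000
            assert s.steady_discard == 1000

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            el.strategy("F")


class TestSelectSamples:
    def test_include_rising_takes_first_block(self, small_bundle):
        strat = small_strategy("B")
        seg = small_bundle.session.segment("+x", 2)
        idx = el.select_samples(small_bundle.session, "+x", 2, strat)
        np.testing.assert_array_equal(idx, seg.active_idx[:400])

    def test_steady_only_discards_leading_block(self, small_bundle):
        strat = small_strategy("D")
        seg = small_bundle.session.segment("+y", 2)
        idx = el.select_samples(small_bundle.session, "+y", 2, strat)
        np.testing.assert_array_equal(idx, seg.active_idx[200:600])

    def test_rising_and_falling_block_composition(self, small_bundle):
        strat = small_strategy("E")
        seg = small_bundle.session.segment("-x", 2)
        idx = el.select_samples(small_bundle.session, "-x", 2, strat)
        assert len(idx) == 400
        np.testing.assert_array_equal(idx[:300], seg.active_idx[:300])
        trail = idx[300:]
        # trailing block lies in the decay context and ends at the end of
        # activation (the last above-threshold frame)
        assert trail[0] >= seg.decay_idx[0]
        assert trail[-1] == seg.last_active_decay
        np.testing.assert_array_equal(np.diff(trail), 1)

    def test_every_strategy_selects_exactly_the_budget(self, small_bundle):
        for name in el.STRATEGY_NAMES:
            strat = small_strategy(name)
            for rep in small_bundle.protocol.repetitions_used:
                for d in small_bundle.protocol.directions:
                    idx = el.select_samples(small_bundle.session, d, rep, strat)
                    assert len(idx) == strat.samples_per_segment

    def test_short_decay_context_rejected_for_e(self, small_bundle):
        strat = el.strategy("E", samples_per_segment=2000, rising_count=10)
        with pytest.raises(ValueError, match="decay context"):
            el.select_samples(small_bundle.session, "+x", 2, strat)


class TestEquations:
    def test_sum_over_electrodes_arithmetic(self):
        frames = np.zeros((3, 32))
        frames[0, 0::4] = np.arange(1, 9)     # MAV of electrodes 1..8
        frames[1, 5] = 1.0                    # electrode 2's WL only
        summed = el.sum_over_electrodes(frames)
        assert summed.shape == (3, 4)
        assert summed[0, 0] == 36.0
        assert summed[1, 1] == 1.0
        np.testing.assert_array_equal(summed[2], 0.0)

    def test_normalization_affine_endpoints(self):
        x_min = np.array([1.0, 0.0, 0.0, 0.0])
        max_f = np.array([3.0, 1.0, 1.0, 1.0])
        x = np.array([[1.0, 0, 0, 0], [3.0, 1, 1, 1], [2.0, 0.5, 0.5, 0.5]])
        out = el.normalize_feature_stream(x, max_f, x_min)
        np.testing.assert_allclose(out[0], [0, 0, 0, 0])
        np.testing.assert_allclose(out[1], [1, 1, 1, 1])
        np.testing.assert_allclose(out[2], [0.5, 0.5, 0.5, 0.5])

    def test_below_rest_clipped_to_zero(self):
        out = el.normalize_feature_stream(
            np.array([[0.5, 0, 0, 0]]), np.ones(4) * 2, np.ones(4))
        assert out[0, 0] == 0.0

    def test_degenerate_normalization_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            el.normalize_feature_stream(np.ones((2, 4)), np.ones(4), np.ones(4))

    def test_combine_divides_by_observed_max(self):
        xp = np.array([[0.25], [0.5], [1.0]]) * np.ones((1, 4))
        labels, label_max = el.combine_to_label(xp)
        np.testing.assert_allclose(labels, [0.25, 0.5, 1.0])
        assert label_max == 4.0

    def test_combine_rejects_all_zero(self):
        with pytest.raises(ValueError):
            el.combine_to_label(np.zeros((5, 4)))

    def test_monotone_streams_give_monotone_label(self):
        xp = np.linspace(0, 1, 20)[:, None] ** np.array([1, 2, 0.5, 1])
        labels, _ = el.combine_to_label(xp)
        assert np.all(np.diff(labels) >= 0)


class TestBuildTrainingLabels:
    def test_binary_plus_x_segment_signs(self, small_labeled, small_bundle):
        data = small_labeled["A"]
        seg_idx = el.select_samples(small_bundle.session, "+x", 2,
                                    small_strategy("A"))
        mask = np.isin(data.frame_idx, seg_idx)
        assert np.all(data.y[mask, 0] == 1.0)
        assert np.all(data.y[mask, 1] == 0.0)

    def test_binary_labels_restricted_to_three_values(self, small_labeled):
        for name in ("A", "C"):
            assert set(np.unique(small_labeled[name].y)) <= {-1.0, 0.0, 1.0}

    def test_continuous_labels_bounded_and_attain_one(self, small_labeled,
                                                      small_bundle):
        for name in ("B", "D", "E"):
            data = small_labeled[name]
            assert np.abs(data.y).max() <= 1.0
            for d in small_bundle.protocol.directions:
                dof, sign = DOF_SIGN[d]
                col = sign * data.y[:, dof]
                assert col.max() == pytest.approx(1.0)

    def test_minus_y_argmax_frame_labeled_minus_one(self, small_labeled):
        data = small_labeled["B"]
        i = np.argmin(data.y[:, 1])
        assert data.y[i, 1] == pytest.approx(-1.0)
        assert data.y[i, 0] == 0.0

    def test_rest_rows_labeled_zero_both_dofs(self, small_labeled,
                                              small_bundle):
        data = small_labeled["B"]
        inactive = ~small_bundle.stream.active[data.frame_idx]
        assert inactive.sum() >= SMALL_STRATEGY_KW["samples_per_segment"]
        np.testing.assert_array_equal(data.y[inactive], 0.0)

    def test_row_count_is_segments_plus_rest(self, small_labeled, small_bundle):
        n_seg = (len(small_bundle.protocol.directions)
                 * len(small_bundle.protocol.repetitions_used))
        n = SMALL_STRATEGY_KW["samples_per_segment"]
        for data in small_labeled.values():
            assert len(data.y) == (n_seg + 1) * n

    def test_transient_strategies_spread_labels_below_half(self, small_labeled):
        frac = {name: el.fraction_below(small_labeled[name].y)
                for name in ("B", "D", "E")}
        assert frac["B"] > frac["D"]
        assert frac["E"] > frac["D"]

    def test_label_computation_deterministic(self, small_bundle):
        kw = dict(profile=small_bundle.profile, stream=small_bundle.stream)
        a = el.build_training_labels(small_bundle.session, small_strategy("B"),
                                     rng=np.random.default_rng(5), **kw)
        b = el.build_training_labels(small_bundle.session, small_strategy("B"),
                                     rng=np.random.default_rng(5), **kw)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.frame_idx, b.frame_idx)

    def test_per_repetition_normalization_flag(self, full_bundle):
        data = el.build_training_labels(
            full_bundle.session, el.strategy("B"), full_bundle.profile,
            full_bundle.stream, per_repetition_norm=True,
            rng=np.random.default_rng(2))
        # each repetition segment attains 1 in magnitude on its own
        for d in full_bundle.protocol.directions:
            dof, sign = DOF_SIGN[d]
            for rep in full_bundle.protocol.repetitions_used:
                idx = el.select_samples(full_bundle.session, d, rep,
                                        el.strategy("B"))
                mask = np.isin(data.frame_idx, idx)
                assert (sign * data.y[mask, dof]).max() == pytest.approx(1.0)
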