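import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parseg.exceptions import DegenerateSampleError, ParsegError
from parseg.validation import (
    ClassifierSpec,
    PixelSample,
    ReplicateStats,
    consistency_index,
    draw_sample,
    replicate_validation,
    sensitivity,
    split_learn_validate,
    train_and_predict,
)

from helpers import make_dataset


class TestDrawSample:
    def test_full_draw_returns_whole_subset(self, rng):
        ds = make_dataset([0, 1, 0, 1, 0])
        subset = np.arange(5)
        sample = draw_sample(ds, subset, 5, rng)
        np.testing.assert_array_equal(np.sort(sample.indices), subset)

    def test_single_index(self, rng):
        ds = make_dataset([0, 1, 0, 1, 0])
        assert draw_sample(ds, np.arange(5), 1, rng).size == 1

    def test_oversized_draw_errors(self, rng):
        ds = make_dataset([0, 1, 0, 1, 0])
        with pytest.raises(DegenerateSampleError):
            draw_sample(ds, np.arange(5), 6, rng)

    def test_indices_unique_and_two_class(self, rng):
        ds = make_dataset([1] * 20 + [0] * 180)
        sample = draw_sample(ds, np.arange(200), 30, rng)
        assert len(np.unique(sample.indices)) == 30
        labels = ds.labels[sample.indices]
        assert labels.min() == 0 and labels.max() == 1


class TestSplitLearnValidate:
    @pytest.mark.parametrize(
        "s,pi,t_expected",
        [(100, 4, 80), (10, 1, 5), (50, 4, 40), (7, 2.5, 5)],
    )
    def test_cardinalities(self, s, pi, t_expected, rng):
        sample = PixelSample(0, np.arange(s))
        split = split_learn_validate(sample, pi, rng)
        assert len(split.learning) == t_expected
        assert len(split.validation) == s - t_expected

    def test_disjoint_and_exhaustive(self, rng):
        sample = PixelSample(0, np.arange(30))
        split = split_learn_validate(sample, 4, rng)
        both = np.concatenate([split.learning, split.validation])
        np.testing.assert_array_equal(np.sort(both), np.arange(30))

    def test_empty_validation_errors(self, rng):
        sample = PixelSample(0, np.arange(2))
        with pytest.raises(DegenerateSampleError):
            split_learn_validate(sample, 9, rng)


class TestTrainAndPredict:
    def test_separable_one_split(self, rng):
        ds = make_dataset([1] * 10 + [0] * 10, separation=0.6)
        sample = PixelSample(0, np.arange(20))
        split = split_learn_validate(sample, 1, rng)
        y_pred = train_and_predict(split, ds, ClassifierSpec())
        np.testing.assert_array_equal(y_pred, ds.labels[split.validation])

    def test_single_class_learning_set_errors(self):
        ds = make_dataset([0] * 10 + [1] * 2)
        split = type("S", (), {"learning": np.arange(5), "validation": np.arange(5, 8)})
        from parseg.validation import SplitPair

        split = SplitPair(np.arange(5), np.arange(5, 8), 1.0)
        with pytest.raises(DegenerateSampleError, match="degenerate learning set"):
            train_and_predict(split, ds, ClassifierSpec())

    def test_unknown_classifier(self):
        with pytest.raises(ParsegError, match="unknown classifier"):
            ClassifierSpec(name="svm-magic").build()


class TestSensitivity:
    def test_standard_half(self):
        assert sensitivity([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_identity_both_modes(self):
        y = np.array([1, 0, 1, 1])
        assert sensitivity(y, y, "standard") == 1.0
        assert sensitivity(y, y, "literal_eq3") == 1.0

    def test_literal_counts_predicted_positives(self):
        # the printed numerator counts predicted positives: 2/2 = 1.0
        assert sensitivity([1, 1, 0, 0], [1, 0, 1, 0], "literal_eq3") == 1.0

    def test_no_positives_errors(self):
        with pytest.raises(DegenerateSampleError):
            sensitivity([0, 0, 0], [1, 0, 0])

    @given(
        y_true=st.lists(st.integers(0, 1), min_size=4, max_size=30),
        y_pred=st.lists(st.integers(0, 1), min_size=4, max_size=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_standard_bounded_literal_not(self, y_true, y_pred):
        """Standard sensitivity stays in [0,1]; the literal-numerator
        variant can exceed 1 (and dominates the standard one)."""
        n = min(len(y_true), len(y_pred))
        y_true, y_pred = np.array(y_true[:n]), np.array(y_pred[:n])
        if y_true.sum() == 0:
            return
        std = sensitivity(y_true, y_pred, "standard")
        lit = sensitivity(y_true, y_pred, "literal_eq3")
        assert 0.0 <= std <= 1.0
        assert lit >= std


class TestReplicateValidation:
    def test_separable_gives_phi_one_sigma_zero(self, rng):
        ds = make_dataset([1] * 40 + [0] * 160)
        stats = replicate_validation(
            ds, np.arange(200), 50, B=10, pi=4, spec=ClassifierSpec(), rng=rng
        )
        assert stats.phi_bar == 1.0
        assert stats.sigma == 0.0

    def test_two_point_summary(self):
        stats = ReplicateStats(0, 10, np.array([0.8, 1.0]))
        assert stats.phi_bar == pytest.approx(0.9)
        assert stats.sigma == pytest.approx(np.sqrt(0.02))

    def test_b_below_two_errors(self, rng):
        ds = make_dataset([1] * 10 + [0] * 10)
        with pytest.raises(ParsegError):
            replicate_validation(
                ds, np.arange(20), 10, B=1, pi=4, spec=ClassifierSpec(), rng=rng
            )

    def test_deterministic_given_seed(self):
        ds = make_dataset(
            [1] * 30 + [0] * 120, np.random.default_rng(3), 0.1, noise_sd=0.15
        )
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            st_ = replicate_validation(
                ds, np.arange(150), 60, B=8, pi=4, spec=ClassifierSpec(), rng=rng
            )
            runs.append(st_.phis)
        np.testing.assert_array_equal(runs[0], runs[1])


class TestConsistencyIndex:
    def test_product_formula(self):
        a = ReplicateStats(0, 100, np.array([0.85, 0.95]))  # mean .9, sd ~.0707
        b = ReplicateStats(0, 1000, np.array([1.0, 1.0]))
        psi = consistency_index(a, b).psi
        assert psi == pytest.approx(abs(0.9 - 1.0) * abs(np.std([0.85, 0.95], ddof=1) - 0.0))

    def test_zero_when_means_equal(self):
        a = ReplicateStats(0, 10, np.array([0.8, 1.0]))
        b = ReplicateStats(0, 20, np.array([0.9, 0.9]))
        assert consistency_index(a, b).psi == 0.0

    def test_self_consistency_is_zero(self):
        a = ReplicateStats(0, 10, np.array([0.7, 0.9]))
        assert consistency_index(a, a).psi == 0.0

    def test_subset_mismatch_errors(self):
        a = ReplicateStats(0, 10, np.array([0.7, 0.9]))
        b = ReplicateStats(1, 20, np.array([0.7, 0.9]))
        with pytest.raises(ParsegError):
            consistency_index(a, b)

    def test_arithmetic_example(self):
        # phi_bar 0.9 vs 1.0 with sigma 0.05 vs 0.01 -> psi = 0.1 * 0.04
        def two_points(mean, sd):
            d = sd / np.sqrt(2)
            return np.array([mean - d, mean + d])

        a = ReplicateStats(0, 10, two_points(0.9, 0.05))
        b = ReplicateStats(0, 99, two_points(1.0, 0.01))
        assert consistency_index(a, b).psi == pytest.approx(0.004)
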