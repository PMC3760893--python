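import numpy as np
import pytest

from brainevo import (
    DegenerateFeatureError,
    InvalidArgumentError,
    TopologyProfile,
    accuracy_table,
    build_training_set,
    train_and_classify,
)
from brainevo.classification import ClassifierReport, FEATURES


def prof(sid, group, value, threshold=0.55):
    return TopologyProfile(
        global_efficiency=value,
        clustering_coefficient=value,
        edge_count=value,
        transitivity=value,
        long_distance_edge_count=0,
        threshold=threshold,
        subject_id=sid,
        group=group,
    )


def cohort_profiles(healthy_values, ad_values, threshold=0.55):
    return [prof(f"h{i}", "healthy", v, threshold) for i, v in enumerate(healthy_values)] + [
        prof(f"a{i}", "ad", v, threshold) for i, v in enumerate(ad_values)
    ]


class TestTrainingSet:
    def test_default_cohort_gives_21_samples(self):
        profiles = cohort_profiles(range(11), range(100, 110))
        train = build_training_set(profiles, "clustering_coefficient", 0.55)
        assert len(train.samples) == 21
        z = train.zscore([s.value for s in train.samples])
        values = np.array([s.value for s in train.samples])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)
        assert train.mean == pytest.approx(values.mean())
        assert train.sd == pytest.approx(values.std())

    def test_single_group_rejected(self):
        profiles = [prof(f"h{i}", "healthy", i) for i in range(5)]
        with pytest.raises(InvalidArgumentError):
            build_training_set(profiles, "transitivity", 0.55)

    def test_zero_spread_feature_rejected(self):
        profiles = cohort_profiles([1.0] * 5, [1.0] * 5)
        with pytest.raises(DegenerateFeatureError):
            build_training_set(profiles, "edge_count", 0.55)

    def test_unknown_feature_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_training_set(cohort_profiles([1, 2], [3, 4]), "degree", 0.55)


class TestClassify:
    def test_far_side_evolved_values_are_all_ad(self):
        train = build_training_set(
            cohort_profiles([1.0, 1.1, 0.9], [-1.0, -1.1, -0.9]), "transitivity", 0.55
        )
        report = train_and_classify(train, [-0.9, -1.2, -0.95])
        assert report.accuracy == 1.0
        report = train_and_classify(train, [1.0, 0.95, 1.1])
        assert report.accuracy == 0.0

    def test_matches_brute_force_margin_maximizer_on_symmetric_toy(self):
        # healthy at {2,3}, ad at {-2,-3}: the maximum-margin 1-D boundary is 0
        train = build_training_set(
            cohort_profiles([2.0, 3.0], [-2.0, -3.0]), "global_efficiency", 0.55
        )
        # brute-force: scan candidate thresholds, keep the widest margin
        values = np.array([2.0, 3.0, -2.0, -3.0])
        labels = np.array([0, 0, 1, 1])  # 1 = ad (below the boundary here)
        best, best_margin = None, -np.inf
        for b in np.linspace(-5, 5, 20001):
            if np.all((values < b) == (labels == 1)):
                margin = np.min(np.abs(values - b))
                if margin > best_margin:
                    best, best_margin = b, margin
        assert best == pytest.approx(0.0, abs=1e-3)
        report = train_and_classify(train, [-0.5, 0.5])
        assert report.n_classified_ad == 1  # only the value below the midpoint

    def test_boundary_tie_goes_to_ad(self):
        train = build_training_set(
            cohort_profiles([1.0, 2.0], [-1.0, -2.0]), "edge_count", 0.55
        )
        report = train_and_classify(train, [0.0])
        assert report.n_classified_ad == 1

    def test_training_order_does_not_change_labels(self):
        rng = np.random.default_rng(2)
        healthy, ad = rng.normal(1, 0.3, 8), rng.normal(-1, 0.3, 8)
        evolved = rng.normal(0, 1.0, 12)
        base = train_and_classify(
            build_training_set(cohort_profiles(healthy, ad), "transitivity", 0.55), evolved
        )
        shuffled_profiles = cohort_profiles(healthy, ad)
        rng.shuffle(shuffled_profiles)
        other = train_and_classify(
            build_training_set(shuffled_profiles, "transitivity", 0.55), evolved
        )
        assert base.n_classified_ad == other.n_classified_ad

    def test_positive_rescaling_of_feature_leaves_report_unchanged(self):
        rng = np.random.default_rng(4)
        healthy, ad = rng.normal(5, 1, 9), rng.normal(2, 1, 9)
        evolved = rng.normal(3.5, 1, 7)
        base = train_and_classify(
            build_training_set(cohort_profiles(healthy, ad), "transitivity", 0.55), evolved
        )
        scaled = train_and_classify(
            build_training_set(cohort_profiles(healthy * 40, ad * 40), "transitivity", 0.55),
            evolved * 40,
        )
        assert base.n_classified_ad == scaled.n_classified_ad

    def test_too_few_samples_per_class_rejected(self):
        train = build_training_set(cohort_profiles([1.0, 2.0], [-1.0]), "transitivity", 0.55)
        with pytest.raises(InvalidArgumentError):
            train_and_classify(train, [0.0])


class TestAccuracyTable:
    def _reports(self, accuracy=1.0):
        taus = [round(0.50 + 0.01 * k, 2) for k in range(11)]
        return [
            ClassifierReport(
                feature=f, threshold=t, n_evolved=11, n_classified_ad=int(round(accuracy * 11))
            )
            for t in taus
            for f in FEATURES
        ]

    def test_shape_and_perfect_average(self):
        table = accuracy_table(self._reports(1.0))
        assert table.shape == (12, 4)
        assert list(table.columns) == list(FEATURES)
        assert np.allclose(table.loc["average"].to_numpy(), 100.0)

    def test_average_is_column_mean(self):
        reports = self._reports(1.0)
        # depress one feature at one threshold and check the average arithmetic
        reports[0] = ClassifierReport(
            feature=reports[0].feature,
            threshold=reports[0].threshold,
            n_evolved=11,
            n_classified_ad=0,
        )
        table = accuracy_table(reports)
        col = reports[0].feature
        expected = np.mean([0.0] + [100.0] * 10)
        assert table.loc["average", col] == pytest.approx(expected)

    def test_missing_cells_rejected(self):
        with pytest.raises(InvalidArgumentError):
            accuracy_table(self._reports()[:-1])
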