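"""Pearson correlation, redundancy filtering, and the threshold sweep."""
import numpy as np
import pandas as pd
import pytest

from logbbpred.errors import DegenerateInputError
from logbbpred.feature_selection import correlation_filter, pearson, sweep_thresholds
from logbbpred.featurization import DescriptorTable
from logbbpred.modeling import LearnerSpec
from logbbpred.synthetic import SyntheticSpec, make_regression_dataset


def check_selection_bruteforce(table, target, result):
    """Exhaustive oracle: no kept pair exceeds the threshold, and every
    dropped feature conflicted with a kept feature of >= relevance."""
    frame = table.data
    kept = result.selected_names
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            pcc = np.corrcoef(frame[a], frame[b])[0, 1]
            assert abs(pcc) <= result.threshold + 1e-12
    for kept_name, dropped_name, pcc in result.dropped_pairs:
        assert kept_name in kept
        assert abs(np.corrcoef(frame[kept_name], frame[dropped_name])[0, 1]) == pytest.approx(
            abs(pcc), abs=1e-12
        )
        assert abs(pcc) > result.threshold
        assert result.relevance[kept_name] >= result.relevance[dropped_name] - 1e-12


class TestPearson:
    def test_self_correlation(self):
        x = [1.0, 2.0, 5.0]
        assert pearson(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # centered x = [-1,0,1], centered y = [-4/3,-1/3,5/3]
        # r = 3 / sqrt(2 * 42/9) = 0.98198...
        expected = 3.0 / np.sqrt(2 * 42 / 9)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_numpy_on_random_vectors(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            assert pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


class TestCorrelationFilter:
    def test_more_relevant_clone_kept(self, rng):
        signal = rng.standard_normal(100)
        y = signal + rng.normal(0, 0.1, 100)
        frame = pd.DataFrame({"noisy_copy": signal + rng.normal(0, 0.5, 100), "clean": signal})
        result = correlation_filter(DescriptorTable(data=frame), y, threshold=0.5)
        assert result.selected_names == ["clean"]
        assert result.dropped_pairs[0][:2] == ("clean", "noisy_copy")

    def test_loose_threshold_keeps_weakly_correlated(self, rng):
        frame = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
        y = rng.standard_normal(200)
        result = correlation_filter(DescriptorTable(data=frame), y, threshold=0.99)
        assert len(result.selected_names) == 5

    def test_bruteforce_oracle_on_random_tables(self, rng):
        for trial in range(10):
            frame = pd.DataFrame(
                rng.standard_normal((60, 10)) @ rng.standard_normal((10, 10)),
                columns=[f"f{j}" for j in range(10)],
            )
            y = rng.standard_normal(60)
            table = DescriptorTable(data=frame)
            result = correlation_filter(table, y, threshold=0.6)
            check_selection_bruteforce(table, y, result)

    def test_block_dataset_keeps_one_per_block(self):
        spec = SyntheticSpec(n_compounds=500, intra_block_corr=0.95, seed=5)
        table, y, truth = make_regression_dataset(spec)
        result = correlation_filter(table, y, threshold=0.8)
        for gen, members in truth.blocks.items():
            survivors = [m for m in members if m in result.selected_names]
            assert len(survivors) == 1

    def test_constant_columns_ignored_with_warning(self, rng, caplog):
        frame = pd.DataFrame({"a": rng.standard_normal(50), "const": np.ones(50)})
        y = rng.standard_normal(50)
        with caplog.at_level("WARNING"):
            result = correlation_filter(DescriptorTable(data=frame), y, threshold=0.5)
        assert result.selected_names == ["a"]

    def test_all_constant_is_error(self):
        frame = pd.DataFrame({"a": np.ones(10), "b": np.full(10, 2.0)})
        with pytest.raises(DegenerateInputError):
            correlation_filter(DescriptorTable(data=frame), np.arange(10.0), threshold=0.5)

    def test_deterministic(self, rng):
        frame = pd.DataFrame(rng.standard_normal((80, 8)), columns=[f"f{j}" for j in range(8)])
        y = rng.standard_normal(80)
        table = DescriptorTable(data=frame)
        r1 = correlation_filter(table, y, 0.4)
        r2 = correlation_filter(table, y, 0.4)
        assert r1.selected_names == r2.selected_names


@pytest.fixture(scope="module")
def block_data():
    spec = SyntheticSpec(
        n_compounds=300, clones_per_block=6, intra_block_corr=0.9, noise_sd=0.5, seed=9
    )
    return make_regression_dataset(spec)


class TestSweep:
    def test_feature_count_monotone_in_threshold(self, block_data):
        table, y, _ = block_data
        sweep = sweep_thresholds(
            table, y, LearnerSpec(name="mlr"), thresholds=[0.2, 0.5, 0.8, 0.95], k=5, seed=1
        )
        assert sweep.n_features == sorted(sweep.n_features)

    def test_folds_identical_across_thresholds(self, block_data):
        table, y, _ = block_data
        sweep = sweep_thresholds(
            table, y, LearnerSpec(name="mlr"), thresholds=[0.3, 0.7], k=5, seed=2
        )
        recs = list(sweep.cv_records.values())
        for a, b in zip(recs[0].fold_test_indices, recs[1].fold_test_indices):
            assert np.array_equal(a, b)

    def test_single_threshold_chosen(self, block_data):
        table, y, _ = block_data
        sweep = sweep_thresholds(table, y, LearnerSpec(name="mlr"), thresholds=[0.5], k=5, seed=3)
        assert sweep.chosen_threshold == 0.5

    def test_chosen_selection_one_representative_per_block(self, block_data):
        table, y, truth = block_data
        sweep = sweep_thresholds(
            table, y, LearnerSpec(name="mlr"), thresholds=[0.3, 0.5, 0.7], k=5, seed=4
        )
        selected = set(sweep.chosen_selection.selected_names)
        for gen, members in truth.blocks.items():
            assert len(selected & set(members)) == 1
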