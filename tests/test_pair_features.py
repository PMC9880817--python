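import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cofrac.errors import UsageError
from cofrac.pair_features import (
    FEATURE_COLUMNS,
    apex_feature,
    bayes_correlation_feature,
    build_feature_table,
    jaccard_feature,
    mutual_information_feature,
    pearson_feature,
    read_feature_table,
    write_feature_table,
)
from cofrac.profiles import ProfileMatrix
from oracles import bayes_oracle, mi_oracle, pearson_oracle

profile_pairs = st.integers(min_value=5, max_value=12).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 9), min_size=n, max_size=n),
        st.lists(st.integers(0, 9), min_size=n, max_size=n),
    )
)


def close_or_both_nan(a, b, tol=1e-9):
    if math.isnan(a) or math.isnan(b):
        return math.isnan(a) and math.isnan(b)
    return abs(a - b) <= tol


class TestHandValues:
    def test_pearson_of_identical_profiles_is_one(self):
        assert pearson_feature([0, 2, 5, 1], [0, 2, 5, 1]) == pytest.approx(1.0)

    def test_pearson_anticorrelated(self):
        assert pearson_feature([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_pearson_zero_variance_is_nan(self):
        assert math.isnan(pearson_feature([1, 1, 1], [0, 2, 1]))

    def test_jaccard_partial_overlap(self):
        assert jaccard_feature([1, 1, 0, 0], [0, 1, 1, 0]) == pytest.approx(1 / 3)

    def test_jaccard_both_empty_is_zero(self):
        assert jaccard_feature([0, 0], [0, 0]) == 0.0

    def test_apex_shared_peak(self):
        assert apex_feature([0, 5, 1], [0, 3, 2]) == 1
        assert apex_feature([5, 0, 1], [0, 3, 2]) == 0

    def test_apex_ties_resolve_to_earliest(self):
        # both vectors tie; their earliest maxima differ
        assert apex_feature([2, 0, 2], [0, 2, 2]) == 0
        assert apex_feature([2, 0, 2], [2, 2, 0]) == 1

    def test_mi_of_two_balanced_bins_is_one_bit(self):
        assert mutual_information_feature(
            [0, 0, 1, 1], [0, 0, 1, 1], n_bins=2
        ) == pytest.approx(1.0)

    def test_mi_of_constant_profile_is_zero(self):
        assert mutual_information_feature(
            [1, 1, 1, 1, 1], [0, 3, 1, 2, 0], n_bins=5
        ) == pytest.approx(0.0)

    def test_bayes_approaches_scale_invariance_at_high_counts(self):
        x = [50, 10, 0, 5, 30]
        y = [40, 20, 5, 0, 25]
        base = bayes_correlation_feature(x, y, alpha=1.0)
        scaled = bayes_correlation_feature(
            [10 * v for v in x], [10 * v for v in y], alpha=1.0
        )
        assert abs(base - scaled) < 0.01

    def test_bayes_shrinks_toward_zero_at_low_counts(self):
        # identical singleton spikes: raw pearson is 1, the smoothed
        # correlation is attenuated but positive
        raw = pearson_feature([1, 0, 0, 0], [1, 0, 0, 0])
        smoothed = bayes_correlation_feature([1, 0, 0, 0], [1, 0, 0, 0], alpha=1.0)
        assert raw == pytest.approx(1.0)
        assert 0.0 < smoothed <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(UsageError):
            pearson_feature([1, 2], [1, 2, 3])
        with pytest.raises(UsageError):
            mutual_information_feature([1, 2], [1, 2], n_bins=5)
        with pytest.raises(UsageError):
            bayes_correlation_feature([1, 2], [1, 2], alpha=0.0)


class TestFeatureProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(profile_pairs)
    def test_all_features_symmetric(self, xy):
        x, y = xy
        assert close_or_both_nan(pearson_feature(x, y), pearson_feature(y, x))
        assert jaccard_feature(x, y) == jaccard_feature(y, x)
        assert apex_feature(x, y) == apex_feature(y, x)
        assert mutual_information_feature(x, y) == pytest.approx(
            mutual_information_feature(y, x)
        )
        assert close_or_both_nan(
            bayes_correlation_feature(x, y), bayes_correlation_feature(y, x)
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(profile_pairs)
    def test_features_within_documented_ranges(self, xy):
        x, y = xy
        r = pearson_feature(x, y)
        assert math.isnan(r) or -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        assert 0.0 <= jaccard_feature(x, y) <= 1.0
        assert apex_feature(x, y) in (0, 1)
        mi = mutual_information_feature(x, y)
        assert 0.0 <= mi <= math.log2(5) + 1e-12
        b = bayes_correlation_feature(x, y)
        assert math.isnan(b) or -1.0 - 1e-12 <= b <= 1.0 + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(profile_pairs)
    def test_pearson_invariant_under_positive_scaling(self, xy):
        x, y = xy
        r1 = pearson_feature(x, y)
        r2 = pearson_feature([3 * v for v in x], [7 * v for v in y])
        assert close_or_both_nan(r1, r2)

    def test_mi_matches_brute_force_on_seeded_sample(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(5, 15))
            x = rng.integers(0, 6, n).tolist()
            y = rng.integers(0, 6, n).tolist()
            assert mutual_information_feature(x, y, n_bins=5) == pytest.approx(
                mi_oracle(x, y, 5), abs=1e-9
            )

    def test_pearson_and_bayes_match_brute_force_on_seeded_sample(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(5, 15))
            x = rng.integers(0, 6, n).tolist()
            y = rng.integers(0, 6, n).tolist()
            assert close_or_both_nan(pearson_feature(x, y), pearson_oracle(x, y))
            assert close_or_both_nan(
                bayes_correlation_feature(x, y), bayes_oracle(x, y, 1.0)
            )


def two_experiment_matrices():
    """Three proteins: a/b co-elute everywhere, c peaks elsewhere."""
    sec = np.array(
        [
            [0, 1, 8, 2, 0, 0, 0, 0, 0, 0],
            [0, 2, 9, 1, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 2, 9, 1, 0],
        ]
    )
    iex = np.array(
        [
            [0, 0, 0, 6, 2, 0, 0, 0, 0, 0],
            [0, 0, 0, 7, 1, 0, 0, 0, 0, 0],
            [3, 6, 1, 0, 0, 0, 0, 0, 0, 0],
        ]
    )
    names = ["a", "b", "c"]
    return [
        ProfileMatrix("SEC1", "SEC", names, sec),
        ProfileMatrix("IEX1", "IEX", names, iex),
    ]


class TestBuildFeatureTable:
    def test_coeluting_pair_survives_others_filtered(self):
        table = build_feature_table(two_experiment_matrices(), {"a", "b", "c"})
        pairs = set(zip(table["protein_a"], table["protein_b"]))
        assert pairs == {("a", "b")}
        row = table.iloc[0]
        assert row["pearson"] > 0.5
        assert row["apex"] == 1
        assert row["n_experiments"] == 2

    def test_prefilter_is_strict(self):
        # r = 1.0 for identical profiles is NOT > 1.0, so nothing survives
        table = build_feature_table(
            two_experiment_matrices(), {"a", "b", "c"}, prefilter=1.0
        )
        assert len(table) == 0

    def test_excluded_proteins_never_scored(self):
        table = build_feature_table(two_experiment_matrices(), {"a", "c"})
        assert "b" not in set(table["protein_a"]) | set(table["protein_b"])

    def test_columns_and_ordering(self):
        table = build_feature_table(two_experiment_matrices(), {"a", "b", "c"},
                                    prefilter=-2.0)
        assert list(table.columns) == [
            "protein_a", "protein_b", *FEATURE_COLUMNS, "n_experiments",
        ]
        pairs = list(zip(table["protein_a"], table["protein_b"]))
        assert pairs == sorted(pairs)
        assert all(a < b for a, b in pairs)

    def test_round_trip(self, tmp_path):
        table = build_feature_table(two_experiment_matrices(), {"a", "b", "c"})
        path = tmp_path / "features.tsv"
        write_feature_table(table, path)
        again = read_feature_table(path)
        assert list(again.columns) == list(table.columns)
        assert len(again) == len(table)

    def test_no_matrices_rejected(self):
        with pytest.raises(UsageError):
            build_feature_table([], {"a"})

    def test_no_retained_proteins_rejected(self):
        with pytest.raises(UsageError):
            build_feature_table(two_experiment_matrices(), {"zzz"})
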