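"""Weight deltas, rank shifts and tier profiles."""

import numpy as np
import pytest

from hesrank.comparison import (
    cluster_profiles,
    compare_regions,
    rank_shifts,
    weight_deltas,
)
from hesrank.clustering import assign_levels, kmeans_1d_optimal
from hesrank.data_model import AlignmentError, SubIndicatorPanel
from hesrank.entropy import WeightVector
from hesrank.published import (
    INDICATORS,
    published_ranks,
    published_weight_vectors,
    published_weights,
)


def wv(weights, region="r", period="p"):
    weights = np.asarray(weights, dtype=float)
    nan = np.full(weights.size, np.nan)
    return WeightVector(
        indicator_ids=tuple(f"i{j}" for j in range(weights.size)),
        entropy=nan, divergence=nan, weights=weights,
        region=region, period=period,
    )


class TestWeightDeltas:
    def test_published_prevention_delta(self):
        early = published_weight_vectors("non_eu")[0]
        late = published_weight_vectors("non_eu")[1]
        assert (early.period, late.period) == ("2019", "2021")
        delta = weight_deltas(early, late)
        assert delta.deltas[0] == pytest.approx(0.014, abs=1e-12)

    def test_identity_gives_zero(self):
        a = wv([0.5, 0.5])
        assert weight_deltas(a, a).deltas.tolist() == [0.0, 0.0]

    def test_antisymmetric(self):
        a, b = wv([0.6, 0.4]), wv([0.3, 0.7])
        assert np.allclose(weight_deltas(a, b).deltas,
                           -weight_deltas(b, a).deltas)

    def test_published_african_detection_delta(self):
        a19 = published_weights("africa", "2019")
        a21 = published_weights("africa", "2021")
        delta = weight_deltas(wv(a19), wv(a21))
        assert delta.deltas[1] == pytest.approx(-0.032, abs=1e-12)

    def test_mismatched_indicators_rejected(self):
        a = wv([0.5, 0.5])
        b = WeightVector(indicator_ids=("x", "y"), entropy=np.full(2, np.nan),
                         divergence=np.full(2, np.nan),
                         weights=np.array([0.5, 0.5]))
        with pytest.raises(AlignmentError):
            weight_deltas(a, b)

    def test_full_precision_deltas_sum_to_zero(self):
        a, b = wv([0.25, 0.35, 0.40]), wv([0.10, 0.50, 0.40])
        assert weight_deltas(a, b).deltas.sum() == pytest.approx(0.0, abs=1e-9)


class TestRankShifts:
    def test_published_rankings_classification(self):
        report = rank_shifts(published_ranks("2019"), published_ranks("2021"))
        assert report.counts == {"improved": 13, "stable": 4, "declined": 10}
        assert report.percentages["improved"] == pytest.approx(48.148, abs=5e-3)
        assert sum(report.percentages.values()) == pytest.approx(100.0)

    def test_identical_rankings_all_stable(self):
        r = {"A": 1, "B": 2, "C": 3}
        report = rank_shifts(r, r)
        assert report.counts == {"improved": 0, "stable": 3, "declined": 0}

    def test_two_country_swap_antisymmetry(self):
        report = rank_shifts({"A": 1, "B": 2}, {"A": 2, "B": 1})
        assert report.counts["improved"] == 1
        assert report.counts["declined"] == 1

    def test_country_set_mismatch(self):
        with pytest.raises(AlignmentError):
            rank_shifts({"A": 1, "B": 2}, {"A": 1, "C": 2})

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            rank_shifts({"A": 1, "B": 3}, {"A": 1, "B": 2})


class TestClusterProfiles:
    def panel(self):
        return SubIndicatorPanel(
            countries=("A", "B", "C"),
            sub_indicators=("s1", "s2"),
            scores=np.array([[80.0, 10.0], [95.0, 20.0], [40.0, 30.0]]),
        )

    def assignment(self, values=(9.0, 8.0, 1.0), K=2):
        return assign_levels(
            kmeans_1d_optimal(values, K=K, countries=("A", "B", "C"))
        )

    def test_pairwise_mean(self):
        prof = cluster_profiles(self.panel(), self.assignment())
        assert prof.loc[1, "s1"] == pytest.approx(87.5)

    def test_singleton_cluster_is_own_score(self):
        prof = cluster_profiles(self.panel(), self.assignment())
        assert prof.loc[2, "s1"] == 40.0

    def test_member_order_invariance(self):
        prof_a = cluster_profiles(self.panel(), self.assignment())
        shuffled = SubIndicatorPanel(
            countries=("C", "A", "B"),
            sub_indicators=("s1", "s2"),
            scores=np.array([[40.0, 30.0], [80.0, 10.0], [95.0, 20.0]]),
        )
        prof_b = cluster_profiles(shuffled, self.assignment())
        assert np.allclose(prof_a.values, prof_b.values)

    def test_missing_country_rejected(self):
        panel = SubIndicatorPanel(
            countries=("A", "B"), sub_indicators=("s1",),
            scores=np.array([[1.0], [2.0]]),
        )
        with pytest.raises(AlignmentError, match="'C'"):
            cluster_profiles(panel, self.assignment())

    def test_means_within_member_range(self):
        prof = cluster_profiles(self.panel(), self.assignment())
        assert 80.0 <= prof.loc[1, "s1"] <= 95.0


class TestCompareRegions:
    def test_published_table_is_54_rows(self):
        table = compare_regions(published_weight_vectors())
        assert len(table) == 9 * 6
        # round-trip: values identical to the ingested table
        cell = table[(table.region == "non_eu") & (table.period == "2019")
                     & (table.indicator == "detection")]
        assert cell.weight.item() == 0.399

    def test_deltas_attached_for_period_pair(self):
        table = compare_regions(
            published_weight_vectors("non_eu"), delta_periods=("2019", "2021")
        )
        cell = table[(table.period == "2021")
                     & (table.indicator == INDICATORS[0])]
        assert cell.delta.item() == pytest.approx(0.014)

    def test_single_vector_has_no_deltas(self):
        table = compare_regions(published_weight_vectors("non_eu")[:1])
        assert table.delta.isna().all()
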