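"""Overlap algebra, contingency tables, suffix-convention distributions."""

import numpy as np
import pytest

from surnamekit import (
    ListMembership,
    RegistryRecord,
    SuffixHeuristicRanker,
    VitalRecord,
    contingency,
    coverage_gain,
    overlap,
    suffix_distribution,
    venn3,
)
from surnamekit.synthetic_data import make_surname


class TestOverlap:
    def test_hand_count(self):
        report = overlap(["X", "Y"], ["Y", "Z"])
        assert (report.only_a, report.only_b, report.both) == (1, 1, 1)
        assert report.jaccard == pytest.approx(1 / 3)
        assert report.pct_of_b_in_a == pytest.approx(50.0)

    def test_identity(self):
        report = overlap(["A", "B"], ["a", "b"])  # case-insensitive
        assert (report.only_a, report.only_b) == (0, 0)
        assert report.jaccard == 1.0

    def test_disjoint(self):
        report = overlap(["A"], ["B"])
        assert report.both == 0 and report.jaccard == 0.0

    def test_empty_lists_flag_undefined_jaccard(self):
        report = overlap([], [])
        assert report.jaccard is None and report.pct_of_b_in_a is None


class TestVenn3:
    def test_disjoint_singletons(self):
        regions = venn3(["A"], ["B"], ["C"])
        assert (regions.a_only, regions.b_only, regions.c_only) == (1, 1, 1)
        assert regions.abc == 0 and regions.union_size == 3

    def test_identical_singletons(self):
        regions = venn3(["X"], ["X"], ["X"])
        assert regions.abc == 1 and regions.union_size == 1

    def test_random_sets_against_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        universe = [f"N{i}" for i in range(60)]
        for _ in range(20):
            a, b, c = (
                {n for n in universe if rng.random() < p} for p in (0.4, 0.5, 0.3)
            )
            regions = venn3(a, b, c)
            tally = {key: 0 for key in regions.as_dict()}
            for name in set().union(a, b, c):
                key = {
                    (True, False, False): "a_only",
                    (False, True, False): "b_only",
                    (False, False, True): "c_only",
                    (True, True, False): "ab_only",
                    (True, False, True): "ac_only",
                    (False, True, True): "bc_only",
                    (True, True, True): "abc",
                }[(name in a, name in b, name in c)]
                tally[key] += 1
            assert regions.as_dict() == tally
            assert regions.union_size == len(a | b | c)
            # marginals agree with pairwise overlap()
            assert regions.marginal("a") == len(a)
            pair = overlap(a, b)
            assert pair.both == regions.ab_only + regions.abc


class TestCoverageGain:
    def test_hand_count(self):
        count, pct = coverage_gain(["A", "B", "C"], ["A"], ["A", "B", "C"])
        assert count == 2 and pct == pytest.approx(200 / 3)

    def test_subset_of_baseline_gains_nothing(self):
        count, pct = coverage_gain(["A"], ["A", "B"], ["A", "B"])
        assert count == 0 and pct == 0.0

    def test_empty_capture_is_flagged(self):
        count, pct = coverage_gain(["X"], ["Y"], ["Z"])
        assert count == 0 and pct is None

    def test_random_sets_against_set_arithmetic(self):
        rng = np.random.default_rng(5)
        universe = [f"N{i}" for i in range(40)]
        for _ in range(20):
            new, base, ref = (
                {n for n in universe if rng.random() < p} for p in (0.5, 0.4, 0.5)
            )
            count, pct = coverage_gain(new, base, ref)
            expected = (ref & new) - base
            assert count == len(expected)
            if ref & new:
                assert pct == pytest.approx(100 * len(expected) / len(ref & new))


class TestContingency:
    RECORDS = [
        VitalRecord("Martirosyan", birthplace="Armenia"),
        VitalRecord("Danielian", birthplace="Armenia"),
        VitalRecord("Weatherford", birthplace="Armenia"),
        VitalRecord("Smith", birthplace=None),
    ]

    def test_hand_count(self):
        table = contingency(self.RECORDS, ["Martirosyan", "Danielian"], "Armenia")
        assert table.counts["yes"] == {"target": 2, "other": 0, "unknown": 0}
        assert table.counts["no"] == {"target": 1, "other": 0, "unknown": 1}
        assert table.column_pct["yes"]["target"] == pytest.approx(200 / 3)
        assert table.column_pct["no"]["target"] == pytest.approx(100 / 3)
        assert table.grand_total == 4

    def test_empty_list_gives_empty_yes_row(self):
        table = contingency(self.RECORDS, [], "Armenia")
        assert all(v == 0 for v in table.counts["yes"].values())

    def test_surname_counts_once_per_stratum(self):
        records = [
            VitalRecord("Nerses", birthplace="Armenia"),
            VitalRecord("Nerses", birthplace="Armenia"),
            VitalRecord("Nerses", birthplace="Russia"),
        ]
        table = contingency(records, ["Nerses"], "Armenia")
        assert table.counts["yes"] == {"target": 1, "other": 1, "unknown": 0}

    def test_column_percentages_sum_to_100(self, default_world):
        table = contingency(
            default_world.registry_records,
            default_world.reference_extract,
            default_world.config.target_birthplace,
            match_mode="truncation_aware",
        )
        for col in ("target", "other", "unknown"):
            if table.column_total(col):
                total_pct = table.column_pct["yes"][col] + table.column_pct["no"][col]
                assert total_pct == pytest.approx(100.0, abs=0.01)

    def test_registry_records_use_country_of_birth(self):
        records = [RegistryRecord("Martirosyan", country_of_birth="Armenia")]
        table = contingency(records, ["Martirosyan"], "Armenia")
        assert table.counts["yes"]["target"] == 1


class TestTruncationAwareMembership:
    def test_truncated_entry_matches_full_query(self):
        membership = ListMembership(["Haroutunia"], match_mode="truncation_aware")
        assert "Haroutunian" in membership
        assert "Haroutunia" in membership
        assert "Haro" not in membership

    def test_exact_mode_requires_exact(self):
        membership = ListMembership(["Haroutunia"], match_mode="exact")
        assert "Haroutunian" not in membership


class TestSuffixDistribution:
    def test_hand_count(self):
        dist = suffix_distribution(["Danielian", "Martirosyan"])
        assert dist["all"]["I_convention"] == pytest.approx(0.5)
        assert dist["all"]["Y_convention"] == pytest.approx(0.5)

    def test_all_other(self):
        dist = suffix_distribution(["Weatherford", "Smith"])
        assert dist["all"]["other"] == 1.0

    def test_proportions_sum_to_one_per_stratum(self):
        strata = {"DANIELIAN": "Russia", "MARTIROSYAN": "Armenia", "SMITH": "Armenia"}
        dist = suffix_distribution(["Danielian", "Martirosyan", "Smith"], strata)
        for stratum, props in dist.items():
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-3)

    def test_recovers_generator_convention_mix(self):
        """A 70/20/10 Y/I/russian mixture is recovered within 3 points."""
        rng = np.random.default_rng(13)
        mix = {"Y_convention": 0.7, "I_convention": 0.2, "russian": 0.1}
        names = []
        for i in range(2000):
            convention = str(rng.choice(list(mix), p=list(mix.values())))
            stem = "".join(
                rng.choice(list("BDGKLMNRSTVZ")) + rng.choice(list("AEIOU"))
                for _ in range(3)
            )
            # numeric tag keeps spellings unique; normalization ignores digits
            names.append(make_surname(stem, convention, rng) + str(i))
        dist = suffix_distribution(names)
        for convention, expected in mix.items():
            assert dist["all"][convention] == pytest.approx(expected, abs=0.03)


def test_demo_origin_ranker_is_plumbing_only():
    ranker = SuffixHeuristicRanker()
    ranks = ranker.rank("Martirosyan")
    assert ranks[0][1] == 1 and len(ranks) <= 10
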