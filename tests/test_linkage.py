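"""Blocked linkage: scoring tiers, oracle equivalence, review round-trip."""

import pytest

from surnamekit import (
    LinkageConfig,
    export_review,
    generate_candidates,
    import_review,
    jaro_winkler,
    link,
    normalize,
    same_block,
    score_pair,
)
from surnamekit.linkage import CandidatePair, ReviewImportError
from surnamekit.synthetic_data import WorldConfig, generate_world


def _pair(left, right):
    from surnamekit import soundex

    return CandidatePair(left, right, soundex(normalize(left)))


class TestJaroWinkler:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("MARTHA", "MARHTA", 0.9611),
            ("DWAYNE", "DUANE", 0.8400),
            ("DIXON", "DICKSONX", 0.8133),
            ("SMITH", "SMITH", 1.0),
        ],
    )
    def test_published_values(self, a, b, expected):
        assert jaro_winkler(a, b) == pytest.approx(expected, abs=1e-4)

    def test_bounds_and_symmetry(self):
        for a, b in [("A", "ZZZZ"), ("MAHTESYAN", "MAHTESIAN"), ("X", "X")]:
            s = jaro_winkler(a, b)
            assert 0.0 <= s <= 1.0
            assert s == jaro_winkler(b, a)


class TestCandidates:
    def test_truncated_reference_pairs_with_full_form(self):
        pairs = generate_candidates(["Haroutunia"], ["Haroutunian", "Smith"])
        assert len(pairs) == 1
        assert (pairs[0].left, pairs[0].right) == ("Haroutunia", "Haroutunian")

    def test_punctuation_variants_pair(self):
        pairs = generate_candidates(["Ter-Minasyan"], ["Ter Minasyan"])
        assert len(pairs) == 1

    def test_reflexive_singleton(self):
        pairs = generate_candidates(["Smith"], ["Smith"])
        assert len(pairs) == 1

    def test_no_pairs_across_blocks(self):
        pairs = generate_candidates(["Smith", "Jones"], ["Martirosyan"])
        assert pairs == []


class TestScorePair:
    def test_punctuation_variant_is_perfect_match(self):
        result = score_pair(_pair("Ter-Minasyan", "Ter Minasyan"))
        assert (result.basis, result.score, result.category) == ("exact_normalized", 1.0, "match")

    @pytest.mark.parametrize("left,right", [("Haroutunia", "Haroutunian"), ("Martirosya", "Martirosyan")])
    def test_ten_letter_prefix_is_truncation_match(self, left, right):
        result = score_pair(_pair(left, right))
        assert result.basis == "truncation_prefix" and result.category == "match"

    def test_short_prefix_is_not_truncation_match(self):
        result = score_pair(_pair("Aram", "Aramyan"))
        assert result.basis == "similarity"

    def test_identity(self):
        result = score_pair(_pair("Smith", "Smith"))
        assert result.basis == "exact_normalized" and result.category == "match"

    def test_asymmetric_truncation_requires_left_to_be_short(self):
        config = LinkageConfig(asymmetric_truncation=True)
        ok = score_pair(_pair("Haroutunia", "Haroutunian"), config)
        assert ok.basis == "truncation_prefix"
        flipped = score_pair(_pair("Haroutunian", "Haroutunia"), config)
        assert flipped.basis == "similarity"


def _brute_force_match_set(left_names, right_names, config):
    """All-pairs oracle: score every same-block pair with the same thresholds."""
    matched = set()
    for l in left_names:
        for r in right_names:
            if not same_block(l, r):
                continue
            result = score_pair(_pair(l, r), config)
            if result.category == "match":
                matched.add((l, r))
    return matched


class TestLink:
    def test_toy_lists_against_brute_force(self):
        left = ["Mahtesyan", "Haroutunia", "Smith"]
        right = ["Mahtesian", "Haroutunian", "Jones"]
        config = LinkageConfig()
        result = link(left, right, config)
        assert {(m.pair.left, m.pair.right) for m in result.matches} == _brute_force_match_set(
            left, right, config
        )
        assert result.left_unmatched == {"Smith"}
        assert result.right_unmatched == {"Jones"}

    def test_synthetic_lists_match_brute_force_oracle(self, build_config):
        from surnamekit.construction import harvest_surnames

        world = generate_world(
            WorldConfig(seed=19, n_target_stems=150, n_other_surnames=120, n_traps=9)
        )
        left = world.reference_extract.surnames()
        right = harvest_surnames(world.vital_records, build_config).surnames()
        assert len(left) <= 500 and len(right) <= 500
        config = LinkageConfig()
        result = link(left, right, config)
        assert {(m.pair.left, m.pair.right) for m in result.matches} == _brute_force_match_set(
            left, right, config
        )

    def test_disjoint_blocks_leave_all_unmatched(self):
        result = link(["Martirosyan"], ["Smith", "Jones"])
        assert result.left_unmatched == {"Martirosyan"}
        assert not result.matches and not result.reviews

    def test_identity_linkage_matches_everything(self):
        names = ["Martirosyan", "Danielian", "Oganesov"]
        result = link(names, names)
        assert result.linked_left() == set(names)
        assert not result.left_unmatched and not result.reviews

    def test_swap_symmetry(self, noise_free_world):
        left = noise_free_world.reference_extract.surnames()[:200]
        right = [r.surname for r in noise_free_world.vital_records[:200]]
        fwd = link(left, right)
        rev = link(right, left)
        assert {(m.pair.left, m.pair.right) for m in fwd.matches} == {
            (m.pair.right, m.pair.left) for m in rev.matches
        }
        assert fwd.left_unmatched == rev.right_unmatched
        assert fwd.right_unmatched == rev.left_unmatched

    def test_raising_threshold_never_adds_similarity_matches(self, default_world, build_config):
        from surnamekit.construction import harvest_surnames

        left = default_world.reference_extract.surnames()
        right = harvest_surnames(default_world.vital_records, build_config).surnames()

        def similarity_matches(threshold):
            result = link(left, right, LinkageConfig(match_threshold=threshold, review_low=0.5))
            return {
                (m.pair.left, m.pair.right) for m in result.matches if m.basis == "similarity"
            }

        previous = similarity_matches(0.80)
        for threshold in (0.85, 0.90, 0.95, 0.99):
            current = similarity_matches(threshold)
            assert current <= previous
            previous = current


class TestReviewRoundTrip:
    @pytest.fixture()
    def result_with_reviews(self):
        # MAHTESYAN vs MAHTESIAN scores in the review band under a raised bar
        config = LinkageConfig(match_threshold=0.97, review_low=0.85)
        return link(["Mahtesyan"], ["Mahtesian"], config), config

    def test_round_trip_with_no_edits_applies_default(self, tmp_path, result_with_reviews):
        result, config = result_with_reviews
        assert len(result.reviews) == 1
        path = tmp_path / "review.csv"
        export_review(result, path)
        resolved = import_review(result, path, config)
        assert not resolved.reviews and not resolved.matches  # default non_match
        assert resolved.left_unmatched == {"Mahtesyan"}

    def test_decisions_are_applied(self, tmp_path, result_with_reviews):
        result, config = result_with_reviews
        path = tmp_path / "review.csv"
        export_review(result, path)
        text = path.read_text().replace("similarity,", "similarity,match")
        path.write_text(text)
        resolved = import_review(result, path, config)
        assert len(resolved.matches) == 1 and not resolved.reviews

    def test_unknown_pair_rejected_with_row_listing(self, tmp_path, result_with_reviews):
        result, config = result_with_reviews
        path = tmp_path / "review.csv"
        path.write_text("left,right,score,basis,decision\nNope,Nada,0.9,similarity,match\n")
        with pytest.raises(ReviewImportError, match="Nope"):
            import_review(result, path, config)

    def test_empty_review_set_round_trips_as_identity(self, tmp_path):
        result = link(["Smith"], ["Smith"])
        assert not result.reviews
        path = tmp_path / "review.csv"
        export_review(result, path)
        resolved = import_review(result, path)
        assert len(resolved.matches) == len(result.matches)

    def test_export_is_deterministic(self, tmp_path, result_with_reviews):
        result, _ = result_with_reviews
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        export_review(result, a)
        export_review(result, b)
        assert a.read_bytes() == b.read_bytes()
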