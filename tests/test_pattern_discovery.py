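import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import apclust as ap
from apclust.errors import DegenerateModelError, ValidationError

from .oracles import brute_force_discover, census


def naive_window_scan(strings, word):
    """Inline occurrence counter: every (k, start) with an exact window."""
    hits = set()
    for k, s in enumerate(strings, start=1):
        for i in range(len(s) - len(word) + 1):
            if s[i : i + len(word)] == word:
                hits.add((k, i + 1))
    return hits


def make_pattern(word, windows):
    occs = tuple(ap.Occurrence(k, start, start + len(word) - 1) for k, start in sorted(windows))
    return ap.Pattern(string=word, occurrences=occs)


class TestEnumerate:
    def test_worked_example_counts_match_direct_scan(self, worked_sequences, text_alphabet):
        cands = ap.enumerate_candidates(worked_sequences, 5, 5, text_alphabet)
        strings = [s.residues for s in worked_sequences]
        by_string = {p.string: p for p in cands}
        for word in ("HELLO", "MELLOW", "MELLO", "ELLOW"):
            expected = naive_window_scan(strings, word)
            assert word in by_string
            assert {(o.seq_index, o.start) for o in by_string[word].occurrences} == expected

    def test_unreachable_floor_gives_empty_list(self, worked_sequences, text_alphabet):
        assert ap.enumerate_candidates(worked_sequences, 5, 1000, text_alphabet) == []

    def test_empty_data_space_rejected(self, text_alphabet):
        with pytest.raises(ValidationError):
            ap.enumerate_candidates(ap.SequenceSet(sequences=()), 2, 2, text_alphabet)

    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_nested_loop_census(self, seed):
        rng = random.Random(seed)
        strings = ["".join(rng.choice("ABCD") for _ in range(rng.randint(5, 30)))
                   for _ in range(rng.randint(1, 8))]
        alphabet = ap.Alphabet.from_string("ABCD")
        S = ap.SequenceSet.from_strings(strings, alphabet=alphabet)
        got = {
            (p.string, frozenset((o.seq_index, o.start) for o in p.occurrences))
            for p in ap.enumerate_candidates(S, 2, 3, alphabet)
        }
        want = {
            (sub, frozenset(occ)) for sub, occ in census(strings, 2, 3).items()
        }
        assert got == want

    def test_anti_monotone_support(self, worked_sequences, text_alphabet):
        cands = ap.enumerate_candidates(worked_sequences, 5, 5, text_alphabet)
        counts = {p.string: p.occurrence_count for p in cands}
        strings = [s.residues for s in worked_sequences]
        for p in cands:
            for cut in (p.string[:-1], p.string[1:]):
                if len(cut) >= 5:
                    assert len(naive_window_scan(strings, cut)) >= counts[p.string]


class TestNullModel:
    def test_single_symbol_expectation(self, text_alphabet):
        S = ap.SequenceSet.from_strings(["A" * 30], alphabet=text_alphabet)
        p = make_pattern("A", {(1, 1)})
        assert ap.pattern_expected_occurrences(p, S, text_alphabet) == pytest.approx(30 / 26)

    def test_worked_five_letter_expectation(self, text_alphabet):
        s = ap.hello_example_sequence()
        S = ap.SequenceSet(sequences=(s,))
        p = make_pattern("HELLO", {(1, 13)})
        assert ap.pattern_expected_occurrences(p, S, text_alphabet) == pytest.approx(25 * 26.0**-5)

    def test_expectation_matches_window_arithmetic(self, worked_sequences, text_alphabet):
        p = make_pattern("HELLO", naive_window_scan([s.residues for s in worked_sequences], "HELLO"))
        e0 = ap.pattern_expected_occurrences(p, worked_sequences, text_alphabet)
        assert e0 == pytest.approx(ap.window_count(worked_sequences, 5) / 26**5)

    def test_residual_zero_at_expectation(self, text_alphabet):
        # two windows of length 1 over a 2-letter alphabet: e0 = 2 * 1/2 = 1 = o
        alphabet = ap.Alphabet.from_string("AB")
        S = ap.SequenceSet.from_strings(["AB"], alphabet=alphabet)
        p = make_pattern("A", {(1, 1)})
        assert ap.pattern_standard_residual(p, S, alphabet) == pytest.approx(0.0)

    def test_residual_formula_and_denominator_switch(self, worked_sequences, text_alphabet):
        p = make_pattern("HELLO", naive_window_scan([s.residues for s in worked_sequences], "HELLO"))
        e0 = ap.pattern_expected_occurrences(p, worked_sequences, text_alphabet)
        o = p.occurrence_count
        assert ap.pattern_standard_residual(p, worked_sequences, text_alphabet) == pytest.approx(
            (o - e0) / math.sqrt(e0)
        )
        assert ap.pattern_standard_residual(
            p, worked_sequences, text_alphabet, residual_denominator="plain"
        ) == pytest.approx((o - e0) / e0)

    def test_empirical_background_uses_observed_frequencies(self, text_alphabet):
        S = ap.SequenceSet.from_strings(["AAAB"], alphabet=text_alphabet)
        p = make_pattern("A", {(1, 1), (1, 2), (1, 3)})
        e0 = ap.pattern_expected_occurrences(p, S, text_alphabet, background="empirical")
        assert e0 == pytest.approx(4 * 0.75)

    def test_gapped_pattern_rejected(self, worked_sequences, text_alphabet):
        with pytest.raises(ValidationError):
            ap.pattern_expected_occurrences(
                ap.Pattern(string="HE-LO"), worked_sequences, text_alphabet
            )


class TestPruning:
    def test_delta_closure_keeps_only_the_super_pattern(self):
        mellow = make_pattern("MELLOW", {(k, 1) for k in range(1, 6)})
        ellow = make_pattern("ELLOW", {(k, 2) for k in range(1, 6)})
        mello = make_pattern("MELLO", {(k, 1) for k in range(1, 6)})
        out = ap.prune_delta_closed([mellow, ellow, mello], delta=0.9)
        assert [p.string for p in out] == ["MELLOW"]

    def test_tight_delta_keeps_everything(self):
        big = make_pattern("ABCD", {(k, 1) for k in range(1, 11)})
        small = make_pattern("ABC", {(k, 1) for k in range(1, 101)})
        assert ap.prune_delta_closed([big, small], delta=0.5) == [big, small]

    @given(seed=st.integers(0, 2_000))
    def test_matches_pairwise_containment_scan(self, seed):
        rng = random.Random(seed)
        words = list({
            "".join(rng.choice("AB") for _ in range(rng.randint(2, 5)))
            for _ in range(rng.randint(2, 6))
        })
        pats = [
            make_pattern(w, {(k, 1) for k in range(1, rng.randint(2, 9))}) for w in words
        ]
        delta = rng.choice([0.5, 0.8, 0.9, 1.0])
        got = {p.string for p in ap.prune_delta_closed(pats, delta)}
        want = {
            p.string
            for p in pats
            if not any(
                q.string != p.string
                and p.string in q.string
                and q.occurrence_count >= delta * p.occurrence_count
                for q in pats
            )
        }
        assert got == want

    def test_long_extension_is_retained(self, text_alphabet):
        # occ(p) == occ(q) with three extra residues: e_cond = occ/26^3 << o
        S = ap.SequenceSet.from_strings(["ABCDEF" * 3], alphabet=text_alphabet)
        q = make_pattern("ABC", {(1, 1), (1, 7), (1, 13)})
        p = make_pattern("ABCDEF", {(1, 1), (1, 7), (1, 13)})
        out = ap.prune_induced([p, q], S, text_alphabet, significance_threshold=0.0)
        assert p in out

    def test_chance_rate_extension_is_removed(self, text_alphabet):
        # p extends q by one symbol and occurs exactly occ(q)/26 = 1 time:
        # conditional residual 0, below any positive threshold
        S = ap.SequenceSet.from_strings(["A" * 100], alphabet=text_alphabet)
        q = make_pattern("ABC", {(1, i) for i in range(1, 27)})
        p = make_pattern("ABCD", {(1, 1)})
        out = ap.prune_induced([p, q], S, text_alphabet, significance_threshold=3.0)
        assert [x.string for x in out] == ["ABC"]

    def test_sub_pattern_forced_by_super_pattern_is_removed(self, worked_sequences, text_alphabet):
        """A shorter pattern whose count barely exceeds its super-pattern's is
        redundant: the excess is tested against chance."""
        strings = [s.residues for s in worked_sequences]
        mellow = make_pattern("MELLOW", naive_window_scan(strings, "MELLOW"))
        ellow = make_pattern("ELLOW", naive_window_scan(strings, "ELLOW"))
        assert ellow.occurrence_count == 6  # one extra from 'HELLOw' in s5
        out = ap.prune_induced([mellow, ellow], worked_sequences, text_alphabet, significance_threshold=3.0)
        assert [p.string for p in out] == ["MELLOW"]


class TestDiscover:
    def test_worked_example_yields_the_two_planted_words(self, worked_patterns):
        assert [p.string for p in worked_patterns] == ["MELLOW", "HELLO"]

    def test_scores_sorted_descending(self, worked_patterns):
        scores = [p.score for p in worked_patterns]
        assert scores == sorted(scores, reverse=True)

    def test_every_occurrence_verifies_by_substring(self, worked_sequences, worked_patterns):
        assert all(p.verify_against(worked_sequences) for p in worked_patterns)

    def test_no_repeats_gives_empty_result(self, text_alphabet):
        S = ap.SequenceSet.from_strings(["ABCDEFGHIJ", "KLMNOPQRST"], alphabet=text_alphabet)
        cfg = ap.DiscoveryConfig(min_order=3, min_occurrence=2, delta=0.9)
        assert ap.discover(S, cfg, text_alphabet) == []

    def test_deterministic_across_runs(self, worked_sequences, text_alphabet):
        cfg = ap.DiscoveryConfig(min_order=5, min_occurrence=5, delta=0.9)
        a = ap.discover(worked_sequences, cfg, text_alphabet)
        b = ap.discover(worked_sequences, cfg, text_alphabet)
        assert a == b

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        alphabet = ap.Alphabet.from_string("ABCD")
        strings = ["".join(rng.choice("ABCD") for _ in range(rng.randint(10, 36)))
                   for _ in range(8)]
        assert sum(map(len, strings)) <= 300
        S = ap.SequenceSet.from_strings(strings, alphabet=alphabet)
        cfg = ap.DiscoveryConfig(min_order=3, min_occurrence=3, delta=0.9)
        got = {
            (p.string, frozenset((o.seq_index, o.start) for o in p.occurrences))
            for p in ap.discover(S, cfg, alphabet)
        }
        want = brute_force_discover(strings, 4, 3, 3, 0.9, 3.0)
        assert got == want


class TestSerialization:
    def test_round_trip(self, tmp_path, worked_patterns):
        tsv, sidecar = tmp_path / "p.tsv", tmp_path / "p.json"
        ap.pattern_discovery.write_patterns(worked_patterns, tsv, sidecar)
        again = ap.pattern_discovery.read_patterns(tsv, sidecar)
        assert again == worked_patterns


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_order": 0},
            {"min_occurrence": 0},
            {"delta": 0.0},
            {"delta": 1.5},
            {"background": "markov"},
            {"residual_denominator": "cube"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ap.DiscoveryConfig(**kwargs)
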