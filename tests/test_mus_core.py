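"""Anchor extraction, repeat detection, and occurrence lookup."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmusdbg import (
    AnchorSet,
    ReadSet,
    UniquenessConfig,
    count_occurrences,
    extract_maximal_repeats,
    extract_mus,
    locate_occurrences,
    reverse_complement,
)
from vmusdbg.mus_core import sanitize_sequence, split_ambiguous

from conftest import TOY_MUS, random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def brute_force_mus(text: str, circular: bool = False) -> list[str]:
    """Independent oracle: enumerate substrings, count, apply minimality."""
    n = len(text)
    found = set()
    for i in range(n):
        for length in range(1, n + 1 if circular else n - i + 1):
            w = (text + text)[i : i + length]
            if count_occurrences(text, w, circular=circular) == 1:
                if length == 1 or count_occurrences(text, w[1:], circular=circular) >= 2:
                    found.add(w)
                break
    return sorted(found)


class TestExtractMus:
    def test_worked_example_circular_genome(self):
        anchors = extract_mus("ATGCTAGCAC", UniquenessConfig(circular=True))
        assert anchors.words == TOY_MUS

    def test_homopolymer_only_unique_substring_is_whole_string(self):
        assert extract_mus("AAAA", UniquenessConfig()).words == ["AAAA"]

    def test_all_distinct_characters_each_is_minimal(self):
        assert extract_mus("ACGT", UniquenessConfig()).words == ["A", "C", "G", "T"]

    def test_empty_and_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            extract_mus("", UniquenessConfig())
        with pytest.raises(ValueError):
            extract_mus("ACGNT", UniquenessConfig())
        with pytest.raises(ValueError):
            extract_mus(ReadSet([]), UniquenessConfig(scope="reads"))

    @pytest.mark.parametrize("backend", ["suffix_array", "suffix_tree", "brute_force"])
    @pytest.mark.parametrize("circular", [False, True])
    def test_backends_match_enumeration_oracle(self, backend, circular):
        rng = random.Random(7 if circular else 8)
        for _ in range(25):
            text = random_dna(rng, rng.randint(1, 80))
            config = UniquenessConfig(backend=backend, circular=circular)
            assert extract_mus(text, config).words == brute_force_mus(text, circular)

    def test_reverse_complement_scope_removes_palindromic_uniqueness(self):
        # In ACGT every 1-mer is unique forward-only; counting both strands,
        # A also matches the reverse complement of T (and vice versa).
        fwd = extract_mus("ACGT", UniquenessConfig()).words
        both = extract_mus("ACGT", UniquenessConfig(use_reverse_complement=True)).words
        assert fwd == ["A", "C", "G", "T"]
        assert "A" not in both and "T" not in both

    def test_reads_scope_counts_across_the_whole_set(self):
        reads = ReadSet.from_pairs([("a", "ACGTT"), ("b", "ACGAA")])
        words = extract_mus(reads, UniquenessConfig(scope="reads")).words
        # ACG occurs in both reads, so nothing inside it can be unique;
        # every returned word must occur exactly once across the set
        for w in words:
            total = sum(count_occurrences(r.seq, w) for r in reads)
            assert total == 1

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(dna)
    def test_minimality_and_anti_nesting_invariants(self, text):
        anchors = extract_mus(text, UniquenessConfig())
        words = anchors.words
        for w in words:
            assert count_occurrences(text, w) == 1
            if len(w) >= 2:
                assert count_occurrences(text, w[1:]) >= 2
                assert count_occurrences(text, w[:-1]) >= 2
        for a in words:
            for b in words:
                if a != b:
                    assert a not in b

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(dna)
    def test_extraction_is_deterministic(self, text):
        cfg = UniquenessConfig()
        assert extract_mus(text, cfg).words == extract_mus(text, cfg).words

    def test_anchors_mark_maximal_repeat_endpoints(self):
        # for each repeat occurrence some anchor starts at or after the
        # occurrence start and extends past its end, i.e. anchors delimit
        # repeats on the right; inapplicable when the occurrence runs to the
        # text end or a longer repeat swallows the remaining suffix
        rng = random.Random(3)
        for _ in range(10):
            text = random_dna(rng, 120)
            anchors = extract_mus(text, UniquenessConfig())
            placed = [(text.find(w), len(w)) for w in anchors.words]
            for rep in extract_maximal_repeats(text):
                for pos in rep.positions:
                    p0 = pos - 1
                    end0 = p0 + len(rep.word)  # 0-based end-exclusive
                    if end0 >= len(text) or count_occurrences(text, text[p0:]) != 1:
                        continue
                    assert any(s >= p0 and s + L > end0 for s, L in placed)


class TestMaximalRepeats:
    def test_worked_example_gc_repeat(self):
        repeats = {(r.word, r.occurrence_count, r.positions)
                   for r in extract_maximal_repeats("ATGCTAGCAC")}
        assert ("GC", 2, (3, 7)) in repeats

    def test_no_repeats_in_all_distinct(self):
        assert extract_maximal_repeats("ACGT") == []

    def test_toy_alphabet_example(self):
        repeats = {(r.word, r.positions) for r in extract_maximal_repeats("AABAA")}
        assert ("AA", (1, 4)) in repeats

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extract_maximal_repeats("")

    def test_matches_brute_force_on_random_strings(self):
        def oracle(text):
            n = len(text)
            out = set()
            for i in range(n):
                for j in range(i + 1, n + 1):
                    w = text[i : j]
                    occ = [k for k in range(n - len(w) + 1) if text[k : k + len(w)] == w]
                    if len(occ) < 2:
                        continue
                    left = {text[p - 1] if p else ("^", p) for p in occ}
                    right = {text[p + len(w)] if p + len(w) < n else ("$", p) for p in occ}
                    if len(left) >= 2 and len(right) >= 2:
                        out.add((w, tuple(p + 1 for p in occ)))
            return out

        rng = random.Random(11)
        for _ in range(15):
            text = random_dna(rng, rng.randint(2, 60))
            got = {(r.word, r.positions) for r in extract_maximal_repeats(text)}
            assert got == oracle(text)


class TestOccurrences:
    @pytest.mark.parametrize(
        "read,expected",
        [
            ("ATGCTA", [("AT", 1, 2), ("TG", 2, 3), ("CT", 4, 5), ("TA", 5, 6)]),
            ("GCTAGC", [("CT", 2, 3), ("TA", 3, 4), ("AG", 4, 5)]),
            ("TAGCAC", [("TA", 1, 2), ("AG", 2, 3), ("GCA", 3, 5), ("AC", 5, 6)]),
            ("GCACAT", [("GCA", 1, 3), ("AC", 3, 4), ("AT", 5, 6)]),
            ("ACATGC", [("AC", 1, 2), ("AT", 3, 4), ("TG", 4, 5)]),
            ("CCCC", []),
        ],
    )
    def test_toy_reads_reproduce_published_table(self, toy_anchors, read, expected):
        occ = locate_occurrences(("r", read), 0, toy_anchors)
        assert [(o.word, o.start, o.end) for o in occ] == expected

    def test_occurrences_sorted_and_consistent(self, toy_anchors):
        occ = locate_occurrences(("r", "ATGCTAGCACATGCTA"), 0, toy_anchors)
        starts = [o.start for o in occ]
        assert starts == sorted(starts) and len(set(starts)) == len(starts)
        for o in occ:
            assert "ATGCTAGCACATGCTA"[o.start - 1 : o.end] == o.word

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            locate_occurrences(("r", "ACGT"), 0, AnchorSet([]))


class TestCountOccurrences:
    @pytest.mark.parametrize(
        "text,word,kw,expected",
        [
            ("ATGCTAGCAC", "GC", {}, 2),
            ("ATGCTAGCAC", "AT", {}, 1),
            ("AAA", "AA", {}, 2),  # overlapping matches count
            ("ATGCTAGCAC", "CA", {"circular": True}, 2),  # wraps 10 -> 1
            ("ATGCTAGCAC", "CA", {}, 1),
            ("ACGT", "ACGTA", {}, 0),  # longer than text, not an error
            ("AT", "AT", {"use_rc": True}, 2),  # AT is its own reverse complement
        ],
    )
    def test_examples(self, text, word, kw, expected):
        assert count_occurrences(text, word, **kw) == expected

    def test_reverse_complement_helper(self):
        assert reverse_complement("ATGC") == "GCAT"
        assert reverse_complement(reverse_complement("ACCGT")) == "ACCGT"


class TestSanitization:
    def test_lowercase_uppercased_and_invalid_rejected(self):
        assert sanitize_sequence("acgt") == "ACGT"
        with pytest.raises(ValueError):
            sanitize_sequence("ACGX")

    def test_ambiguous_runs_split(self):
        assert split_ambiguous("ACGTNNNACG") == ["ACGT", "ACG"]
        assert split_ambiguous("NNN") == []

    def test_readset_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            ReadSet.from_pairs([("a", "ACGT"), ("a", "GGCC")])
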