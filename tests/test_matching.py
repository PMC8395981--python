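import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segmatch import (
    MatchConfig,
    build_match_tables,
    canonical,
    classify_microsatellite,
    count_pair_matches,
    enumerate_fragments,
    is_simple_repeat,
    revcomp,
)
from conftest import make_section_set, oracle_pair_count, random_dna

dna = st.text(alphabet="acgt", min_size=0, max_size=60)


class TestRevcomp:
    @pytest.mark.parametrize("seq,expected", [("acgt", "acgt"), ("aac", "gtt")])
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(dna.filter(lambda s: len(s) > 0))
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_rejects_n(self):
        with pytest.raises(ValueError):
            revcomp("acn")


class TestSimpleRepeat:
    @pytest.mark.parametrize(
        "frag,expected",
        [
            ("caaaag", True),  # internal mononucleotide run of 4
            ("gatatatc", True),  # three dinucleotides
            ("acgacgt", True),  # two trinucleotides
            ("acgtacgt", False),  # unit length 4 not covered by default rules
            ("aaat", False),  # run of 3 < 4
        ],
    )
    def test_default_rules(self, frag, expected):
        assert is_simple_repeat(frag) is expected

    @settings(derandomize=True, max_examples=200)
    @given(dna.filter(lambda s: len(s) >= 1))
    def test_agrees_with_regex_oracle(self, s):
        import re

        oracle = bool(re.search(r"(.)\1{3}|(..)\2{2}|(...)\3", s))
        assert is_simple_repeat(s) is oracle


class TestEnumerate:
    def test_window_count(self):
        assert enumerate_fragments("acgta", MatchConfig(L=4)) == [
            (0, "acgt"),
            (1, "cgta"),
        ]

    def test_n_windows_skipped(self):
        assert enumerate_fragments("acnta", MatchConfig(L=4)) == []

    def test_repeat_filter(self):
        assert enumerate_fragments("aaaaa", MatchConfig(L=4, exclude_repeats=True)) == []

    def test_short_sequence_empty(self):
        assert enumerate_fragments("ac", MatchConfig(L=4)) == []

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="acgtn", min_size=0, max_size=80), st.integers(2, 8))
    def test_matches_naive_window_scan(self, s, L):
        got = enumerate_fragments(s, MatchConfig(L=L))
        want = [
            (i, s[i : i + L])
            for i in range(max(0, len(s) - L + 1))
            if "n" not in s[i : i + L]
        ]
        assert got == want


class TestPairCount:
    @pytest.mark.parametrize(
        "a,b,L,expected",
        [
            ("aaaa", "aaaa", 2, 9),  # 3x3 forward "aa" pairs
            ("at", "at", 2, 1),  # palindromic double hit counted once
            ("acg", "cgt", 3, 1),  # reverse-complement only
            ("acgt", "tttt", 4, 0),
        ],
    )
    def test_examples(self, a, b, L, expected):
        count, _ = count_pair_matches(a, b, MatchConfig(L=L))
        assert count == expected
        assert count == oracle_pair_count(a, b, L)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(dna, dna, st.integers(2, 8))
    def test_symmetry(self, a, b, L):
        cfg = MatchConfig(L=L)
        assert count_pair_matches(a, b, cfg)[0] == count_pair_matches(b, a, cfg)[0]

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(dna, dna, st.integers(2, 7))
    def test_monotone_in_L(self, a, b, L):
        c1 = count_pair_matches(a, b, MatchConfig(L=L))[0]
        c2 = count_pair_matches(a, b, MatchConfig(L=L + 1))[0]
        assert c2 <= c1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(dna, dna, st.integers(2, 8))
    def test_filter_monotone(self, a, b, L):
        on = count_pair_matches(a, b, MatchConfig(L=L, exclude_repeats=True))[0]
        off = count_pair_matches(a, b, MatchConfig(L=L))[0]
        assert on <= off

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(dna.filter(lambda s: len(s) > 0), dna.filter(lambda s: len(s) > 0), st.integers(2, 8))
    def test_orientation_invariance(self, a, b, L):
        cfg = MatchConfig(L=L)
        assert (
            count_pair_matches(a, b, cfg)[0] == count_pair_matches(a, revcomp(b), cfg)[0]
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.text(alphabet="acgtn", max_size=60),
        st.text(alphabet="acgtn", max_size=60),
        st.integers(2, 8),
        st.booleans(),
    )
    def test_oracle_equivalence(self, a, b, L, filt):
        cfg = MatchConfig(L=L, exclude_repeats=filt)
        assert count_pair_matches(a, b, cfg)[0] == oracle_pair_count(a, b, L, filt)


class TestMatchTables:
    def test_three_section_example(self):
        ss = make_section_set(["aaaa", "aaaa", "cccc"])
        table, catalog = build_match_tables(ss, MatchConfig(L=2))
        assert table.counts[0, 1] == 9
        assert table.counts[0, 2] == 0
        assert table.counts[1, 2] == 0
        assert catalog.no == {"aa": 9}

    def test_homopolymers_filtered_to_zero(self):
        ss = make_section_set(["aaaaaa", "tttttt", "gggggg"])
        table, _ = build_match_tables(ss, MatchConfig(L=4, exclude_repeats=True))
        assert not table.counts.any()

    def test_no_conservation(self, toy_sections):
        table, catalog = build_match_tables(toy_sections, MatchConfig(L=4))
        assert catalog.total() == table.total()

    def test_counts_match_pairwise_oracle(self, toy_sections):
        cfg = MatchConfig(L=6)
        table, _ = build_match_tables(toy_sections, cfg)
        for i in range(3):
            for j in range(i + 1, 4):
                expect = count_pair_matches(
                    toy_sections[i].sequence, toy_sections[j].sequence, cfg
                )[0]
                assert table.counts[i, j] == expect

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        seqs = [random_dna(rng, 150) for _ in range(4)]
        perm = [2, 0, 3, 1]
        t1, _ = build_match_tables(make_section_set(seqs), MatchConfig(L=4))
        t2, _ = build_match_tables(
            make_section_set([seqs[p] for p in perm]), MatchConfig(L=4)
        )
        for a in range(4):
            for b in range(4):
                assert t2.counts[a, b] == t1.counts[perm[a], perm[b]]

    def test_symmetric_with_zero_diagonal(self, toy_sections):
        table, _ = build_match_tables(toy_sections, MatchConfig(L=5))
        assert (table.counts == table.counts.T).all()
        assert not np.diag(table.counts).any()


class TestCanonicalAndMicrosatellite:
    @settings(derandomize=True, max_examples=100)
    @given(dna.filter(lambda s: len(s) > 0))
    def test_canonical_strand_agnostic(self, s):
        assert canonical(s) == canonical(revcomp(s))

    @pytest.mark.parametrize(
        "frag,motif",
        [
            ("atatatatat", "at"),
            ("tcccagtcccagtcccag", "tcccag"),
            ("gattacagatt", None),
            ("aaaaaa", "a"),
            ("gatagatagata", "gata"),
        ],
    )
    def test_examples(self, frag, motif):
        assert classify_microsatellite(frag) == motif

    def test_exhaustive_motif_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            frag = random_dna(rng, int(rng.integers(2, 20)))
            got = classify_microsatellite(frag)
            # oracle: smallest motif length whose tiling reproduces frag
            want = None
            for p in range(1, 7):
                if len(frag) >= 2 * p and (frag[:p] * len(frag))[: len(frag)] == frag:
                    want = frag[:p]
                    break
            assert got == want
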