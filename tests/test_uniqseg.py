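from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbrscout import seqio, uniqseg
from hbrscout.errors import InputError
from helpers import oracle_flags, oracle_unique_segments, random_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def family_from(seqs: dict[str, str]) -> seqio.SequenceFamily:
    return seqio.SequenceFamily.of(
        [seqio.SequenceRecord(i, s) for i, s in seqs.items()]
    )


class TestBuildIndex:
    def test_single_member_single_kmer(self):
        index = uniqseg.build_index(family_from({"a": "AAAA"}), L=3)
        assert dict(index.carriers) == {"AAA": frozenset({"a"})}

    def test_two_member_carriers(self, toy_family):
        index = uniqseg.build_index(toy_family, L=3)
        assert index.carriers["RCK"] == {"a", "b"}
        assert index.carriers["NYR"] == {"a"}
        assert index.carriers["NYQ"] == {"b"}

    def test_member_shorter_than_pattern_rejected(self):
        family = family_from({"a": "NY", "b": "NYRWRC"})
        with pytest.raises(InputError, match="a"):
            uniqseg.build_index(family, L=3)

    def test_every_carrier_contains_its_pattern(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            seqs = random_family(rng, 5, 30, AA[:8])
            index = uniqseg.build_index(family_from(seqs), L=3)
            for pattern, ids in index.carriers.items():
                for mid in ids:
                    assert pattern in seqs[mid]
                for mid in set(seqs) - ids:
                    assert pattern not in seqs[mid]


class TestUniquenessMask:
    def test_hand_example(self, toy_family):
        index = uniqseg.build_index(toy_family, L=3)
        mask = uniqseg.uniqueness_mask(index, toy_family["a"], m=1)
        assert mask.flags == (True, True, True, True, False, False, False, False)

    def test_m_equal_family_size_flags_everything(self, toy_family):
        index = uniqseg.build_index(toy_family, L=3)
        mask = uniqseg.uniqueness_mask(index, toy_family["a"], m=2)
        assert all(mask.flags)

    def test_identical_members_flag_nothing(self):
        family = family_from({"a": "NYRWRCKNQN", "b": "NYRWRCKNQN"})
        index = uniqseg.build_index(family, L=3)
        mask = uniqseg.uniqueness_mask(index, family["a"], m=1)
        assert not any(mask.flags)

    def test_unindexed_member_rejected(self, toy_family):
        index = uniqseg.build_index(toy_family, L=3)
        stranger = seqio.SequenceRecord("z", "WWWWWWW")
        with pytest.raises(InputError, match="z"):
            uniqseg.uniqueness_mask(index, stranger, m=1)


class TestMergeSegments:
    def test_single_run(self, toy_family):
        index = uniqseg.build_index(toy_family, L=3)
        mask = uniqseg.uniqueness_mask(index, toy_family["a"], m=1)
        segments = uniqseg.merge_segments(mask, toy_family["a"], index)
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.start, seg.end, seg.text, seg.level) == (1, 6, "NYRWRC", 1)

    def test_all_false_yields_empty(self):
        family = family_from({"a": "NYRWRCK", "b": "NYRWRCK"})
        index = uniqseg.build_index(family, L=3)
        mask = uniqseg.uniqueness_mask(index, family["a"], m=1)
        assert uniqseg.merge_segments(mask, family["a"], index) == []

    def test_two_isolated_runs_not_merged(self):
        # member length 7, runs at starts {1} and {5} only
        member = seqio.SequenceRecord("a", "ACDEFGH")
        mask = uniqseg.UniquenessMask("a", (True, False, False, False, True), m=1, L=3)
        segments = uniqseg.merge_segments(mask, member)
        assert [(s.start, s.end) for s in segments] == [(1, 3), (5, 7)]
        assert [s.text for s in segments] == ["ACD", "FGH"]

    def test_mask_member_mismatch_rejected(self):
        member = seqio.SequenceRecord("a", "ACDEFGH")
        mask = uniqseg.UniquenessMask("a", (True,), m=1, L=3)
        with pytest.raises(InputError):
            uniqseg.merge_segments(mask, member)


class TestUniqueSegments:
    def test_disjoint_members_give_full_length_segments(self):
        rng = np.random.default_rng(7)
        while True:  # construct two 50-mers sharing no 3-mer
            a = "".join(AA[i] for i in rng.integers(10, size=50))
            b = "".join(AA[i + 10] for i in rng.integers(10, size=50))
            seqs = {"a": a, "b": b}
            if not set(oracle_flags(seqs, "a", 3, 1)) == {True}:
                continue
            break
        result = uniqseg.unique_segments(family_from(seqs), L=3, m=1)
        assert [(s.start, s.end) for s in result["a"]] == [(1, 50)]
        assert [(s.start, s.end) for s in result["b"]] == [(1, 50)]

    def test_requires_two_members(self):
        with pytest.raises(InputError):
            uniqseg.unique_segments(family_from({"a": "NYRWRC"}))

    def test_matches_oracle_on_random_families(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            k = int(rng.integers(4, 21))
            seqs = random_family(rng, n, 60, AA[:k])
            got = uniqseg.unique_segments(family_from(seqs), L=3, m=1)
            want = oracle_unique_segments(seqs, 3, 1)
            for mid in seqs:
                assert [(s.start, s.end, s.text) for s in got[mid]] == want[mid]

    def test_maximality(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            seqs = random_family(rng, 4, 40, AA[:6])
            family = family_from(seqs)
            index = uniqseg.build_index(family, L=3)
            for mid, segments in uniqseg.unique_segments(family, L=3, m=1).items():
                flags = oracle_flags(seqs, mid, 3, 1)
                for seg in segments:
                    run_lo, run_hi = seg.start - 1, seg.end - 3  # 0-based starts
                    assert all(flags[run_lo : run_hi + 1])
                    if run_lo > 0:
                        assert not flags[run_lo - 1]
                    if run_hi + 1 < len(flags):
                        assert not flags[run_hi + 1]

    def test_independent_of_member_order(self):
        rng = np.random.default_rng(17)
        seqs = random_family(rng, 5, 40, AA[:6])
        fwd = uniqseg.unique_segments(family_from(seqs), L=3, m=1)
        rev = uniqseg.unique_segments(
            family_from(dict(reversed(list(seqs.items())))), L=3, m=1
        )
        assert {m: [(s.start, s.end) for s in v] for m, v in fwd.items()} == {
            m: [(s.start, s.end) for s in v] for m, v in rev.items()
        }


@settings(max_examples=40, deadline=None)
@given(
    st.dictionaries(
        st.sampled_from(["a", "b", "c", "d"]),
        st.text(alphabet=AA[:5], min_size=4, max_size=30),
        min_size=2,
        max_size=4,
    ),
    st.integers(min_value=1, max_value=3),
)
def test_flags_monotone_in_level(seqs, m):
    family = family_from(seqs)
    index = uniqseg.build_index(family, L=3)
    for mid in seqs:
        lo = uniqseg.uniqueness_mask(index, family[mid], m=m).flags
        hi = uniqseg.uniqueness_mask(index, family[mid], m=m + 1).flags
        assert all(h or not l for l, h in zip(lo, hi))


@settings(max_examples=40, deadline=None)
@given(
    st.dictionaries(
        st.sampled_from(["a", "b", "c"]),
        st.text(alphabet=AA[:5], min_size=5, max_size=30),
        min_size=2,
        max_size=3,
    )
)
def test_flags_monotone_in_pattern_length(seqs):
    family = family_from(seqs)
    idx3 = uniqseg.build_index(family, L=3)
    idx4 = uniqseg.build_index(family, L=4)
    for mid in seqs:
        f3 = uniqseg.uniqueness_mask(idx3, family[mid], m=1).flags
        f4 = uniqseg.uniqueness_mask(idx4, family[mid], m=1).flags
        # a unique 3-window start stays unique when extended to 4 residues
        for i, flag in enumerate(f4):
            if f3[i]:
                assert flag


def test_segments_nested_across_levels():
    rng = np.random.default_rng(23)
    for _ in range(10):
        seqs = random_family(rng, 5, 40, AA[:5])
        family = family_from(seqs)
        for m in (1, 2):
            lo = uniqseg.unique_segments(family, L=3, m=m)
            hi = uniqseg.unique_segments(family, L=3, m=m + 1)
            for mid in seqs:
                for seg in lo[mid]:
                    assert any(
                        parent.start <= seg.start and parent.end >= seg.end
                        for parent in hi[mid]
                    )
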