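"""Extraction of member-unique peptide segments from a protein family.

The atomic unit is the fixed-length *primary pattern* (default 3 residues).
A pattern is unique at level ``m`` when at most ``m`` family members carry it
anywhere in their sequence (the carrying member itself included; within-member
repeats do not matter).  Maximal runs of consecutive unique pattern starts are
merged bottom-up into unique segments.

Note that two maximal runs separated by a single non-unique start yield
segments whose residue spans may share up to ``L - 1`` residues; runs (start
positions) are always disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import InputError
from .seqio import SequenceFamily, SequenceRecord


@dataclass(frozen=True)
class PrimaryPatternIndex:
    """Carrier index: each length-L substring -> set of member ids containing it."""

    L: int
    carriers: Mapping[str, frozenset[str]]

    def carrier_count(self, pattern: str) -> int:
        return len(self.carriers.get(pattern, frozenset()))


@dataclass(frozen=True)
class UniquenessMask:
    """Per-start boolean flags: True where the L-window occurs in <= m members."""

    member: str
    flags: tuple[bool, ...]
    m: int
    L: int


@dataclass(frozen=True)
class UniqueSegment:
    """Maximal run of member-unique primary patterns, 1-based inclusive span."""

    member: str
    start: int
    end: int
    text: str
    level: int

    def __post_init__(self) -> None:
        if len(self.text) != self.end - self.start + 1:
            raise ValueError("segment text does not match its span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def build_index(family: SequenceFamily, L: int = 3) -> PrimaryPatternIndex:
    """Index every length-L substring of the family to its carrier-member set.

    Exact substring matching; occurrence multiplicity within one member does
    not change carrier-set membership.
    """
    if L < 1:
        raise InputError(f"primary pattern length must be >= 1, got {L}")
    for rec in family:
        if len(rec) < L:
            raise InputError(
                f"member {rec.id!r} is shorter ({len(rec)}) than pattern length {L}"
            )
    carriers: dict[str, set[str]] = {}
    for rec in family:
        seq = rec.residues
        for i in range(len(seq) - L + 1):
            carriers.setdefault(seq[i : i + L], set()).add(rec.id)
    return PrimaryPatternIndex(
        L, {p: frozenset(ids) for p, ids in carriers.items()}
    )


def uniqueness_mask(
    index: PrimaryPatternIndex, member: SequenceRecord, m: int = 1
) -> UniquenessMask:
    """Flag each pattern start of ``member`` whose carrier count is <= m."""
    if m < 1:
        raise InputError(f"uniqueness level must be >= 1, got {m}")
    L = index.L
    seq = member.residues
    n_windows = len(seq) - L + 1
    flags = []
    for i in range(n_windows):
        pattern = seq[i : i + L]
        count = index.carrier_count(pattern)
        if count == 0 or member.id not in index.carriers[pattern]:
            raise InputError(f"member {member.id!r} was not indexed")
        flags.append(count <= m)
    return UniquenessMask(member.id, tuple(flags), m, L)


def merge_segments(
    mask: UniquenessMask,
    member: SequenceRecord,
    index: PrimaryPatternIndex | None = None,
) -> list[UniqueSegment]:
    """Merge each maximal run of flagged starts into one segment.

    A run over (1-based) starts ``i..j`` yields the residue span
    ``[i, j + L - 1]``.  Strictly adjacent but non-overlapping unique patterns
    belong to different runs and are not merged.  The segment level is the
    maximum carrier count among its constituent patterns (equals 1 for m=1).
    """
    L = mask.L
    seq = member.residues
    if len(mask.flags) != len(seq) - L + 1:
        raise InputError(
            f"mask for {mask.member!r} does not match member {member.id!r}"
        )
    segments: list[UniqueSegment] = []
    run_start: int | None = None
    for i, flag in enumerate(list(mask.flags) + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            start, end = run_start + 1, i + L - 1  # 1-based inclusive
            text = seq[start - 1 : end]
            level = 1
            if index is not None:
                level = max(
                    index.carrier_count(seq[k : k + L])
                    for k in range(run_start, i)
                )
            segments.append(UniqueSegment(member.id, start, end, text, level))
            run_start = None
    return segments


def unique_segments(
    family: SequenceFamily, L: int = 3, m: int = 1
) -> dict[str, list[UniqueSegment]]:
    """Full extraction: index, mask, and merge for every family member."""
    if len(family) < 2:
        raise InputError("uniqueness analysis needs a family of >= 2 members")
    index = build_index(family, L)
    out: dict[str, list[UniqueSegment]] = {}
    for rec in family:
        mask = uniqueness_mask(index, rec, m)
        out[rec.id] = merge_segments(mask, rec, index)
    return out
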