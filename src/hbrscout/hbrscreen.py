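"""Screening of unique segments for cationic (putative heparin-binding) windows.

A fixed-width window qualifies when it contains at least ``b`` basic residues
and overlaps its parent unique segment by at least ``min_overlap`` residues.
Each segment is extended by ``flank`` residues on both sides before scanning:
a basic residue just outside the segment boundary (e.g. a catalytic lysine one
position past the segment end) may complete a cationic window.  Per segment a
single representative window is reported: maximal basic count, leftmost on
ties; the full qualifying list is available via ``collapse=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InputError
from .seqio import SequenceRecord
from .uniqseg import UniqueSegment

#: Histidine is only weakly protonated at physiological pH and is excluded
#: from the default basic set; include it via ScreenConfig(basic_set=...).
DEFAULT_BASIC_SET = frozenset("RK")


@dataclass(frozen=True)
class ScreenConfig:
    """Window screening parameters (all knobs exposed)."""

    w: int = 5
    b: int = 3
    basic_set: frozenset[str] = DEFAULT_BASIC_SET
    flank: int = 2
    min_overlap: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.b <= self.w:
            raise InputError(f"need 1 <= b <= w, got b={self.b}, w={self.w}")
        if self.flank < 0:
            raise InputError(f"flank must be >= 0, got {self.flank}")
        if not 1 <= self.min_overlap <= self.w:
            raise InputError(
                f"need 1 <= min_overlap <= w, got min_overlap={self.min_overlap}"
            )
        if not self.basic_set <= frozenset("ACDEFGHIKLMNPQRSTVWY"):
            raise InputError(f"basic_set contains non-residues: {self.basic_set}")


@dataclass(frozen=True)
class HBRCandidate:
    """Qualifying cationic window, 1-based inclusive, tied to a parent segment."""

    member: str
    start: int
    end: int
    window: str
    basic_count: int
    parent: tuple[int, int]


def basic_count(window: str, basic_set: frozenset[str] = DEFAULT_BASIC_SET) -> int:
    """Number of positions in ``window`` whose residue is in ``basic_set``."""
    if not window:
        raise InputError("empty window")
    return sum(1 for ch in window if ch in basic_set)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def screen_member(
    member: SequenceRecord,
    segments: Sequence[UniqueSegment],
    cfg: ScreenConfig = ScreenConfig(),
    collapse: bool = True,
) -> list[HBRCandidate]:
    """Scan each segment's flank-extended span for qualifying cationic windows.

    With ``collapse=True`` (default) one representative window per segment is
    returned (max basic count, leftmost tie-break); output sorted by start.
    """
    seq = member.residues
    n = len(seq)
    out: list[HBRCandidate] = []
    for seg in segments:
        if seg.member != member.id:
            raise InputError(
                f"segment for {seg.member!r} passed with member {member.id!r}"
            )
        lo = max(1, seg.start - cfg.flank)
        hi = min(n, seg.end + cfg.flank)
        qualifying: list[HBRCandidate] = []
        for w_start in range(lo, hi - cfg.w + 2):
            w_end = w_start + cfg.w - 1
            if _overlap(w_start, w_end, seg.start, seg.end) < cfg.min_overlap:
                continue
            window = seq[w_start - 1 : w_end]
            count = basic_count(window, cfg.basic_set)
            if count >= cfg.b:
                qualifying.append(
                    HBRCandidate(member.id, w_start, w_end, window, count, seg.span)
                )
        if not qualifying:
            continue
        if collapse:
            best = max(qualifying, key=lambda c: (c.basic_count, -c.start))
            out.append(best)
        else:
            out.extend(qualifying)
    return sorted(out, key=lambda c: (c.start, c.end))


def screen_family(
    family,
    segments_by_member: Mapping[str, Sequence[UniqueSegment]],
    cfg: ScreenConfig = ScreenConfig(),
    collapse: bool = True,
) -> dict[str, list[HBRCandidate]]:
    """Apply :func:`screen_member` per member; unknown member ids are errors."""
    out: dict[str, list[HBRCandidate]] = {}
    for member_id, segments in segments_by_member.items():
        if member_id not in family:
            raise InputError(f"segments refer to unknown member {member_id!r}")
        out[member_id] = screen_member(family[member_id], segments, cfg, collapse)
    return out
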