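"""Identity computations: positional motif identity and global alignment identity.

Motif identity is plain positional (Hamming) identity over equal-length,
pre-aligned motif strings; a gap character at either position is a mismatch
and the denominator is the full motif length.

Whole-protein identity is computed from a Needleman-Wunsch global alignment
with affine gaps (Gotoh three-state recursion): opening a gap costs
``gap_open`` and each extension ``gap_extend``.  Traceback tie-breaking is
deterministic: diagonal, then up (gap in the second sequence), then left.
Columns lying in a terminal gap run of either sequence are excluded from the
compared-position denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError
from .seqio import GAP, MotifRow, SequenceFamily, SequenceRecord

NEG_INF = float("-inf")


@dataclass(frozen=True)
class IdentityResult:
    query: str
    subject: str
    identical_positions: int
    compared_positions: int

    def __post_init__(self) -> None:
        if not 0 <= self.identical_positions <= self.compared_positions:
            raise ValueError("identical positions exceed compared positions")

    @property
    def percent(self) -> float:
        if self.compared_positions == 0:
            return 0.0
        return 100.0 * self.identical_positions / self.compared_positions


@dataclass(frozen=True)
class AlignParams:
    gap_open: float = 10.0
    gap_extend: float = 0.2
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")


# ---------------------------------------------------------------------------
# Motif-level (positional) identity


def motif_identity_percent(a: str, b: str, query: str = "a", subject: str = "b") -> IdentityResult:
    """Positional identity of two equal-length motif strings.

    Positions with equal non-gap residues count as identical; any position
    involving a gap is a mismatch; the denominator is the full length.
    """
    if len(a) != len(b):
        raise InputError(f"motif length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise InputError("empty motifs")
    identical = sum(
        1 for x, y in zip(a, b) if x == y and x != GAP
    )
    return IdentityResult(query, subject, identical, len(a))


def subwindow(motif: str, offset: int, width: int) -> str:
    """Contiguous slice of a motif; ``offset`` is 1-based within the motif."""
    if offset < 1 or offset + width - 1 > len(motif):
        raise InputError(
            f"subwindow {offset}..{offset + width - 1} outside motif of length {len(motif)}"
        )
    return motif[offset - 1 : offset - 1 + width]


def corresponding_hbr_identity(
    table: Sequence[MotifRow],
    reference: MotifRow,
    offset: int = 3,
    width: int = 5,
) -> list[IdentityResult]:
    """Identity of each row's motif subwindow against the reference subwindow.

    With the defaults, motif positions 3-7 map the 10-residue reference motif
    (mature residues 32-41) onto the HBR1 window (residues 34-38).
    """
    ref_win = subwindow(reference.motif, offset, width)
    results = []
    for row in table:
        row_win = subwindow(row.motif, offset, width)
        res = motif_identity_percent(
            row_win, ref_win, query=row.label, subject=reference.label
        )
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Global alignment identity

_DIAG, _UP, _LEFT = 0, 1, 2  # preference order on score ties


def _matrix_lookup(name: str):
    try:
        return substitution_matrices.load(name)
    except (FileNotFoundError, ValueError) as exc:
        raise InputError(f"unknown substitution matrix {name!r}") from exc


def needleman_wunsch(
    a: str, b: str, params: AlignParams = AlignParams()
) -> tuple[str, str, float]:
    """Global affine-gap alignment of two residue strings.

    Returns (aligned_a, aligned_b, score).  End gaps are penalized (true
    global alignment).  Ties during traceback prefer diagonal, then up,
    then left, so the result is deterministic.
    """
    if not a or not b:
        raise InputError("cannot align empty sequences")
    sub = _matrix_lookup(params.matrix)
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)

    # Three-state Gotoh: M ends in a match/mismatch, X in a gap in b
    # (consuming a), Y in a gap in a (consuming b).
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge

    # 0 = came from M, 1 = from X, 2 = from Y (per state, for traceback)
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_X[2:, 0] = _UP  # boundary gap runs stay in their own state
    ptr_Y[0, 2:] = _LEFT

    for i in range(1, n + 1):
        sub_row = {ch: sub[a[i - 1], ch] for ch in set(b)}
        for j in range(1, m + 1):
            s = sub_row[b[j - 1]]
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = cands[k] + s
            ptr_M[i, j] = k

            cands = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            k = int(np.argmax(cands))
            X[i, j] = cands[k]
            ptr_X[i, j] = k

            cands = (M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            k = int(np.argmax(cands))
            Y[i, j] = cands[k]
            ptr_Y[i, j] = k

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    score = float(finals[state])

    aligned_a: list[str] = []
    aligned_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _DIAG and i > 0 and j > 0:
            prev = int(ptr_M[i, j])
            aligned_a.append(a[i - 1])
            aligned_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _UP and i > 0:
            prev = int(ptr_X[i, j])
            aligned_a.append(a[i - 1])
            aligned_b.append(GAP)
            i -= 1
        elif state == _LEFT and j > 0:
            prev = int(ptr_Y[i, j])
            aligned_a.append(GAP)
            aligned_b.append(b[j - 1])
            j -= 1
        else:  # boundary rows/columns
            if i > 0:
                aligned_a.append(a[i - 1])
                aligned_b.append(GAP)
                i -= 1
            else:
                aligned_a.append(GAP)
                aligned_b.append(b[j - 1])
                j -= 1
            continue
        state = prev
    return "".join(reversed(aligned_a)), "".join(reversed(aligned_b)), score


def _terminal_gap_columns(aligned: str) -> set[int]:
    cols: set[int] = set()
    for k, ch in enumerate(aligned):
        if ch != GAP:
            break
        cols.add(k)
    for k in range(len(aligned) - 1, -1, -1):
        if aligned[k] != GAP:
            break
        cols.add(k)
    return cols


def global_identity_percent(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams = AlignParams()
) -> IdentityResult:
    """Percent identity over a global alignment of two sequences.

    Identical positions are alignment columns pairing equal residues;
    compared positions exclude columns inside a terminal gap run of either
    sequence.
    """
    al_a, al_b, _ = needleman_wunsch(a.residues, b.residues, params)
    skip = _terminal_gap_columns(al_a) | _terminal_gap_columns(al_b)
    identical = compared = 0
    for k, (x, y) in enumerate(zip(al_a, al_b)):
        if k in skip:
            continue
        compared += 1
        if x == y and x != GAP:
            identical += 1
    return IdentityResult(a.id, b.id, identical, compared)


def family_identity_table(
    family: SequenceFamily,
    reference_id: str,
    params: AlignParams = AlignParams(),
) -> list[IdentityResult]:
    """Reference vs every member (self included, reported as 100%)."""
    if reference_id not in family:
        raise InputError(f"unknown reference id {reference_id!r}")
    ref = family[reference_id]
    results = []
    for rec in family:
        if rec.id == reference_id:
            results.append(IdentityResult(ref.id, rec.id, len(ref), len(ref)))
        else:
            results.append(global_identity_percent(ref, rec, params))
    return results
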