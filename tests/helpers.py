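"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# Unique-segment oracle: direct substring containment checks, maximal runs.


def oracle_unique_segments(
    seqs: dict[str, str], L: int, m: int
) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    for mid, s in seqs.items():
        flags = []
        for i in range(len(s) - L + 1):
            pat = s[i : i + L]
            carriers = sum(1 for other in seqs.values() if pat in other)
            flags.append(carriers <= m)
        segs = []
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                segs.append((i + 1, j + L, s[i : j + L]))
                i = j + 1
            else:
                i += 1
        out[mid] = segs
    return out


def oracle_flags(seqs: dict[str, str], mid: str, L: int, m: int) -> list[bool]:
    s = seqs[mid]
    return [
        sum(1 for other in seqs.values() if s[i : i + L] in other) <= m
        for i in range(len(s) - L + 1)
    ]


# ---------------------------------------------------------------------------
# Global-alignment score oracles.

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_align_score_memo(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.2
) -> float:
    """Top-down memoized recursion over (i, j, last-move) states."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        scores = []
        if i < len(a) and j < len(b):
            scores.append(_BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            scores.append(best(i + 1, j, "X") - cost)
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            scores.append(best(i, j + 1, "Y") - cost)
        return max(scores)

    return best(0, 0, "M")


def oracle_align_score_enum(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.2
) -> float:
    """Exhaustive enumeration of every alignment path (tiny inputs only)."""
    best = [float("-inf")]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + _BLOSUM62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "X", score - (gap_extend if prev == "X" else gap_open))
        if j < len(b):
            rec(i, j + 1, "Y", score - (gap_extend if prev == "Y" else gap_open))

    rec(0, 0, "M", 0.0)
    return best[0]


def random_family(rng, n_members: int, max_len: int, alphabet: str) -> dict[str, str]:
    out = {}
    for k in range(n_members):
        n = int(rng.integers(5, max_len + 1))
        out[f"m{k}"] = "".join(
            alphabet[i] for i in rng.integers(len(alphabet), size=n)
        )
    return out
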