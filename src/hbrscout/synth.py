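"""Seeded synthetic protein families with planted, recoverable ground truth.

Each family is built from one random scaffold; members are scaffold copies
with per-residue substitution noise.  Member-unique segments are spliced in
by rejection sampling: every length-L window of a planted segment must be
absent from every other member's final sequence, so downstream extraction is
guaranteed (recall 1.0 by construction).  Optionally, a cationic window is
planted inside a segment with basic residues anchored at both window ends and
all competing basics in the screening range damped, making the planted window
the strict representative that default screening reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import GenerationError, InputError
from .seqio import SequenceFamily, SequenceRecord

ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")

_MAX_PASSES = 60
_MAX_TRIES = 400


@dataclass(frozen=True)
class SynthConfig:
    n_members: int = 13
    scaffold_length: int = 130
    n_planted_segments: tuple[int, int] = (2, 4)
    planted_segment_length: tuple[int, int] = (5, 14)
    n_planted_cationic: tuple[int, int] = (0, 2)
    cationic_width: int = 5
    cationic_min_basic: int = 3
    cationic_flank: int = 2
    substitution_noise: float = 0.05
    pattern_length: int = 3
    basic_set: frozenset[str] = frozenset("RK")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise InputError("need at least 2 members")
        if self.scaffold_length < self.pattern_length:
            raise InputError("scaffold shorter than pattern length")
        if not 0.0 <= self.substitution_noise <= 1.0:
            raise InputError("substitution_noise must be in [0, 1]")
        lo, hi = self.planted_segment_length
        if lo < max(self.pattern_length, 1) or hi < lo:
            raise InputError("bad planted_segment_length range")
        if self.cationic_width > hi:
            raise InputError("cationic window wider than longest planted segment")
        if not 1 <= self.cationic_min_basic <= self.cationic_width:
            raise InputError("bad cationic_min_basic")


@dataclass(frozen=True)
class FamilyTruth:
    """Planted spans per member, 1-based inclusive."""

    segments: Mapping[str, tuple[tuple[int, int], ...]]
    cationic: Mapping[str, tuple[tuple[int, int], ...]]


def _kmers(text: str, L: int) -> set[str]:
    return {text[i : i + L] for i in range(len(text) - L + 1)}


def _mutate(seq: list[str], noise: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    if noise <= 0:
        return out
    hits = np.nonzero(rng.random(len(seq)) < noise)[0]
    for i in hits:
        choices = [ch for ch in ALPHABET if ch != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _place_spans(
    length: int, sizes: Sequence[int], rng: np.random.Generator, gap: int = 1
) -> list[tuple[int, int]]:
    """Non-overlapping 1-based spans separated by >= ``gap`` residues."""
    if not sizes:
        return []
    for _ in range(_MAX_TRIES):
        starts = sorted(rng.integers(1, length + 1, size=len(sizes)).tolist())
        spans = []
        ok = True
        prev_end = -gap
        for start, size in zip(starts, sorted(sizes, reverse=True)):
            start = max(start, prev_end + gap + 1)
            end = start + size - 1
            if end > length:
                ok = False
                break
            spans.append((start, end))
            prev_end = end
        if ok:
            return spans
    raise GenerationError(
        f"cannot place {len(sizes)} non-overlapping segments in length {length}"
    )


class _Builder:
    def __init__(self, cfg: SynthConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.L = cfg.pattern_length
        self.ids = [f"syn{i + 1:02d}" for i in range(cfg.n_members)]
        scaffold = [ALPHABET[k] for k in rng.integers(len(ALPHABET), size=cfg.scaffold_length)]
        self.seqs: dict[str, list[str]] = {
            mid: _mutate(scaffold, cfg.substitution_noise, rng) for mid in self.ids
        }
        self.seg_spans: dict[str, list[tuple[int, int]]] = {}
        self.cat_spans: dict[str, list[tuple[int, int]]] = {}
        self.cat_by_seg: dict[tuple[str, tuple[int, int]], tuple[int, int]] = {}

    # -- geometry ---------------------------------------------------------

    def place(self) -> None:
        cfg, rng = self.cfg, self.rng
        for mid in self.ids:
            n_seg = int(rng.integers(cfg.n_planted_segments[0], cfg.n_planted_segments[1] + 1))
            sizes = [
                int(rng.integers(cfg.planted_segment_length[0], cfg.planted_segment_length[1] + 1))
                for _ in range(n_seg)
            ]
            # gap >= L keeps at least one fully-scaffold window between spans
            spans = _place_spans(cfg.scaffold_length, sizes, rng, gap=self.L)
            self.seg_spans[mid] = spans
            self.cat_spans[mid] = []
            eligible = [s for s in spans if s[1] - s[0] + 1 >= cfg.cationic_width]
            n_cat = int(rng.integers(cfg.n_planted_cationic[0], cfg.n_planted_cationic[1] + 1))
            n_cat = min(n_cat, len(eligible))
            chosen = (
                [eligible[k] for k in rng.choice(len(eligible), size=n_cat, replace=False)]
                if n_cat
                else []
            )
            for seg in chosen:
                seg_len = seg[1] - seg[0] + 1
                off = int(rng.integers(0, seg_len - cfg.cationic_width + 1))
                win = (seg[0] + off, seg[0] + off + cfg.cationic_width - 1)
                self.cat_spans[mid].append(win)
                self.cat_by_seg[(mid, seg)] = win

    # -- segment texts ----------------------------------------------------

    def _segment_text(self, mid: str, seg: tuple[int, int]) -> str:
        cfg, rng = self.cfg, self.rng
        size = seg[1] - seg[0] + 1
        text = [ALPHABET[k] for k in rng.integers(len(ALPHABET), size=size)]
        win = self.cat_by_seg.get((mid, seg))
        if win is not None:
            off = win[0] - seg[0]
            wdt = cfg.cationic_width
            basics = sorted(self.cfg.basic_set)
            # anchor basics at both window ends so shifted windows lose one
            slots = [0, wdt - 1]
            middle = list(range(1, wdt - 1))
            extra = max(0, cfg.cationic_min_basic - 2)
            if extra:
                slots += [middle[k] for k in rng.choice(len(middle), size=extra, replace=False)]
            for k in range(wdt):
                if k in slots:
                    text[off + k] = basics[rng.integers(len(basics))]
                else:
                    text[off + k] = self._nonbasic()
        return "".join(text)

    def _nonbasic(self) -> str:
        choices = [ch for ch in ALPHABET if ch not in self.cfg.basic_set]
        return choices[self.rng.integers(len(choices))]

    def _foreign_kmers(self, mid: str) -> set[str]:
        out: set[str] = set()
        for other in self.ids:
            if other != mid:
                out |= _kmers("".join(self.seqs[other]), self.L)
        return out

    def _reserved_kmers(self, exclude: str) -> set[str]:
        out: set[str] = set()
        for other in self.ids:
            if other == exclude:
                continue
            seq = "".join(self.seqs[other])
            for start, end in self.seg_spans[other]:
                out |= _kmers(seq[start - 1 : end], self.L)
        return out

    def _splice(self, mid: str, seg: tuple[int, int], text: str) -> None:
        self.seqs[mid][seg[0] - 1 : seg[1]] = list(text)

    def _violates(self, mid: str, seg: tuple[int, int]) -> bool:
        seq = "".join(self.seqs[mid])
        text = seq[seg[0] - 1 : seg[1]]
        foreign = self._foreign_kmers(mid)
        return bool(_kmers(text, self.L) & foreign)

    def initial_plant(self) -> None:
        """Unconditionally splice fresh planted text (with cationic enrichment)."""
        for mid in self.ids:
            for seg in self.seg_spans[mid]:
                self._splice(mid, seg, self._segment_text(mid, seg))

    def plant_segments(self) -> None:
        for _ in range(_MAX_PASSES):
            dirty = False
            for mid in self.ids:
                for seg in self.seg_spans[mid]:
                    if not self._violates(mid, seg):
                        continue
                    dirty = True
                    foreign = self._foreign_kmers(mid)
                    for _try in range(_MAX_TRIES):
                        text = self._segment_text(mid, seg)
                        if not _kmers(text, self.L) & foreign:
                            self._splice(mid, seg, text)
                            break
                    else:
                        raise GenerationError(
                            f"cannot find unique text for {mid} span {seg}"
                        )
            if not dirty:
                return
        raise GenerationError("segment planting did not converge")

    # -- cationic dominance ----------------------------------------------

    def damp_competing_basics(self) -> None:
        """Remove basics competing with each planted window in its screen range.

        The screen scans the *detected* segment extended by the flank, and
        detection may extend past the planted span (noise can make adjacent
        windows unique too), so damping is driven by an actual detection pass
        and iterated to a fixpoint.  Positions inside any planted cationic
        window of the member are never touched.
        """
        from .uniqseg import unique_segments

        cfg = self.cfg
        if not self.cat_by_seg:
            return
        for _ in range(_MAX_PASSES):
            self.plant_segments()  # re-fix any span broken by earlier damping
            family, _ = self.build()
            detected = unique_segments(family, L=self.L, m=1)
            dirty = False
            for (mid, seg), win in sorted(self.cat_by_seg.items()):
                containing = [
                    d for d in detected[mid] if d.start <= seg[0] and d.end >= seg[1]
                ]
                span = containing[0].span if containing else seg
                lo = max(1, span[0] - cfg.cationic_flank)
                hi = min(len(self.seqs[mid]), span[1] + cfg.cationic_flank)
                reserved = self._reserved_kmers(mid)
                protected = self.cat_spans[mid]
                for pos in range(lo, hi + 1):
                    if any(w[0] <= pos <= w[1] for w in protected):
                        continue
                    if self.seqs[mid][pos - 1] not in cfg.basic_set:
                        continue
                    self._replace_avoiding(mid, pos, reserved)
                    dirty = True
            if not dirty:
                return
        raise GenerationError("cationic damping did not converge")

    def _replace_avoiding(self, mid: str, pos: int, reserved: set[str]) -> None:
        seq = self.seqs[mid]
        choices = [ch for ch in ALPHABET if ch not in self.cfg.basic_set]
        order = self.rng.permutation(len(choices))
        for k in order:
            old = seq[pos - 1]
            seq[pos - 1] = choices[k]
            window = "".join(
                seq[max(0, pos - self.L) : min(len(seq), pos + self.L - 1)]
            )
            if not _kmers(window, self.L) & reserved:
                return
            seq[pos - 1] = old
        raise GenerationError(f"cannot damp basic residue at {mid}:{pos}")

    # -- final assembly ---------------------------------------------------

    def verify(self) -> None:
        for mid in self.ids:
            for seg in self.seg_spans[mid]:
                if self._violates(mid, seg):
                    raise GenerationError(f"planted span {mid}:{seg} not unique")

    def build(self) -> tuple[SequenceFamily, FamilyTruth]:
        records = [
            SequenceRecord(mid, "".join(self.seqs[mid]), "synthetic family member")
            for mid in self.ids
        ]
        truth = FamilyTruth(
            segments={mid: tuple(self.seg_spans[mid]) for mid in self.ids},
            cationic={mid: tuple(sorted(self.cat_spans[mid])) for mid in self.ids},
        )
        return SequenceFamily.of(records), truth


def generate_family(cfg: SynthConfig) -> tuple[SequenceFamily, FamilyTruth]:
    """Generate a synthetic family plus ground truth; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    builder = _Builder(cfg, rng)
    builder.place()
    builder.initial_plant()
    builder.plant_segments()
    builder.damp_competing_basics()
    builder.verify()
    return builder.build()


# ---------------------------------------------------------------------------
# Recovery scoring


def evaluate_recovery(
    detected: Mapping[str, Sequence],
    truth: FamilyTruth,
    mode: Literal["segment", "hbr"] = "segment",
) -> tuple[float, float]:
    """Span-level (precision, recall) of detections against planted truth.

    Segment mode: a planted span is recovered when some detected span contains
    it.  HBR mode: a detected span must equal the planted span.  A detection
    is supported when it recovers at least one planted span.  With no
    detections at all, precision is reported as 1.0 (with a warning) by
    convention.
    """
    if mode not in ("segment", "hbr"):
        raise InputError(f"unknown mode {mode!r}")
    planted_map = truth.segments if mode == "segment" else truth.cationic
    unknown = set(detected) - set(planted_map)
    if unknown:
        raise InputError(f"detections for unknown members: {sorted(unknown)}")

    def matches(d: tuple[int, int], p: tuple[int, int]) -> bool:
        if mode == "segment":
            return d[0] <= p[0] and d[1] >= p[1]
        return d == p

    n_planted = n_recovered = n_detected = n_supported = 0
    for mid, planted in planted_map.items():
        spans = [
            (item.start, item.end) if hasattr(item, "start") else tuple(item)
            for item in detected.get(mid, ())
        ]
        n_detected += len(spans)
        for p in planted:
            n_planted += 1
            if any(matches(d, p) for d in spans):
                n_recovered += 1
        for d in spans:
            if any(matches(d, p) for p in planted):
                n_supported += 1

    recall = 1.0 if n_planted == 0 else n_recovered / n_planted
    if n_detected == 0:
        if n_planted:
            warnings.warn("no detections; precision reported as 1.0 by convention")
        precision = 1.0
    else:
        precision = n_supported / n_detected
    return precision, recall
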