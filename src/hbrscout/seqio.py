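"""Sequence/alignment I/O, packaged fixture tables, and report serialization.

Coordinates everywhere are 1-based inclusive on the mature protein chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import InputError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated as an unknown residue and matched literally downstream.
VALID_RESIDUES = AMINO_ACIDS | {"X"}
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: unique id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        if not self.residues:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.residues) - VALID_RESIDUES)
        if bad:
            raise InputError(
                f"record {self.id!r}: invalid residue characters {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceFamily:
    """Ordered collection of SequenceRecord with pairwise-distinct ids."""

    members: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.members:
            if rec.id in seen:
                raise InputError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @classmethod
    def of(cls, members: Sequence[SequenceRecord]) -> "SequenceFamily":
        return cls(tuple(members))

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.members]

    def __getitem__(self, member_id: str) -> SequenceRecord:
        for rec in self.members:
            if rec.id == member_id:
                return rec
        raise KeyError(member_id)

    def __contains__(self, member_id: str) -> bool:
        return any(rec.id == member_id for rec in self.members)


@dataclass(frozen=True)
class MotifRow:
    """One printed 10-residue motif with protein/organism labels.

    ``note`` marks cells whose printed identity percentage is not reproduced
    by positional comparison of the printed motifs themselves.
    """

    protein: str
    organism: str = ""
    accession: str = ""
    motif: str = ""
    protein_identity_pct: float | None = None
    motif_identity_pct: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) != 10:
            raise InputError(
                f"motif for {self.protein}/{self.organism}: expected 10 characters,"
                f" got {self.motif!r}"
            )
        for pct in (self.protein_identity_pct, self.motif_identity_pct):
            if pct is not None and not 0.0 <= pct <= 100.0:
                raise InputError(f"identity percent {pct} outside [0, 100]")

    @property
    def label(self) -> str:
        return f"{self.protein} ({self.organism})" if self.organism else self.protein


@dataclass(frozen=True)
class SegmentReport:
    """Flat report row for a unique segment or an HBR candidate window."""

    member: str
    start: int
    end: int
    text: str
    level: int
    tag: str = "unique-segment"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise InputError(
                f"report for {self.member!r}: bad coordinates {self.start}..{self.end}"
            )
        if len(self.text) != self.end - self.start + 1:
            raise InputError(
                f"report for {self.member!r}: text length {len(self.text)} does not"
                f" match span {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class FixtureSet:
    """Packaged in-study reference data (motif tables, motifs, HBR windows)."""

    table4: tuple[MotifRow, ...]
    table5: tuple[MotifRow, ...]
    unique_motifs: tuple[str, ...]
    hbr_windows: tuple[tuple[str, int, int], ...]

    @property
    def motif_table(self) -> tuple[MotifRow, ...]:
        return self.table4 + self.table5

    def table5_row(self, protein: str) -> MotifRow:
        for row in self.table5:
            if row.protein == protein:
                return row
        raise KeyError(protein)


# ---------------------------------------------------------------------------
# FASTA / alignment I/O


def _clean_residues(raw: str, record_id: str) -> str:
    residues = raw.strip().upper().rstrip("*")
    if GAP in residues:
        raise InputError(
            f"record {record_id!r}: gap character '-' not allowed in sequences"
        )
    return residues


def read_fasta(path: str | Path) -> SequenceFamily:
    """Read a FASTA file into a SequenceFamily (order preserved).

    Residues are upper-cased and trailing ``*`` terminators stripped.  Empty
    files, duplicate ids, gap characters and non-amino-acid characters raise
    :class:`InputError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _clean_residues(str(rec.seq), rec.id)
        records.append(SequenceRecord(rec.id, residues, rec.description))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return SequenceFamily.of(records)


def write_fasta(family: SequenceFamily, path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description=rec.description or "")
        for rec in family
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path, fmt: str | None = None):
    """Read a multiple alignment (aligned FASTA or CLUSTAL), sniffing the format.

    Returns a Bio.Align.MultipleSeqAlignment; read-only convenience.
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:1]
        fmt = "fasta" if head == ">" else "clustal"
    try:
        return AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise InputError(f"cannot parse alignment {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_text(name: str) -> str:
    return (resources.files("hbrscout.data") / name).read_text()


def _parse_motif_tsv(text: str) -> tuple[MotifRow, ...]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        cells += [""] * (len(header) - len(cells))
        rec = dict(zip(header, cells))
        rows.append(
            MotifRow(
                protein=rec["protein"],
                organism=rec["organism"],
                accession=rec["accession"],
                motif=rec["motif"],
                protein_identity_pct=float(rec["protein_identity_pct"]),
                motif_identity_pct=float(rec["motif_identity_pct"]),
                note=rec.get("note", ""),
            )
        )
    return tuple(rows)


def load_paper_fixtures() -> FixtureSet:
    """Load the packaged reference tables.

    Returns the 12-row primate comparison table, the 13-row human family
    comparison table, the 11 unique motif strings of human RNase3, and the
    three HBR windows (RWRCK 34-38, RSRFR 73-77, RPGRR 101-105).
    """
    table4 = _parse_motif_tsv(_data_text("table4.tsv"))
    table5 = _parse_motif_tsv(_data_text("table5.tsv"))
    motifs = tuple(
        ln.strip() for ln in _data_text("unique_motifs.txt").splitlines() if ln.strip()
    )
    windows = []
    for ln in _data_text("hbr_windows.tsv").splitlines()[1:]:
        if not ln.strip():
            continue
        _, window, start, end = ln.split("\t")
        windows.append((window, int(start), int(end)))
    return FixtureSet(table4, table5, motifs, tuple(windows))


def hrnase3_mature() -> SequenceRecord:
    """The mature human RNase3 (ECP) chain, 133 residues, packaged as FASTA."""
    text = _data_text("hrnase3_mature.fasta")
    lines = text.splitlines()
    header = lines[0][1:].split(None, 1)
    residues = "".join(ln.strip() for ln in lines[1:])
    return SequenceRecord(header[0], residues, header[1] if len(header) > 1 else "")


# ---------------------------------------------------------------------------
# Report serialization

_TSV_HEADER = ("member", "start", "end", "length", "segment", "level", "tag")


def sort_reports(reports: Sequence[SegmentReport]) -> list[SegmentReport]:
    return sorted(reports, key=lambda r: (r.member, r.start, r.end))


def write_segments_tsv(
    reports: Sequence[SegmentReport],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write reports as TSV, sorted by (member, start); 1-based inclusive."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for r in sort_reports(reports):
            fh.write(
                f"{r.member}\t{r.start}\t{r.end}\t{r.end - r.start + 1}"
                f"\t{r.text}\t{r.level}\t{r.tag}\n"
            )


def write_segments_json(
    reports: Sequence[SegmentReport],
    path: str | Path,
    meta: dict | None = None,
) -> None:
    payload = {
        "meta": meta or {},
        "segments": [
            {
                "member": r.member,
                "start": r.start,
                "end": r.end,
                "length": r.end - r.start + 1,
                "segment": r.text,
                "level": r.level,
                "tag": r.tag,
            }
            for r in sort_reports(reports)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
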