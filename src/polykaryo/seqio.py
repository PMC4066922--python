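"""Alignment, region-map and sample-sheet I/O.

All downstream statistics operate on a :class:`MultipleAlignment` — an
in-memory, equal-length, gapped nucleotide alignment — together with a
:class:`RegionMap` labelling every alignment column as exon or intron and a
:class:`SampleSheet` mapping clone sequences to the basidioma (fruit body)
they were amplified from.

Coordinate convention: alignment columns are 1-based and inclusive
throughout the package, so positions in reports line up with positions as
they are conventionally printed for annotated loci.  BED-style region input
(0-based, half-open) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")

__all__ = [
    "MultipleAlignment",
    "Region",
    "RegionMap",
    "SampleRow",
    "SampleSheet",
    "read_alignment",
    "write_alignment",
    "read_regions",
    "read_sample_sheet",
    "write_sample_sheet",
    "partition_alignment",
]


class AlignmentError(ValueError):
    """Raised when an alignment, region map or sample sheet is malformed."""


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped sequences with stable, unique identifiers.

    Sequences are stored uppercase over the alphabet ``{A, C, G, T, N, -}``;
    record order is preserved from the input.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one sequence")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        if any(not rid for rid in ids):
            raise AlignmentError("empty sequence id")
        length = len(self.records[0][1])
        if length < 1:
            raise AlignmentError(f"zero-length sequence: {ids[0]!r}")
        for rid, seq in self.records:
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: {rid!r} has length {len(seq)}, "
                    f"expected {length} (as {ids[0]!r})"
                )
            bad = set(seq) - ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq, start=1) if c in bad)
                raise AlignmentError(
                    f"illegal character {seq[pos - 1]!r} in {rid!r} at column {pos}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MultipleAlignment":
        """Build an alignment from (id, sequence) pairs, normalising case.

        ``U`` is mapped to ``T`` with a logged warning (RNA-style FASTA).
        """
        cleaned = []
        for rid, seq in pairs:
            s = seq.upper()
            if "U" in s:
                logger.warning("sequence %r contains U; mapping U->T", rid)
                s = s.replace("U", "T")
            cleaned.append((rid, s))
        return cls(tuple(cleaned))

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def column(self, position: int) -> str:
        """States at a 1-based column, in record order."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside 1..{self.length}")
        return "".join(seq[position - 1] for _, seq in self.records)

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        """Row subset in the given order."""
        lookup = dict(self.records)
        return MultipleAlignment(tuple((i, lookup[i]) for i in ids))

    def take_columns(self, positions: Sequence[int]) -> "MultipleAlignment":
        """Column subset (1-based positions, kept in the given order)."""
        idx = [p - 1 for p in positions]
        return MultipleAlignment(
            tuple((rid, "".join(seq[i] for i in idx)) for rid, seq in self.records)
        )


@dataclass(frozen=True)
class Region:
    """A labelled run of alignment columns, 1-based inclusive."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AlignmentError(f"bad interval ({self.start}, {self.end})")
        if self.label not in ("exon", "intron"):
            raise AlignmentError(f"unknown region label {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class RegionMap:
    """Sorted, non-overlapping exon/intron intervals covering every column."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise AlignmentError("region map is empty")
        prev_end = 0
        for reg in self.regions:
            if reg.start != prev_end + 1:
                raise AlignmentError(
                    f"region map has a gap or overlap before ({reg.start}, {reg.end}, "
                    f"{reg.label}): previous interval ended at {prev_end}"
                )
            prev_end = reg.end

    @property
    def length(self) -> int:
        return self.regions[-1].end

    def label_at(self, position: int) -> str:
        for reg in self.regions:
            if position in reg:
                return reg.label
        raise IndexError(f"column {position} outside 1..{self.length}")

    def region_length(self, label: str) -> int:
        return sum(r.length for r in self.regions if r.label == label)

    def columns(self, label: str) -> list[int]:
        """1-based columns carrying the given label, ascending."""
        out: list[int] = []
        for reg in self.regions:
            if reg.label == label:
                out.extend(range(reg.start, reg.end + 1))
        return out

    @property
    def labels(self) -> tuple[str, ...]:
        seen = []
        for r in self.regions:
            if r.label not in seen:
                seen.append(r.label)
        return tuple(seen)


@dataclass(frozen=True)
class SampleRow:
    seq_id: str
    basidioma_id: str
    locality: str
    clone_count: int

    def __post_init__(self) -> None:
        if self.clone_count < 1:
            raise AlignmentError(
                f"clone_count for {self.seq_id!r} must be >= 1, got {self.clone_count}"
            )
        if not self.basidioma_id or not self.locality:
            raise AlignmentError(f"empty basidioma_id or locality for {self.seq_id!r}")


@dataclass(frozen=True)
class SampleSheet:
    """Maps clone sequences to basidioma and locality, with support counts."""

    rows: tuple[SampleRow, ...]

    @property
    def basidioma_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for row in self.rows:
            if row.basidioma_id not in seen:
                seen.append(row.basidioma_id)
        return tuple(seen)

    def rows_for(self, basidioma_id: str) -> tuple[SampleRow, ...]:
        out = tuple(r for r in self.rows if r.basidioma_id == basidioma_id)
        if not out:
            raise AlignmentError(f"unknown basidioma_id {basidioma_id!r}")
        return out

    def locality_of(self, basidioma_id: str) -> str:
        return self.rows_for(basidioma_id)[0].locality

    def validate_against(self, aln: MultipleAlignment) -> None:
        missing = [r.seq_id for r in self.rows if r.seq_id not in aln.ids]
        if missing:
            raise AlignmentError(f"sample sheet seq_ids missing from alignment: {missing}")


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file.

    Ragged lengths or illegal characters raise :class:`AlignmentError`
    naming the offending record.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return MultipleAlignment.from_pairs(records)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_regions(path: str | Path, alignment_length: int) -> RegionMap:
    """Read a BED-style region file (chrom, start, end, label).

    Input is 0-based half-open per BED; the returned map is 1-based
    inclusive.  Intervals must tile ``1..alignment_length`` exactly.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 4 columns (chrom start end label)"
                )
            _, start, end, label = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AlignmentError(f"{path}:{lineno}: non-integer interval") from exc
            if end_i <= start_i:
                raise AlignmentError(f"{path}:{lineno}: empty interval [{start_i},{end_i})")
            regions.append(Region(start_i + 1, end_i, label))
    regions.sort(key=lambda r: r.start)
    rmap = RegionMap(tuple(regions))
    if rmap.length != alignment_length:
        raise AlignmentError(
            f"regions cover 1..{rmap.length} but alignment has "
            f"{alignment_length} columns"
        )
    return rmap


def write_regions(rmap: RegionMap, path: str | Path, chrom: str = "locus") -> None:
    with open(path, "w") as fh:
        for reg in rmap.regions:
            fh.write(f"{chrom}\t{reg.start - 1}\t{reg.end}\t{reg.label}\n")


SHEET_HEADER = ("seq_id", "basidioma_id", "locality", "clone_count")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the tab-separated sample sheet.

    Header must be ``seq_id  basidioma_id  locality  clone_count``.
    """
    rows: list[SampleRow] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if tuple(header) != SHEET_HEADER:
            raise AlignmentError(
                f"bad sample sheet header {header}; expected {list(SHEET_HEADER)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise AlignmentError(f"{path}:{lineno}: expected 4 columns")
            rows.append(SampleRow(parts[0], parts[1], parts[2], int(parts[3])))
    return SampleSheet(tuple(rows))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SHEET_HEADER) + "\n")
        for r in sheet.rows:
            fh.write(f"{r.seq_id}\t{r.basidioma_id}\t{r.locality}\t{r.clone_count}\n")


def partition_alignment(
    aln: MultipleAlignment, regions: RegionMap, keep: str
) -> MultipleAlignment:
    """Concatenate the columns of every interval carrying label ``keep``.

    Used to strip introns before exon-only analyses; row order is preserved
    and the returned length equals the summed length of the kept intervals.
    """
    if regions.length != aln.length:
        raise AlignmentError(
            f"region map covers {regions.length} columns, alignment has {aln.length}"
        )
    if keep not in regions.labels:
        raise AlignmentError(f"label {keep!r} absent from region map {regions.labels}")
    return aln.take_columns(regions.columns(keep))
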