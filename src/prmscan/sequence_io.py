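"""Protein FASTA and region-table I/O.

All residue coordinates in this package are 1-based and inclusive at both
ends, matching the convention of domain annotations such as "amino acids
273-351".  Conversion to 0-based half-open slices happens only at internal
array boundaries.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical residues plus X (unknown).  X participates in scoring
#: with the scale's median value and matches only explicit wildcard
#: positions in motif patterns.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Gap characters silently stripped on input.
_GAP_CHARS = "-.*"


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid protein records."""


class RegionBoundsError(ValueError):
    """Raised when a region lies outside its protein's coordinates."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier and free-text description.

    The sequence is uppercase and restricted to the 20 canonical amino-acid
    letters plus X.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for offset, ch in enumerate(self.sequence):
            if ch not in VALID_RESIDUES:
                raise FastaParseError(
                    f"record {self.id!r}: illegal residue {ch!r} at position "
                    f"{offset + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class SequenceRegion:
    """A labelled residue range on a protein, 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region {self.start}-{self.end} on {self.protein_id!r}: "
                "need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper()
    for g in _GAP_CHARS:
        seq = seq.replace(g, "")
    seq = "".join(seq.split())
    if not seq:
        raise FastaParseError(f"record {record_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA file.

    Lowercase letters are uppercased; gap characters and whitespace are
    stripped; record order is preserved.  Raises :class:`FastaParseError`
    naming the record and offset on any illegal residue, on duplicate ids,
    and on empty files.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if not sr.id:
            raise FastaParseError(f"{path}: record with empty header")
        if sr.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {sr.id!r}")
        seen.add(sr.id)
        seq = _normalize(str(sr.seq), sr.id)
        records.append(ProteinRecord(id=sr.id, sequence=seq, description=sr.description))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def extract_region(record: ProteinRecord, region: SequenceRegion) -> ProteinRecord:
    """Extract a 1-based inclusive residue range as a new record.

    The returned id is annotated with the coordinates, e.g. ``KLF11/273-351``.
    """
    if region.end > len(record):
        raise RegionBoundsError(
            f"region {region.start}-{region.end} exceeds length "
            f"{len(record)} of {record.id!r}"
        )
    sub = record.sequence[region.start - 1 : region.end]
    return ProteinRecord(
        id=f"{record.id}/{region.start}-{region.end}",
        sequence=sub,
        description=(region.label or record.description),
    )


def read_regions_tsv(path: str | Path) -> list[SequenceRegion]:
    """Read regions from 4-column TSV: protein_id, start, end, label."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(
                SequenceRegion(parts[0], int(parts[1]), int(parts[2]), label)
            )
    return regions


def write_regions_tsv(
    regions: Sequence[SequenceRegion], path: str | Path, header: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        for r in regions:
            fh.write(f"{r.protein_id}\t{r.start}\t{r.end}\t{r.label}\n")
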