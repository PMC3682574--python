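"""Degenerate proline-rich motif (PRM) consensus scanning.

A PRM pattern is an ordered list of position classes: a literal residue, the
hydrophobic class Φ (written ``f`` in the text format), or the wildcard X
(written ``x``).  The four built-in consensus patterns delimit and fill a
TRD3-like interaction domain:

* PRM1  ``PPfPfffQffP``   — N-terminal boundary
* PRM2  ``QffPfPQPfffGP`` — central
* PRM3  ``ffPPPfPfff``    — central
* PRM4  ``GfxxffPffPfP``  — C-terminal boundary

By default Φ is the set of residues with positive Kyte-Doolittle hydropathy
{A, C, F, I, L, M, V}; W and Y can be added for a more permissive class.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .sequence_io import ProteinRecord, SequenceRegion

PHI_TOKEN = "f"
ANY_TOKEN = "x"


@dataclasses.dataclass(frozen=True)
class HydrophobicClass:
    """The residue set matched by Φ positions."""

    members: frozenset[str]

    def __contains__(self, residue: str) -> bool:
        return residue in self.members


#: Residues with positive Kyte-Doolittle hydropathy.
PHI_DEFAULT = HydrophobicClass(frozenset("ACFILMV"))
#: Permissive variant including the aromatics W and Y.
PHI_WITH_AROMATICS = HydrophobicClass(frozenset("ACFILMVWY"))


@dataclasses.dataclass(frozen=True)
class PRMPattern:
    """A degenerate motif: per-position literal residue, ``f`` (Φ) or ``x``."""

    name: str
    positions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"pattern {self.name!r}: need length >= 3")
        for tok in self.positions:
            if tok not in (PHI_TOKEN, ANY_TOKEN) and not (tok.isupper() and tok.isalpha()):
                raise ValueError(f"pattern {self.name!r}: bad token {tok!r}")

    @classmethod
    def from_string(cls, name: str, spec: str) -> "PRMPattern":
        return cls(name, tuple(spec))

    def __len__(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:
        return "".join(self.positions)


PRM1 = PRMPattern.from_string("PRM1", "PPfPfffQffP")
PRM2 = PRMPattern.from_string("PRM2", "QffPfPQPfffGP")
PRM3 = PRMPattern.from_string("PRM3", "ffPPPfPfff")
PRM4 = PRMPattern.from_string("PRM4", "GfxxffPffPfP")
BUILTIN_PATTERNS = (PRM1, PRM2, PRM3, PRM4)


@dataclasses.dataclass(frozen=True)
class PRMMatch:
    """A motif hit in protein coordinates (1-based inclusive)."""

    pattern_name: str
    protein_id: str
    start: int
    end: int
    n_mismatches: int


def _position_matches(residue: str, token: str, phi: HydrophobicClass) -> bool:
    if token == ANY_TOKEN:
        return True
    if residue == "X":
        # unknown residue only satisfies explicit wildcard positions
        return False
    if token == PHI_TOKEN:
        return residue in phi
    return residue == token


def match_at(
    sequence: str,
    pos: int,
    pattern: PRMPattern,
    phi: HydrophobicClass = PHI_DEFAULT,
    max_mismatch: int = 0,
    protein_id: str = "",
) -> Optional[PRMMatch]:
    """Test the pattern at 1-based position ``pos``; None when it misses.

    A position matches when the residue equals a literal, belongs to Φ for a
    Φ position, or unconditionally for X positions; the hit is returned iff
    the number of failing positions is <= ``max_mismatch``.
    """
    plen = len(pattern)
    if pos < 1 or pos + plen - 1 > len(sequence):
        raise ValueError(
            f"pattern {pattern.name!r} at {pos} exceeds sequence of length {len(sequence)}"
        )
    window = sequence[pos - 1 : pos - 1 + plen]
    mism = sum(
        not _position_matches(res, tok, phi)
        for res, tok in zip(window, pattern.positions)
    )
    if mism > max_mismatch:
        return None
    return PRMMatch(pattern.name, protein_id, pos, pos + plen - 1, mism)


def _collapse_overlaps(matches: list[PRMMatch]) -> list[PRMMatch]:
    """Within one pattern, keep the best of each overlapping run.

    Best = fewest mismatches, ties to the leftmost; a kept match suppresses
    every raw match of the same pattern overlapping it.
    """
    kept: list[PRMMatch] = []
    for m in sorted(matches, key=lambda m: (m.n_mismatches, m.start)):
        if all(m.end < k.start or m.start > k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def scan(
    record: ProteinRecord,
    patterns: Sequence[PRMPattern] = BUILTIN_PATTERNS,
    phi: HydrophobicClass = PHI_DEFAULT,
    max_mismatch: int = 0,
    region: Optional[SequenceRegion] = None,
    collapse: bool = True,
) -> list[PRMMatch]:
    """Scan a protein (or a sub-region) for all pattern occurrences.

    Matches are reported in protein coordinates, sorted by start then
    pattern name.  Overlapping matches of the *same* pattern are collapsed
    to the best-scoring one (fewest mismatches, ties leftmost); distinct
    patterns may overlap freely.  Set ``collapse=False`` for raw matches.
    """
    if not patterns:
        raise ValueError("need at least one pattern to scan")
    lo, hi = 1, len(record)
    if region is not None:
        if region.end > len(record):
            raise ValueError(
                f"region {region.start}-{region.end} exceeds {record.id!r} "
                f"(length {len(record)})"
            )
        lo, hi = region.start, region.end

    out: list[PRMMatch] = []
    for pat in patterns:
        raw = []
        for pos in range(lo, hi - len(pat) + 2):
            m = match_at(record.sequence, pos, pat, phi, max_mismatch, record.id)
            if m is not None:
                raw.append(m)
        out.extend(_collapse_overlaps(raw) if collapse else raw)
    out.sort(key=lambda m: (m.start, m.pattern_name))
    return out


def read_patterns(path: str | Path) -> list[PRMPattern]:
    """Read patterns from text: ``NAME<TAB>TOKENS`` or bare token strings.

    Tokens: uppercase literals, ``f`` for Φ, ``x`` for any residue.
    """
    patterns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, spec = line.split("\t", 1)
            else:
                name, spec = f"pattern{lineno}", line
            patterns.append(PRMPattern.from_string(name.strip(), spec.strip()))
    return patterns


def write_matches_tsv(matches: Iterable[PRMMatch], path, header=None) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tpattern\tstart\tend\tn_mismatches\n")
        for m in matches:
            fh.write(f"{m.protein_id}\t{m.pattern_name}\t{m.start}\t{m.end}\t{m.n_mismatches}\n")


def write_matches_gff3(matches: Iterable[PRMMatch], path, header=None) -> None:
    """Protein-space GFF3-like features: seqid = protein id, type = PRM."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header or []:
            fh.write(f"# {line}\n")
        for m in matches:
            fh.write(
                f"{m.protein_id}\tprmscan\tPRM\t{m.start}\t{m.end}\t"
                f"{m.n_mismatches}\t.\t.\tName={m.pattern_name}\n"
            )
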