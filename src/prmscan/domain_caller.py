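"""Calling TRD3-like proline-rich domains from window profiles and PRM hits.

The call logic follows the defining description of these domains: regions of
high polyproline-II character combined with either high hydrophobicity or
high Pro/Gly/Gln content.  Concretely, a window is a *candidate* iff

    ppii >= P(ppii_percentile)  AND
    (hydropathy >= P(hydropathy_percentile) OR pgq >= P(pgq_percentile))

where P(.) are per-protein percentiles of that protein's own profile, making
the rule scale-free (robust to the pluggable PPII scale).  Candidate windows
separated by fewer than ``merge_gap`` residues fuse into regions; regions
shorter than ``min_length`` or lacking PRM support are dropped.

An optional boundary screen aligns reference R1/R2 repression domains
(e.g. from KLF10/KLF11) against the call's N terminus and advances the start
past any confidently aligned block, so that the reported domain begins after
the known upstream domains.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .conservation import BLOSUM62_DEFAULT, SubstitutionMatrix, align_global_free_ends
from .prm_scanner import PRMMatch
from .sequence_io import ProteinRecord
from .window_profiler import WindowProfile

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DomainCallConfig:
    """Thresholds for domain calling.

    Percentiles are per-protein, in (0, 100); ``merge_gap`` (residues)
    defaults to the window size so islands separated by less than one
    window fuse.
    """

    ppii_percentile: float = 75.0
    hydropathy_percentile: float = 75.0
    pgq_percentile: float = 75.0
    merge_gap: int = 15
    min_prm_support: int = 1
    min_length: int = 20

    def __post_init__(self) -> None:
        for p in (self.ppii_percentile, self.hydropathy_percentile, self.pgq_percentile):
            if not (0 < p < 100):
                raise ValueError("percentile thresholds must be in (0, 100)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclasses.dataclass(frozen=True)
class DomainCall:
    """One called domain (1-based inclusive protein coordinates)."""

    protein_id: str
    start: int
    end: int
    n_windows: int
    prm_matches: tuple[PRMMatch, ...] = ()
    flags: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.end - self.start + 1


def candidate_windows(profile: WindowProfile, config: DomainCallConfig) -> np.ndarray:
    """Boolean mask of candidate windows under the combination rule."""
    ppii_thr = np.percentile(profile.ppii, config.ppii_percentile)
    kd_thr = np.percentile(profile.hydropathy, config.hydropathy_percentile)
    pgq_thr = np.percentile(profile.pgq, config.pgq_percentile)
    return (profile.ppii >= ppii_thr) & (
        (profile.hydropathy >= kd_thr) | (profile.pgq >= pgq_thr)
    )


def call_domains(
    profile: WindowProfile,
    matches: Sequence[PRMMatch],
    config: DomainCallConfig = DomainCallConfig(),
) -> list[DomainCall]:
    """Merge candidate windows into domain calls and filter them.

    A region spans from its first candidate window's start to its last
    candidate window's end; only PRM matches fully inside the span count as
    support.  Calls are sorted by start.
    """
    if len(profile) == 0:
        raise ValueError("empty window profile")
    for m in matches:
        if m.protein_id and m.protein_id != profile.protein_id:
            raise ValueError(
                f"match on {m.protein_id!r} does not belong to profile of "
                f"{profile.protein_id!r}"
            )

    mask = candidate_windows(profile, config)
    w = profile.window_size
    calls: list[DomainCall] = []
    groups: list[list[int]] = []
    for i in np.nonzero(mask)[0]:
        s = int(profile.starts[i])
        if groups:
            prev_end = int(profile.starts[groups[-1][-1]]) + w - 1
            if s - prev_end - 1 < config.merge_gap:
                groups[-1].append(int(i))
                continue
        groups.append([int(i)])

    for g in groups:
        start = int(profile.starts[g[0]])
        end = int(profile.starts[g[-1]]) + w - 1
        contained = tuple(
            m for m in matches if m.start >= start and m.end <= end
        )
        if end - start + 1 < config.min_length:
            continue
        if len(contained) < config.min_prm_support:
            continue
        calls.append(
            DomainCall(
                protein_id=profile.protein_id,
                start=start,
                end=end,
                n_windows=len(g),
                prm_matches=contained,
            )
        )
    calls.sort(key=lambda c: c.start)
    return calls


def screen_boundary(
    call: DomainCall,
    record: ProteinRecord,
    references: Sequence[ProteinRecord],
    identity_threshold: float = 0.4,
    coverage_threshold: float = 0.8,
    matrix: SubstitutionMatrix = BLOSUM62_DEFAULT,
    max_block_offset: int = 15,
) -> Optional[DomainCall]:
    """Trim a call's N-terminal boundary against reference R1/R2 domains.

    Each reference is aligned (free end gaps) to the call's sequence.  When a
    reference aligns with identity >= ``identity_threshold`` over >=
    ``coverage_threshold`` of its own length, with the aligned block starting
    within ``max_block_offset`` residues of the call's N terminus, the call
    start advances past the block and the call is flagged ``trimmed-R1R2``.
    Returns None (with a log note) if trimming would empty the call.
    """
    if not references:
        raise ValueError("need at least one reference domain sequence")
    call_seq = record.sequence[call.start - 1 : call.end]
    call_rec = ProteinRecord(id=f"{record.id}/call", sequence=call_seq)

    best_cut = 0
    for ref in references:
        aln = align_global_free_ends(ref, call_rec, matrix)
        # columns where the reference has a residue, in call coordinates
        ref_res = np.array([c != "-" for c in aln.aligned_a])
        call_res = np.array([c != "-" for c in aln.aligned_b])
        both = ref_res & call_res
        if not both.any():
            continue
        cols = np.nonzero(both)[0]
        block = slice(cols[0], cols[-1] + 1)
        aligned_cols = int(both[block].sum())
        ident = sum(
            a == b
            for a, b, k in zip(aln.aligned_a[block], aln.aligned_b[block], both[block])
            if k
        ) / aligned_cols
        coverage = aligned_cols / len(ref)
        block_start_in_call = int(call_res[: cols[0]].sum())  # 0-based
        block_end_in_call = int(call_res[: cols[-1] + 1].sum())  # 1-based count
        if (
            ident >= identity_threshold
            and coverage >= coverage_threshold
            and block_start_in_call < max_block_offset
        ):
            best_cut = max(best_cut, block_end_in_call)

    if best_cut == 0:
        return call
    new_start = call.start + best_cut
    if new_start > call.end:
        logger.info(
            "dropping call %s:%d-%d: reference trim consumed the whole call",
            call.protein_id, call.start, call.end,
        )
        return None
    kept = tuple(m for m in call.prm_matches if m.start >= new_start)
    return dataclasses.replace(
        call,
        start=new_start,
        prm_matches=kept,
        flags=call.flags + ("trimmed-R1R2",),
    )


def write_calls_tsv(calls: Sequence[DomainCall], path, header=None) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tstart\tend\tn_windows\tn_prm\tflags\n")
        for c in calls:
            fh.write(
                f"{c.protein_id}\t{c.start}\t{c.end}\t{c.n_windows}\t"
                f"{len(c.prm_matches)}\t{','.join(c.flags) or '.'}\n"
            )


def write_calls_gff3(calls: Sequence[DomainCall], path, header=None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header or []:
            fh.write(f"# {line}\n")
        for c in calls:
            fh.write(
                f"{c.protein_id}\tprmscan\tdomain\t{c.start}\t{c.end}\t.\t.\t.\t"
                f"Name=TRD3-like;n_prm={len(c.prm_matches)}\n"
            )
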