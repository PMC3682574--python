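"""Seed-deterministic synthetic data generators with machine-readable truth.

Two generators cover the package's inputs:

* :func:`simulate_proteins` — proteins built from a charged/polar background
  with planted PRM-rich hydrophobic islands, emulating the observed
  architecture of TRD3-like domains: polyproline-enriched islands amid
  hydrophobic stretches, flanked by charged/polar sequence.
* :func:`simulate_tiling` — promoter tiling-array datasets: Gaussian log2
  ratio noise over 5-kb upstream spans with spike-in enriched probe runs in
  a subset of promoters.

Every generator is a pure function of (config, seed) and returns ground
truth alongside the data.  :func:`synthetic_trd3_protein` builds a fixed
KLF11-like protein for end-to-end demonstrations; it is synthetic, not the
curated human sequence.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .prm_scanner import (
    ANY_TOKEN,
    BUILTIN_PATTERNS,
    PHI_DEFAULT,
    PHI_TOKEN,
    HydrophobicClass,
    PRMPattern,
)
from .sequence_io import ProteinRecord
from .tiling_peaks import UPSTREAM_BP, PromoterRegion

#: Charged/polar background alphabet: maximal contrast with the Φ class.
BACKGROUND_ALPHABET = "DEKRNSTH"
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class ProteinSimConfig:
    """Configuration for the planted-island protein generator."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (150, 250)
    islands_per_protein: int = 1
    linker_range: tuple[int, int] = (2, 6)
    patterns: tuple[PRMPattern, ...] = BUILTIN_PATTERNS
    phi: HydrophobicClass = PHI_DEFAULT
    background_alphabet: str = BACKGROUND_ALPHABET
    background_freqs: tuple[float, ...] | None = None  # None = uniform

    def __post_init__(self) -> None:
        if self.background_freqs is not None:
            if len(self.background_freqs) != len(self.background_alphabet):
                raise ValueError("one frequency per background residue required")
            if abs(sum(self.background_freqs) - 1.0) > 1e-9:
                raise ValueError("background frequencies must sum to 1")


@dataclasses.dataclass(frozen=True)
class PlantedIsland:
    """Truth for one planted island."""

    start: int  # 1-based inclusive
    end: int
    prm_positions: dict[str, int]  # pattern name -> 1-based start


@dataclasses.dataclass(frozen=True)
class ProteinGroundTruth:
    islands: dict[str, list[PlantedIsland]]  # protein id -> islands

    def to_json(self) -> str:
        payload = {
            pid: [
                {"start": isl.start, "end": isl.end, "prms": isl.prm_positions}
                for isl in isls
            ]
            for pid, isls in self.islands.items()
        }
        return json.dumps(payload, indent=1)


def _instantiate_pattern(
    pattern: PRMPattern, phi: HydrophobicClass, rng: np.random.Generator
) -> str:
    phi_members = sorted(phi.members)
    out = []
    for tok in pattern.positions:
        if tok == PHI_TOKEN:
            out.append(phi_members[rng.integers(len(phi_members))])
        elif tok == ANY_TOKEN:
            out.append(CANONICAL[rng.integers(len(CANONICAL))])
        else:
            out.append(tok)
    return "".join(out)


def _build_island(
    config: ProteinSimConfig, rng: np.random.Generator
) -> tuple[str, dict[str, int]]:
    """Island = PRM instances separated by short hydrophobic linkers."""
    phi_members = sorted(config.phi.members)
    lo, hi = config.linker_range
    parts: list[str] = []
    offsets: dict[str, int] = {}
    pos = 0
    for k, pat in enumerate(config.patterns):
        if k > 0:
            linker_len = int(rng.integers(lo, hi + 1))
            linker = "".join(
                phi_members[i] for i in rng.integers(len(phi_members), size=linker_len)
            )
            parts.append(linker)
            pos += linker_len
        inst = _instantiate_pattern(pat, config.phi, rng)
        offsets[pat.name] = pos  # 0-based within island
        parts.append(inst)
        pos += len(inst)
    return "".join(parts), offsets


def simulate_proteins(
    config: ProteinSimConfig = ProteinSimConfig(), seed: int | None = None
) -> tuple[list[ProteinRecord], ProteinGroundTruth]:
    """Generate proteins with planted PRM islands and exact truth coordinates.

    A mandatory seed makes generation byte-deterministic.  Raises when the
    islands cannot fit in the configured protein length.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    bg = np.array(list(config.background_alphabet))
    freqs = (
        np.array(config.background_freqs)
        if config.background_freqs is not None
        else None
    )

    records: list[ProteinRecord] = []
    truth: dict[str, list[PlantedIsland]] = {}
    for i in range(config.n_proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        islands: list[tuple[str, dict[str, int]]] = [
            _build_island(config, rng) for _ in range(config.islands_per_protein)
        ]
        total_island = sum(len(s) for s, _ in islands)
        if total_island > L:
            raise ValueError(
                f"islands ({total_island} aa) exceed protein length {L}; "
                "increase length_range"
            )
        # place islands without overlap by splitting the leftover background
        n_gaps = config.islands_per_protein + 1
        leftover = L - total_island
        cuts = np.sort(rng.integers(0, leftover + 1, size=n_gaps - 1))
        gap_lens = np.diff(np.concatenate([[0], cuts, [leftover]]))
        seq_parts: list[str] = []
        pid = f"sim{i:04d}"
        planted: list[PlantedIsland] = []
        cursor = 0
        for g, (island_seq, offsets) in zip(gap_lens[:-1], islands):
            bg_seq = "".join(rng.choice(bg, size=int(g), p=freqs))
            seq_parts.append(bg_seq)
            cursor += int(g)
            start = cursor + 1  # 1-based
            planted.append(
                PlantedIsland(
                    start=start,
                    end=cursor + len(island_seq),
                    prm_positions={
                        name: start + off for name, off in offsets.items()
                    },
                )
            )
            seq_parts.append(island_seq)
            cursor += len(island_seq)
        seq_parts.append("".join(rng.choice(bg, size=int(gap_lens[-1]), p=freqs)))
        records.append(ProteinRecord(id=pid, sequence="".join(seq_parts)))
        truth[pid] = planted
    return records, ProteinGroundTruth(islands=truth)


def simulate_background_proteins(
    config: ProteinSimConfig = ProteinSimConfig(), seed: int | None = None
) -> list[ProteinRecord]:
    """Island-free negative controls drawn from the background alphabet."""
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    bg = np.array(list(config.background_alphabet))
    freqs = (
        np.array(config.background_freqs)
        if config.background_freqs is not None
        else None
    )
    out = []
    for i in range(config.n_proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        out.append(
            ProteinRecord(id=f"bg{i:04d}", sequence="".join(rng.choice(bg, size=L, p=freqs)))
        )
    return out


@dataclasses.dataclass(frozen=True)
class TilingGroundTruth:
    """Spiked promoters and the genomic span of each spiked probe run."""

    spiked: dict[str, tuple[int, int]]  # gene id -> (first bp, last bp) of spike

    def to_json(self) -> str:
        return json.dumps(
            {g: {"start": s, "end": e} for g, (s, e) in self.spiked.items()}, indent=1
        )


def simulate_tiling(
    n_promoters: int = 200,
    probe_spacing_bp: int = 100,
    noise_sd: float = 0.5,
    n_spiked: int = 10,
    spike_len_probes: int = 5,
    spike_shift: float = 2.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[PromoterRegion], TilingGroundTruth]:
    """Simulate a promoter tiling array with spike-in enriched probe runs.

    Probes tile each 5-kb upstream span at ``probe_spacing_bp``; log2 ratios
    are N(0, noise_sd); in ``n_spiked`` randomly chosen promoters a run of
    ``spike_len_probes`` consecutive probes is shifted by ``spike_shift``.
    Strands alternate 50/50.  Returns (probes, promoters, truth).
    """
    if seed is None:
        raise ValueError("a seed is required")
    if probe_spacing_bp > UPSTREAM_BP:
        raise ValueError("probe spacing exceeds the 5-kb promoter span")
    if n_spiked > n_promoters:
        raise ValueError("cannot spike more promoters than exist")
    rng = np.random.default_rng(seed)

    promoters: list[PromoterRegion] = []
    rows: list[tuple[str, int, float]] = []
    spiked_ids = set(rng.choice(n_promoters, size=n_spiked, replace=False).tolist())
    truth: dict[str, tuple[int, int]] = {}

    block = 2 * UPSTREAM_BP + 2000  # genomic room per promoter, no overlap
    n_probes_per = UPSTREAM_BP // probe_spacing_bp
    for i in range(n_promoters):
        gene = f"gene{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        base = i * block
        tss = base + UPSTREAM_BP + 500 if strand == "+" else base + 500
        prom = PromoterRegion(gene, "chr1", tss, strand)
        promoters.append(prom)
        lo, hi = prom.span
        pos = np.arange(lo, hi + 1, probe_spacing_bp)[:n_probes_per]
        vals = rng.normal(0.0, noise_sd, size=pos.size)
        if i in spiked_ids:
            if spike_len_probes > pos.size:
                raise ValueError("spike longer than the probe run in the span")
            s0 = int(rng.integers(0, pos.size - spike_len_probes + 1))
            vals[s0 : s0 + spike_len_probes] += spike_shift
            truth[gene] = (int(pos[s0]), int(pos[s0 + spike_len_probes - 1]))
        rows.extend(("chr1", int(p), float(v)) for p, v in zip(pos, vals))

    probes = pd.DataFrame(rows, columns=["chrom", "position", "log2ratio"])
    probes = probes.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)
    return probes, promoters, TilingGroundTruth(spiked=truth)


def synthetic_trd3_protein() -> tuple[ProteinRecord, "PlantedIsland"]:
    """A fixed synthetic KLF11-like protein for end-to-end demonstrations.

    SYNTHETIC STAND-IN: this is *not* the curated human KLF11 sequence; it
    is a deterministic 512-residue protein whose region 281-373 carries the
    four PRM consensus motifs in order (PRM1 N-terminal-most, PRM4
    C-terminal-most) embedded in a hydrophobic Gly/Gln environment, with
    charged/polar flanks — the architecture reported for the TRD3 region.
    """
    rng = np.random.default_rng(20120415)
    config = ProteinSimConfig(n_proteins=1)
    island_seq, offsets = _build_island(config, rng)
    bg = np.array(list(BACKGROUND_ALPHABET))
    # pad the island with hydrophobic/G/Q environment out to 93 aa (281..373)
    env_alphabet = np.array(list("ACFILMVGQ"))
    region_len = 373 - 281 + 1
    pad = region_len - len(island_seq)
    pad_left = pad // 2
    pad_right = pad - pad_left
    env_l = "".join(rng.choice(env_alphabet, size=pad_left))
    env_r = "".join(rng.choice(env_alphabet, size=pad_right))
    nterm = "".join(rng.choice(bg, size=280))
    cterm = "".join(rng.choice(bg, size=512 - 373))
    seq = nterm + env_l + island_seq + env_r + cterm
    assert len(seq) == 512
    island_start = 281 + pad_left
    truth = PlantedIsland(
        start=island_start,
        end=island_start + len(island_seq) - 1,
        prm_positions={n: island_start + o for n, o in offsets.items()},
    )
    return (
        ProteinRecord(
            id="KLF11like_synthetic",
            sequence=seq,
            description="synthetic TRD3-bearing protein (not UniProt O14901)",
        ),
        truth,
    )
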