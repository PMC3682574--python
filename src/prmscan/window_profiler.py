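"""Sliding-window triplet profiling of protein sequences.

Each window of ``w`` residues (default 15, stepping by 1) is scored three
ways on the same residues:

* **hydropathy** — unweighted mean of Kyte-Doolittle values;
* **ppii** — unweighted mean of a polyproline-II propensity scale;
* **pgq** — fraction of the window that is Pro, Gly or Gln, in [0, 1].

Proline-rich interaction domains appear in such profiles as islands of high
PPII propensity and PGQ content embedded in hydrophobic stretches.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .scales import KYTE_DOOLITTLE, PPII_DEFAULT, AminoAcidScale
from .sequence_io import ProteinRecord

DEFAULT_WINDOW = 15


def window_score(window: str, scale: AminoAcidScale) -> float:
    """Arithmetic mean of per-residue scale values over one window.

    X residues contribute the scale's median.
    """
    if not window:
        raise ValueError("window must be non-empty")
    return sum(scale.score(r) for r in window) / len(window)


def pgq_index(window: str) -> float:
    """Fraction of the window that is proline, glycine or glutamine."""
    if not window:
        raise ValueError("window must be non-empty")
    n = sum(window.count(r) for r in "PGQ")
    return n / len(window)


@dataclasses.dataclass(frozen=True)
class WindowProfile:
    """Per-window score triplets for one protein.

    ``starts`` are 1-based window start positions; a window at start ``s``
    covers residues ``s .. s + window_size - 1`` inclusive.
    """

    protein_id: str
    window_size: int
    step: int
    starts: np.ndarray
    hydropathy: np.ndarray
    ppii: np.ndarray
    pgq: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "window_start": self.starts,
                "hydropathy": self.hydropathy,
                "ppii": self.ppii,
                "pgq": self.pgq,
            }
        )

    def to_tsv(self, path, header: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _scale_vector(scale: AminoAcidScale) -> np.ndarray:
    # index residues by ord() for vectorized lookup; X -> median
    vec = np.full(91, np.nan)
    for r, v in scale.values.items():
        vec[ord(r)] = v
    vec[ord("X")] = scale.median
    return vec


def profile(
    record: ProteinRecord,
    w: int = DEFAULT_WINDOW,
    step: int = 1,
    kd_scale: AminoAcidScale = KYTE_DOOLITTLE,
    ppii_scale: AminoAcidScale = PPII_DEFAULT,
) -> WindowProfile:
    """Profile a protein with all three scores on each sliding window.

    Produces ``floor((L - w) / step) + 1`` rows for a length-L sequence;
    raises ``ValueError`` when L < w.
    """
    L = len(record)
    if L < w:
        raise ValueError(
            f"sequence {record.id!r} has length {L}; needs at least w={w} residues"
        )
    if w < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")

    codes = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    kd_vals = _scale_vector(kd_scale)[codes]
    ppii_vals = _scale_vector(ppii_scale)[codes]
    is_pgq = np.isin(codes, [ord("P"), ord("G"), ord("Q")]).astype(float)

    # cumulative sums give every window mean in O(L)
    def win_means(x: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(x)])
        sums = cs[w:] - cs[:-w]
        return sums[::step] / w

    starts = np.arange(0, L - w + 1, step) + 1
    return WindowProfile(
        protein_id=record.id,
        window_size=w,
        step=step,
        starts=starts,
        hydropathy=win_means(kd_vals),
        ppii=win_means(ppii_vals),
        pgq=win_means(is_pgq),
    )
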