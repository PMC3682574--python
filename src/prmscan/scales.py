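"""Per-residue amino-acid scales used by the window profiler.

Two scales ship with the package:

* ``KYTE_DOOLITTLE`` — the standard Kyte-Doolittle hydropathy values
  (Ile 4.5 ... Arg -4.5).
* ``PPII_DEFAULT`` — a polyproline-II helix propensity scale.  This is a
  synthetic, rank-faithful stand-in following experimental host-guest PPII
  trends (proline highest; glutamine, alanine and charged residues
  intermediate; aromatic and beta-branched residues lowest).  Downstream
  domain calling compares PPII scores only through per-protein percentiles,
  so only the ranking matters; a measured scale can be substituted via
  :func:`read_scale`.

The residue X (unknown) is scored with the scale's median value.
"""

from __future__ import annotations

import dataclasses
import statistics
from pathlib import Path
from typing import Mapping

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class AminoAcidScale:
    """A named mapping from each of the 20 canonical residues to a value."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        for res, v in self.values.items():
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"scale {self.name!r}: non-finite value for {res}")

    @property
    def median(self) -> float:
        return statistics.median(self.values[r] for r in CANONICAL_RESIDUES)

    def score(self, residue: str) -> float:
        """Value for one residue; X maps to the scale median."""
        if residue == "X":
            return self.median
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} absent from scale {self.name!r}"
            ) from None


KYTE_DOOLITTLE = AminoAcidScale(
    "kyte-doolittle",
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

# Synthetic PPII propensity stand-in: values are constructed, the *ranking*
# follows experimental host-guest trends (Pro >> Gln/Ala/charged > G/H >
# aromatics/beta-branched).  Replaceable at every call site.
PPII_DEFAULT = AminoAcidScale(
    "ppii-synthetic-hostguest",
    {
        "P": 1.00, "Q": 0.66, "A": 0.64, "R": 0.62, "L": 0.56,
        "S": 0.54, "K": 0.52, "E": 0.51, "M": 0.50, "D": 0.48,
        "N": 0.46, "T": 0.44, "I": 0.42, "C": 0.41, "G": 0.40,
        "V": 0.39, "H": 0.38, "F": 0.34, "Y": 0.32, "W": 0.30,
    },
)


def read_scale(path: str | Path, name: str | None = None) -> AminoAcidScale:
    """Read a scale from a 2-column text file (residue, value).

    Lines starting with ``#`` are comments.
    """
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'RESIDUE VALUE'")
            values[parts[0].upper()] = float(parts[1])
    return AminoAcidScale(name or path.stem, values)


def write_scale(scale: AminoAcidScale, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale: {scale.name}\n")
        for r in CANONICAL_RESIDUES:
            fh.write(f"{r}\t{scale.values[r]}\n")
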