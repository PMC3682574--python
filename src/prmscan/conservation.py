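"""Cross-ortholog conservation: pairwise alignment, distances, NJ trees.

Alignment is exact semi-global dynamic programming — global alignment with
free end gaps — under BLOSUM62 with affine gap costs (defaults: open 10,
extend 1).  Distances are 1 - fractional identity over the aligned
(non-end-gap) columns, with an optional Poisson correction.  Trees are
built by neighbor joining and rooted at the midpoint of the outgroup's
pendant edge, matching the analysis settings used for the cabut/KLF family
(BLOSUM62, free gap ends, outgroup = cabut).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SubstitutionMatrix:
    """A named residue substitution matrix with affine gap penalties."""

    name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def to_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(self.name)
        aligner.mode = "global"
        # affine: first gap residue costs open, each further one extend
        aligner.open_internal_gap_score = -self.gap_open
        aligner.extend_internal_gap_score = -self.gap_extend
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
        return aligner


BLOSUM62_DEFAULT = SubstitutionMatrix()


@dataclasses.dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal free-end-gap alignment of two sequences."""

    ids: tuple[str, str]
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")


def _identity(aligned_a: str, aligned_b: str) -> float:
    """Fractional identity over non-end-gap columns.

    End-gap columns (leading/trailing overhangs of either sequence) are
    excluded; internal gap columns count in the denominator.
    """
    n = len(aligned_a)
    a_res = [c != "-" for c in aligned_a]
    b_res = [c != "-" for c in aligned_b]

    def span(res):
        idx = [i for i, r in enumerate(res) if r]
        return idx[0], idx[-1]

    a0, a1 = span(a_res)
    b0, b1 = span(b_res)
    lo, hi = max(a0, b0), min(a1, b1)
    if hi < lo:
        return 0.0
    cols = hi - lo + 1
    same = sum(
        1
        for i in range(lo, hi + 1)
        if aligned_a[i] == aligned_b[i] and aligned_a[i] != "-"
    )
    return same / cols


def align_global_free_ends(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: SubstitutionMatrix = BLOSUM62_DEFAULT,
) -> PairwiseAlignment:
    """Optimal semi-global alignment of two protein records.

    Leading and trailing gaps are unpenalized; gaps are affine
    (open + extend per additional residue).  The first optimal alignment in
    the aligner's deterministic enumeration order is reported.
    """
    aligner = matrix.to_aligner()
    alignments = aligner.align(a.sequence, b.sequence)
    aln = alignments[0]
    sa, sb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(
        ids=(a.id, b.id),
        aligned_a=sa,
        aligned_b=sb,
        score=float(aln.score),
        identity=_identity(sa, sb),
    )


def distance_matrix(
    records: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix = BLOSUM62_DEFAULT,
    poisson: bool = False,
) -> DistanceMatrix:
    """All-pairs distances d = 1 - identity (optionally Poisson-corrected).

    The Poisson correction is d = -ln(identity), clipped for identity 0.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in distance matrix input")
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = align_global_free_ends(records[i], records[j], matrix).identity
            if poisson:
                dist = -math.log(ident) if ident > 0 else 10.0
            else:
                dist = 1.0 - ident
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


@dataclasses.dataclass(frozen=True)
class PhyloTree:
    """A rooted NJ tree with the root on the outgroup's pendant edge."""

    root: TreeNode
    outgroup: str

    @property
    def newick(self) -> str:
        return str(self.root).strip()

    def write(self, path) -> None:
        self.root.write(str(path), format="newick")

    def patristic_distance(self, a: str, b: str) -> float:
        return float(self.root.find(a).distance(self.root.find(b)))

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]


def _clamp_negative_branches(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            logger.info("clamping negative branch length %.4g to 0", node.length)
            node.length = 0.0


def neighbor_joining(dm: DistanceMatrix, outgroup: str) -> PhyloTree:
    """Neighbor-joining tree rooted at the midpoint of the outgroup edge.

    Negative branch lengths produced by NJ on non-additive data are clamped
    to zero (with a log note).
    """
    if outgroup not in dm.ids:
        raise ValueError(f"outgroup {outgroup!r} not among leaves {list(dm.ids)}")
    unrooted = nj(dm)
    _clamp_negative_branches(unrooted)
    tip = unrooted.find(outgroup)
    half = (tip.length or 0.0) / 2.0
    rooted = unrooted.root_at(tip, above=half if half > 0 else True,
                              branch_attrs=[], root_name=None)
    return PhyloTree(root=rooted, outgroup=outgroup)


def write_distance_tsv(dm: DistanceMatrix, path, header=None) -> None:
    """Square distance matrix as TSV with leading id row/column."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, name in enumerate(dm.ids):
            fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in dm[i]) + "\n")
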