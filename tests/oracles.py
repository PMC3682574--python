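"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is a deliberately naive re-derivation of an operation's
definition — direct enumeration, position-by-position scanning, exhaustive
window sliding — kept free of the implementation code paths it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from prmscan.prm_scanner import ANY_TOKEN, PHI_TOKEN
from prmscan.tiling_peaks import (
    DEFAULT_CUTOFF_PERCENTS,
    promoter_space_cutoffs,
)

# ---------------------------------------------------------------- PRM scan


def naive_scan(sequence, patterns, phi_members, max_mismatch):
    """Position-by-position O(L * |pattern|) scan; raw (uncollapsed) hits."""
    hits = []
    for pat in patterns:
        plen = len(pat.positions)
        for start in range(1, len(sequence) - plen + 2):
            mm = 0
            for off, tok in enumerate(pat.positions):
                res = sequence[start - 1 + off]
                if tok == ANY_TOKEN:
                    continue
                if res == "X":
                    mm += 1
                elif tok == PHI_TOKEN:
                    mm += res not in phi_members
                else:
                    mm += res != tok
            if mm <= max_mismatch:
                hits.append((pat.name, start, mm))
    return sorted(hits)


# ------------------------------------------------------------- alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignments(a: str, b: str):
    """Yield every monotone alignment of a and b as gapped string pairs."""

    def rec(i, j, sa, sb):
        if i == len(a) and j == len(b):
            yield sa, sb
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, sa + a[i], sb + b[j])
        if i < len(a):
            yield from rec(i + 1, j, sa + a[i], sb + "-")
        if j < len(b):
            yield from rec(i, j + 1, sa + "-", sb + b[j])

    yield from rec(0, 0, "", "")


def score_alignment(sa: str, sb: str, gap_open=10.0, gap_extend=1.0) -> float:
    """BLOSUM62 score with affine gaps; leading/trailing gap runs are free."""
    n = len(sa)
    s = 0.0
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            s += _BLOSUM62[x][y]
    for g in (sa, sb):
        i = 0
        while i < n:
            if g[i] == "-":
                j = i
                while j < n and g[j] == "-":
                    j += 1
                if i != 0 and j != n:  # internal gap run
                    s -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    return s


def best_alignment_score(a: str, b: str) -> float:
    return max(score_alignment(sa, sb) for sa, sb in enumerate_alignments(a, b))


# ------------------------------------------------------------------ trees

from skbio import TreeNode  # noqa: E402
from io import StringIO  # noqa: E402


def random_additive_tree(n_taxa: int, rng: np.random.Generator) -> TreeNode:
    """A random topology with positive branch lengths (hence additive)."""
    t = TreeNode.read(StringIO("(t0:1,t1:1,t2:1);"))
    for name in ("t0", "t1", "t2"):
        t.find(name).length = float(rng.uniform(0.5, 2.0))
    for i in range(3, n_taxa):
        edges = list(t.traverse(include_self=False))
        edge = edges[rng.integers(len(edges))]
        parent = edge.parent
        newint = TreeNode(length=float(edge.length) / 2)
        edge.length = float(edge.length) / 2
        parent.remove(edge)
        parent.append(newint)
        newint.append(edge)
        newint.append(TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 2.0))))
    return t


def tree_distances(t: TreeNode, names: list[str]) -> np.ndarray:
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = t.find(names[i]).distance(t.find(names[j]))
    return m


# ------------------------------------------------------------------ peaks


def brute_force_peaks(
    probes,
    promoters,
    window_bp=500,
    min_probes=4,
    cutoff_percents=DEFAULT_CUTOFF_PERCENTS,
    cutoff_mode="range",
):
    """Exhaustive 1-bp sliding-window peak enumeration.

    Returns sorted tuples (gene, start, end, score, level) for comparison
    with the implementation's peak list.
    """
    cutoffs = promoter_space_cutoffs(probes, promoters, cutoff_percents, cutoff_mode)
    out = []
    for prom in promoters:
        sub = probes[probes["chrom"] == prom.chrom]
        lo, hi = prom.span
        inside = sub[(sub["position"] >= lo) & (sub["position"] <= hi)]
        if len(inside) == 0:
            continue
        pos = inside["position"].to_numpy()
        val = inside["log2ratio"].to_numpy()
        accepted = []
        for level in sorted(cutoff_percents, reverse=True):
            cut = cutoffs[level]
            above = val > cut
            apos = pos[above]
            avals = val[above]
            member_sets = set()
            for s in range(lo - window_bp + 1, hi + 1):
                in_win = (apos >= s) & (apos <= s + window_bp - 1)
                if in_win.sum() >= min_probes:
                    member_sets.add(tuple(np.nonzero(in_win)[0]))
            merged: list[set] = []
            for ms in sorted((set(t) for t in member_sets), key=min):
                if merged and min(ms) <= max(merged[-1]):
                    merged[-1] |= ms
                else:
                    merged.append(set(ms))
            for ms in merged:
                mi = sorted(ms)
                startbp, endbp = int(apos[mi[0]]), int(apos[mi[-1]])
                if any(startbp <= e and endbp >= s2 for s2, e, _, _ in accepted):
                    continue
                sv = np.sort(avals[mi])[::-1]
                k = min(min_probes, 4)
                score = float(sv[k - 1]) if sv.size >= k else float(sv[-1])
                accepted.append((startbp, endbp, score, level))
        for s2, e, sc, level in accepted:
            out.append((prom.gene_id, s2, e, round(sc, 9), level))
    return sorted(out)
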