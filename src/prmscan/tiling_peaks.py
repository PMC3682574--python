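"""Promoter tiling-array (ChIP-chip) peak detection with permutation FDR.

The procedure mirrors the NimbleGen-style promoter analysis workflow:

1. Work within the 5-kb strand-aware span upstream of each TSS.
2. Walk a descending ladder of cutoff levels (90% down to 15% in 5% steps);
   the cutoff *value* at level p interpolates between the median and the
   maximum of the promoter-space log2-ratio distribution:
   ``cutoff = q50 + (p/100) * (qmax - q50)``.
3. At each level, any 500-bp window holding >= 4 probes above the cutoff
   seeds a peak; overlapping seeds at the same level merge; peaks found at
   a higher cutoff suppress overlapping rediscovery at lower cutoffs.
4. A peak's score is the log2 ratio of its 4th-highest member probe.
5. Per gene, only the peak nearest the TSS is reported.
6. The FDR of each observed peak score s is estimated from value-shuffled
   data (default 20 randomizations): mean permuted count of peaks scoring
   >= s divided by the observed count; peaks with FDR < 0.2 are deemed
   high-confidence.

Probes are a BED-like table (chrom, position, log2ratio); promoters a table
(gene_id, chrom, tss, strand).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UPSTREAM_BP = 5000
DEFAULT_CUTOFF_PERCENTS = tuple(range(90, 14, -5))  # 90, 85, ..., 15


@dataclasses.dataclass(frozen=True)
class PromoterRegion:
    """A strand-aware 5-kb upstream promoter span."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive bp range of the upstream window."""
        if self.strand == "+":
            return (self.tss - UPSTREAM_BP, self.tss - 1)
        return (self.tss + 1, self.tss + UPSTREAM_BP)


@dataclasses.dataclass(frozen=True)
class Peak:
    """A called peak with 4th-order-statistic score."""

    gene_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    score: float
    cutoff_level: int
    distance_to_tss: int
    fdr: float | None = None


def read_probes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "position", "log2ratio"],
        dtype={"chrom": str, "position": int, "log2ratio": float},
    )
    return df


def read_promoters(path: str | Path) -> list[PromoterRegion]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["gene_id", "chrom", "tss", "strand"],
        dtype={"gene_id": str, "chrom": str, "tss": int, "strand": str},
    )
    return [PromoterRegion(*row) for row in df.itertuples(index=False)]


def _validate_probes(probes: pd.DataFrame) -> pd.DataFrame:
    if not np.isfinite(probes["log2ratio"]).all():
        raise ValueError("probe log2 ratios must be finite")
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["position"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(
                f"probes on {chrom} must be sorted with strictly increasing positions"
            )
    return probes


def promoter_space_cutoffs(
    probes: pd.DataFrame,
    promoters: Sequence[PromoterRegion],
    cutoff_percents: Sequence[int] = DEFAULT_CUTOFF_PERCENTS,
    cutoff_mode: str = "range",
) -> dict[int, float]:
    """Cutoff value per level from the promoter-space ratio distribution.

    ``cutoff_mode="range"`` (default) anchors level p between the median and
    the maximum: ``q50 + (p/100) * (qmax - q50)``.  ``cutoff_mode=
    "percentile"`` instead uses the p-th percentile of the distribution.
    """
    vals: list[np.ndarray] = []
    for prom in promoters:
        sub = probes[probes["chrom"] == prom.chrom]
        lo, hi = prom.span
        inside = sub[(sub["position"] >= lo) & (sub["position"] <= hi)]
        vals.append(inside["log2ratio"].to_numpy())
    allv = np.concatenate(vals) if vals else np.array([])
    if allv.size == 0:
        raise ValueError("no probes fall inside any promoter span")
    if cutoff_mode == "range":
        q50 = float(np.median(allv))
        qmax = float(allv.max())
        return {p: q50 + (p / 100.0) * (qmax - q50) for p in cutoff_percents}
    if cutoff_mode == "percentile":
        return {p: float(np.percentile(allv, p)) for p in cutoff_percents}
    raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")


def _seed_windows(
    pos: np.ndarray, above: np.ndarray, window_bp: int, min_probes: int
) -> list[tuple[int, int]]:
    """Index ranges [i, j] (into ``pos``) of merged above-cutoff probe runs.

    Windows are anchored at each above-cutoff probe: a seed is the maximal
    set of above probes within ``window_bp`` of its leftmost member.  Seeds
    sharing probes merge.  Equivalent to exhaustive 1-bp sliding.
    """
    idx = np.nonzero(above)[0]
    if idx.size < min_probes:
        return []
    apos = pos[idx]
    seeds: list[tuple[int, int]] = []
    j = 0
    for i in range(idx.size):
        if j < i:
            j = i
        while j + 1 < idx.size and apos[j + 1] - apos[i] < window_bp:
            j += 1
        if j - i + 1 >= min_probes:
            a, b = int(idx[i]), int(idx[j])
            if seeds and a <= seeds[-1][1]:
                seeds[-1] = (seeds[-1][0], max(seeds[-1][1], b))
            else:
                seeds.append((a, b))
    # keep only above-cutoff members; endpoints are above by construction
    return seeds


def detect_peaks(
    probes: pd.DataFrame,
    promoters: Sequence[PromoterRegion],
    window_bp: int = 500,
    min_probes: int = 4,
    cutoff_percents: Sequence[int] = DEFAULT_CUTOFF_PERCENTS,
    cutoff_mode: str = "range",
) -> list[Peak]:
    """Detect peaks in every promoter span over the descending cutoff ladder.

    Within a promoter, a 500-bp window with >= ``min_probes`` probes strictly
    above the level's cutoff seeds a peak over those probes; overlapping
    seeds at one level merge; a peak accepted at a higher level suppresses
    any overlapping peak at lower levels.  Score = 4th-highest member ratio
    (``min_probes``-th-highest when ``min_probes`` < 4).  The result is
    sorted by score, descending.
    """
    _validate_probes(probes)
    cutoffs = promoter_space_cutoffs(probes, promoters, cutoff_percents, cutoff_mode)
    order = sorted(cutoff_percents, reverse=True)

    peaks: list[Peak] = []
    by_chrom = {c: g for c, g in probes.groupby("chrom", sort=False)}
    for prom in promoters:
        sub = by_chrom.get(prom.chrom)
        if sub is None:
            continue
        lo, hi = prom.span
        inside = sub[(sub["position"] >= lo) & (sub["position"] <= hi)]
        if len(inside) == 0:
            continue
        pos = inside["position"].to_numpy()
        val = inside["log2ratio"].to_numpy()

        accepted: list[tuple[int, int, float, int]] = []  # (startbp, endbp, score, level)
        for level in order:
            cut = cutoffs[level]
            above = val > cut
            for i, j in _seed_windows(pos, above, window_bp, min_probes):
                members = np.nonzero(above[i : j + 1])[0] + i
                startbp, endbp = int(pos[members[0]]), int(pos[members[-1]])
                if any(startbp <= e and endbp >= s for s, e, _, _ in accepted):
                    continue  # suppressed by a higher-cutoff peak
                mvals = np.sort(val[members])[::-1]
                k = min(min_probes, 4)
                score = float(mvals[k - 1]) if mvals.size >= k else float(mvals[-1])
                accepted.append((startbp, endbp, score, level))

        for startbp, endbp, score, level in accepted:
            n = int(((pos >= startbp) & (pos <= endbp) & (val > cutoffs[level])).sum())
            mid = (startbp + endbp) // 2
            peaks.append(
                Peak(
                    gene_id=prom.gene_id,
                    chrom=prom.chrom,
                    start=startbp,
                    end=endbp,
                    n_probes=n,
                    score=score,
                    cutoff_level=level,
                    distance_to_tss=abs(mid - prom.tss),
                )
            )
    peaks.sort(key=lambda p: (-p.score, p.gene_id, p.start))
    return peaks


def nearest_tss_filter(peaks: Sequence[Peak]) -> list[Peak]:
    """Keep at most one peak per gene: the one nearest its TSS.

    Distance ties break to the higher score, then the smaller start.
    """
    best: dict[str, Peak] = {}
    for p in peaks:
        cur = best.get(p.gene_id)
        if cur is None or (p.distance_to_tss, -p.score, p.start) < (
            cur.distance_to_tss, -cur.score, cur.start
        ):
            best[p.gene_id] = p
    out = list(best.values())
    out.sort(key=lambda p: (-p.score, p.gene_id, p.start))
    return out


def permutation_fdr(
    probes: pd.DataFrame,
    promoters: Sequence[PromoterRegion],
    n_perm: int = 20,
    seed: int | None = None,
    window_bp: int = 500,
    min_probes: int = 4,
    cutoff_percents: Sequence[int] = DEFAULT_CUTOFF_PERCENTS,
    cutoff_mode: str = "range",
    fdr_threshold: float = 0.2,
) -> tuple[list[Peak], list[Peak]]:
    """Annotate nearest-TSS peaks with a permutation FDR.

    Each permutation shuffles the log2 ratios across all probe positions
    (positions fixed, values permuted) and reruns the full peak pipeline.
    For an observed score s, fdr(s) = (mean permuted count of peaks with
    score >= s) / (observed count with score >= s).

    Returns ``(annotated, retained)`` where ``retained`` are the peaks with
    fdr < ``fdr_threshold``.
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation FDR")
    observed = nearest_tss_filter(
        detect_peaks(probes, promoters, window_bp, min_probes, cutoff_percents,
                     cutoff_mode)
    )
    if not observed:
        return [], []

    rng = np.random.default_rng(seed)
    obs_scores = np.array([p.score for p in observed])
    perm_counts = np.zeros(len(observed))
    for _ in range(n_perm):
        shuffled = probes.copy()
        shuffled["log2ratio"] = rng.permutation(shuffled["log2ratio"].to_numpy())
        perm_peaks = nearest_tss_filter(
            detect_peaks(shuffled, promoters, window_bp, min_probes,
                         cutoff_percents, cutoff_mode)
        )
        if perm_peaks:
            pscores = np.array([p.score for p in perm_peaks])
            perm_counts += (pscores[:, None] >= obs_scores[None, :]).sum(axis=0)

    mean_perm = perm_counts / n_perm
    obs_counts = (obs_scores[:, None] >= obs_scores[None, :]).sum(axis=0)
    annotated = [
        dataclasses.replace(p, fdr=float(mean_perm[i] / obs_counts[i]))
        for i, p in enumerate(observed)
    ]
    retained = [p for p in annotated if p.fdr < fdr_threshold]
    return annotated, retained


def write_peaks_tsv(peaks: Iterable[Peak], path, header=None) -> None:
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write(
            "gene_id\tchrom\tstart\tend\tn_probes\tscore\tcutoff_level\t"
            "distance_to_tss\tfdr\n"
        )
        for p in peaks:
            fdr = "NA" if p.fdr is None else f"{p.fdr:.4g}"
            fh.write(
                f"{p.gene_id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.n_probes}\t"
                f"{p.score:.4g}\t{p.cutoff_level}\t{p.distance_to_tss}\t{fdr}\n"
            )


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    """BED with name=gene_id and the peak score in column 5."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.gene_id}\t{p.score:.4g}\n"
            )
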