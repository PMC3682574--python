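# Methods

This note documents the models and procedures `prmscan` implements, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Coordinates and sequence model

All residue coordinates are 1-based and inclusive at both ends (the
convention of domain annotations like "amino acids 273–351"); conversion to
0-based half-open slices happens only at internal array boundaries.
Sequences are uppercase over the 20 canonical residues plus `X`. `X` is
scored with a scale's median value and, in motif matching, satisfies only
explicit wildcard positions — an unknown residue is never allowed to
impersonate a literal or a hydrophobic-class residue.

## Window profiling

Each window of `w` residues (default 15, step 1) is scored three ways on
the same residues:

* **hydropathy** — unweighted arithmetic mean of Kyte-Doolittle values
  (Ile 4.5 … Arg −4.5). No triangular weighting: the unweighted mean is the
  standard sliding-window convention for this scale.
* **PPII propensity** — unweighted mean of a per-residue polyproline-II
  helix propensity scale.
* **PGQ index** — the fraction of the window that is Pro, Gly or Gln.
  Defined as a fraction (not a count) so it lies in [0, 1] and is
  comparable across window sizes.

A length-L sequence yields `floor((L − w)/step) + 1` windows.

**The PPII scale is pluggable and its default is synthetic.** Measured
host-guest PPII propensity sets exist but no specific set ships with the
package; the default (`data/ppii_default.scale`) is a constructed stand-in
that preserves the experimentally observed ranking — Pro by far the
highest; Gln, Ala and charged residues intermediate; aromatic and
β-branched residues lowest. Every downstream decision consumes PPII scores
only through per-protein percentiles, so results depend on the ranking, not
the numeric values; a measured scale can be substituted as a 2-column text
file (`prmscan profile --ppii-scale my.scale`).

## PRM patterns and matching

A pattern is an ordered list of position classes: literal residue,
hydrophobic class Φ, or wildcard X. The four built-in consensus patterns
(PRM1 `PPΦPΦΦΦQΦΦP`, PRM2 `QΦΦPΦPQPΦΦΦGP`, PRM3 `ΦΦPPPΦPΦΦΦ`, PRM4
`GΦXXΦΦPΦΦPΦP`) describe, respectively, the N-terminal boundary, two
central elements, and the C-terminal boundary of a TRD3-like domain.

Φ defaults to the residues with positive Kyte-Doolittle hydropathy,
`{A,C,F,I,L,M,V}`; a documented switch adds W and Y. The hydrophobic class
is not fixed by any published enumeration, so it is config-exposed; the
positive-hydropathy definition keeps it consistent with the profiling
scale.

Matching tolerates up to `max_mismatch` failing positions (default 0;
the patterns are consensus sequences over family members, so small
tolerances are legitimate for divergent orthologs). Overlapping matches of
the *same* pattern collapse to the best-scoring one (fewest mismatches,
ties to the leftmost); distinct patterns may overlap freely, since the
motifs are described as distinct adjacent islands. Matches are always
reported in protein coordinates, even when scanning a sub-region.

## Domain calling

The defining description of these domains — high polyproline content with
either high hydrophobic character or high P/G/Q content — is implemented
as: a window is a candidate iff

```
ppii ≥ P(ppii_pct)  AND  (hydropathy ≥ P(hydro_pct)  OR  pgq ≥ P(pgq_pct))
```

with `P(·)` the per-protein percentile (all three default 75). Percentile
thresholds were chosen over absolute values because no numeric cutoffs are
published and percentiles make the rule scale-free — in particular robust
to the pluggable PPII scale. Candidate windows separated by fewer than
`merge_gap` residues (default 15 = one window) fuse into regions; a region
must span ≥ `min_length` residues (default 20) and contain ≥
`min_prm_support` PRM matches (default 1) to become a call. The PRM-support
requirement is what keeps percentile thresholds honest: a protein with no
proline-rich content still has top-quartile windows, but they carry no
motifs and are discarded.

Call spans run from the first candidate window's start to the last one's
end. A window that only partially covers a domain edge can legitimately
exceed the thresholds, so calls carry an intrinsic smear of up to about
half a window on each side; the recovery benchmark therefore scores
boundaries as correct within one window size (15 residues).

**Boundary screening.** KLF10/KLF11-style proteins carry R1/R2 repression
domains upstream of the proline-rich domain. `screen_boundary` aligns
user-supplied reference domains (free end gaps, BLOSUM62) to the call; when
a reference aligns with identity ≥ 0.4 over ≥ 80 % of its own length and
the aligned block starts within 15 residues of the call's N terminus, the
call start advances past the block. The identity/coverage criteria are
interpretations (none are published) and are config-exposed. References are
always user-supplied FASTA; none are hard-coded.

## Conservation analysis

Pairwise alignment is exact dynamic programming in semi-global mode:
global alignment with free end gaps, BLOSUM62, affine gap costs (open 10,
extend 1 — a common BLOSUM62 pairing; a gap of length k costs
`open + (k−1)·extend`). An exact DP dominates a progressive multiple-
alignment heuristic for pairwise use, and the stated settings (matrix, free
gap ends, outgroup) fully determine the computation. Identity is the
fraction of identical columns among non-end-gap columns; internal gap
columns count in the denominator.

Distances are `d = 1 − identity` — simple, monotone in identity, and
sufficient for qualitative ortholog grouping; a Poisson-corrected variant
(`−ln identity`) is available behind a flag. Trees are built by canonical
neighbor joining; negative branch lengths (possible on non-additive input)
are clamped to zero with a log note, and the root is placed at the midpoint
of the outgroup's pendant edge. On additive distance matrices NJ provably
recovers the generating topology, which the tests use as the primary
correctness check (100/100 random 5-taxon additive matrices at
Robinson-Foulds distance 0).

## Tiling-array peak calling

Within each promoter's strand-aware 5-kb upstream span:

1. **Cutoff ladder.** Levels run 90 % down to 15 % in 5 % steps. The
   default anchoring interpolates the cutoff *value* between the median and
   the maximum of the promoter-space log2-ratio distribution:
   `cutoff(p) = q50 + (p/100)(qmax − q50)`. The alternative reading — the
   p-th percentile of the distribution — is implemented as
   `cutoff_mode="percentile"`; which of the two the original instrument
   convention intended is not documented, so both are config options.
   "Above cutoff" is strict (`>`), so degenerate constant-ratio input
   yields zero peaks rather than wall-to-wall peaks.
2. **Seeding.** At each level (descending), any 500-bp window holding
   ≥ 4 probes above the cutoff seeds a peak over those probes. Windows are
   anchored at probe positions, which is equivalent to exhaustive 1-bp
   sliding (verified against a brute-force enumerator). Overlapping seeds
   at one level merge; a peak accepted at a higher level suppresses
   overlapping rediscovery at lower levels.
3. **Scoring.** A peak's score is the log2 ratio of its 4th-highest member
   probe — an order statistic that is robust to a single outlier probe.
   The minimum probe count is ≥ 4 (the smallest value for which the score
   is well defined; the "more than 4" phrasing and the 4th-highest-probe
   score would otherwise conflict).
4. **Reporting.** One peak per gene: the one nearest the TSS (distance =
   |peak midpoint − TSS|), ties broken by higher score then smaller start.
5. **FDR.** Ratios are shuffled across all probe positions (positions
   fixed, values permuted — preserves the signal distribution, destroys
   spatial clustering), default 20 permutations, mandatory seed. For an
   observed score s, `fdr(s) = mean permuted count of peaks ≥ s / observed
   count ≥ s`; peaks with FDR < 0.2 are retained as high confidence.

## Synthetic benchmarks

`simulate_proteins` emulates the observed domain architecture: a
charged/polar background (`{D,E,K,R,N,S,T,H}`, uniform — chosen for
maximal contrast with Φ so planted islands are unambiguous) carrying one
island per protein built from the four PRM instances in order, joined by
2–6-residue hydrophobic linkers (islands of 46–64 residues). Default
protein length is 150–250 residues, in the range of KLF N-terminal regions
and chosen so that island windows occupy more than the top quartile of the
profile — which pins the percentile thresholds inside the island's score
range and keeps the P/G/Q-free background below them. Ground truth
(island and per-motif coordinates) is emitted beside the sequences, and
generation is a pure function of (config, seed).

`simulate_tiling` emulates promoter tiling data: probes every 100 bp
across 200 five-kb spans (strands alternating), log2 ratios N(0, 0.5),
with 10 promoters carrying 5 consecutive probes shifted +2.0. A
heavier-tailed noise option (t, 5 df) exists for robustness checks.

What passing these benchmarks shows — and does not. The generators place
clean, single islands in maximally contrasting backgrounds and spatially
uncorrelated Gaussian array noise; real proteins have compositionally
intermediate regions, multiple partial domains and biased backgrounds, and
real arrays have probe-response and spatial artifacts that value
permutation does not model. Oracle-agreement results (scanner, aligner,
peak caller) are exact statements about the algorithms; recovery and
recall figures are statements about these simulated conditions only.

## Problem sizes and numerical choices

* Planted-domain benchmark: 200 proteins (plus 200 island-free controls).
* Scanner oracle: 1,000 random sequences, lengths 20–200, mismatches 0–1.
* Alignment oracle: exhaustive enumeration of all alignments for sampled
  reduced-alphabet pairs of lengths ≤ 8 (exhausting all *pairs* of that
  length is combinatorially pointless; the enumeration per pair is what
  makes the oracle exact).
* Tree recovery: 100 random 5-taxon additive matrices.
* Peak-caller oracle: 100 random instances of ≤ 100 probes, every 1-bp
  window enumerated.
* Spike-in calibration: 50 replicates (tests) / 20 replicates (acceptance
  script) of the default tiling simulation, 20 permutations each.
* Ties in alignment traceback follow the aligner's deterministic
  enumeration order; NJ negative branches clamp to 0; FDR division is
  guarded (no observed peaks → empty result).
* Output-file manifest headers are deterministic (tool version, resolved
  config, input digests, seeds — no timestamps), so identical commands
  produce byte-identical outputs.

## Known limitations

* The default PPII scale is rank-faithful but synthetic; absolute PPII
  values carry no meaning.
* The fixed demonstration protein (`synthetic_trd3_protein`) is a
  constructed stand-in, not the curated human KLF11 sequence; analyses of
  real KLF proteins should load their own FASTA.
* The aligner is strictly pairwise; no true multiple alignment, bootstrap
  support, or likelihood-based phylogenetics.
* The peak caller assumes normalized log2 ratios; array normalization and
  dye-bias correction are out of scope.
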