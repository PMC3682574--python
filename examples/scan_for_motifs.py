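"""Scan a protein for the four degenerate PRM consensus patterns.

Uses the synthetic KLF11-like demonstration protein (a constructed
stand-in, not the curated human sequence) and scans its TRD3-like region
(residues 281-373).  The four motifs appear in order, PRM1 marking the
N-terminal boundary and PRM4 the C-terminal boundary of the domain.
"""

from prmscan import SequenceRegion, scan
from prmscan.synthetic_fixtures import synthetic_trd3_protein

rec, truth = synthetic_trd3_protein()
matches = scan(rec, region=SequenceRegion(rec.id, 281, 373))

print(f"protein {rec.id} ({len(rec)} aa), scanning region 281-373:")
for m in matches:
    print(f"  {m.pattern_name}  residues {m.start:3d}-{m.end:3d}  "
          f"mismatches={m.n_mismatches}")
print()
print(f"{len(matches)} PRM sites; the first is {matches[0].pattern_name} and "
      f"the last is {matches[-1].pattern_name} — the two boundary motifs "
      "delimit the proline-rich interaction domain.")
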