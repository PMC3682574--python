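"""Profile a protein with the three sliding-window scores.

Builds a small protein with a proline-rich centre inside hydrophobic
flanks, profiles it with 15-residue windows, and prints the windows with
the highest PPII propensity.  High-PPII windows that also score high on
hydropathy or PGQ content are the raw signal the domain caller works from.
"""

from prmscan import ProteinRecord, profile

seq = (
    "DEKRDEKRDEKRDEKRDEKR"          # charged N-terminal flank
    + "LLALLVAMLLAV"                # hydrophobic environment
    + "PPLPLLLQLLPAAPPPLPLAA"      # proline-rich core
    + "LLALLVAMLLAV"
    + "DEKRDEKRDEKRDEKRDEKR"
)
rec = ProteinRecord(id="demo", sequence=seq)
prof = profile(rec)  # 15-residue windows, step 1

df = prof.to_frame()
print(df.sort_values("ppii", ascending=False).head(5).to_string(index=False))
print()
top = df.loc[df["ppii"].idxmax()]
print(
    f"window starting at residue {int(top.window_start)} has the highest "
    f"PPII propensity ({top.ppii:.3f}) with PGQ fraction {top.pgq:.2f} — "
    "this is where a polyproline island sits."
)
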