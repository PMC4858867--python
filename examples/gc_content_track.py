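"""GC-content strip from the sequence embedded in a GFF ##FASTA section.

Shows the N-exclusion rule: Ns drop out of the denominator, so a window
of ACGTNNNN still reports 50 % GC.
"""

from chromotile import SequenceRecord, gc_track, get_scale, map_density, tile

rec = SequenceRecord("demo", 24, "GCGCGCGG" + "ATATATTA" + "ACGTNNNN")
windows = tile("demo", rec.length, 8)
track = gc_track(rec, windows, rounding="floor")

scale = get_scale(12)  # GC archetype: <30 grey, 30-49 green->red, >=50 dark red
for w, v in zip(track.windows, track.values):
    print(f"window {w.start:>2}-{w.end:<2}  GC={v:>3}%  colour={map_density(v, scale)}")
print("the last window is 50% because the four Ns are excluded from the denominator")
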