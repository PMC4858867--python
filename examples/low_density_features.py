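"""Why rounding matters for sparse features.

A rolling-circle transposon covering 0.5 % of a 40 kb window disappears
under the default floor rounding (density 0, first colour bin) but stays
visible under ceil with the low-density scale 10 (density 1, blue).
"""

from chromotile import density, get_scale, map_density, merge, tile

mi = merge([(12_001, 12_200)], track="fused", seqid="chr4")  # 200 bp covered
windows = tile("chr4", 40_000, 40_000)
scale = get_scale(10)

for rounding in ("floor", "ceil"):
    (v,) = density(mi, windows, "RC", rounding).values
    print(f"rounding={rounding:<5} density={v}  colour={map_density(v, scale)}")
print("floor hides sub-percent coverage (grey 0-bin); ceil promotes it to the 1% bin")
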