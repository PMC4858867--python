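"""Build a gene/exon density map for a small synthetic genome.

Generates a two-chromosome annotation, computes strand-separated and
fused gene densities in 5 kb windows, and writes the SVG + CSV pair.
"""

from pathlib import Path

from chromotile import (
    RenderOptions,
    compute_layout,
    density,
    get_scale,
    merge,
    parse_gff,
    render_svg,
    select_track,
    tile,
    write_density_csv,
    write_fixture,
)

out = Path("scratch_example")
out.mkdir(exist_ok=True)
gff = write_fixture(
    out / "toy.gff3", seed=42, n_seqs=2, seq_length=60_000,
    n_features=400, types=("gene", "exon"), gc_bias=0.45,
)

features, records = parse_gff(gff, {"gene", "exon"})
print(f"parsed {len(features)} features on {len(records)} chromosomes")

tracks, scales = [], []
for rec in records:
    windows = tile(rec.seqid, rec.length, 5_000)
    for ftype in ("gene", "exon"):
        fs = [f for f in features if f.seqid == rec.seqid and f.ftype == ftype]
        # "all" builds three strips: minus, plus and their fused union
        for label, sub in select_track(fs, "all"):
            mi = merge(sub, track=label, seqid=rec.seqid)
            tracks.append(density(mi, windows, ftype, rounding="floor"))
            scales.append(get_scale(1))

opts = RenderOptions(title="Toy gene/exon density", show_scale=10)
layout = compute_layout(tracks, opts, scales)
(out / "toy.svg").write_bytes(render_svg(layout, tracks, scales, opts))
write_density_csv(tracks, out / "toy.csv", window_size=5_000)

t = tracks[2]  # chr1 gene fused
print(f"{t.seqid} {t.ftype} ({t.track}) densities: {t.values}")
print("each value is the percent of that 5 kb window covered by >=1 gene;")
print(f"image: {layout.image_width:.0f} x {layout.image_height:.0f} px ->", out / "toy.svg")
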