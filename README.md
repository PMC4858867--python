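# chromotile

Chromosome-scale density maps of genomic features, computed directly from
GFF annotation.

Genome browsers excel at small regions but give no whole-genome overview,
and ideogram tools struggle with very dense annotation such as
interspersed repeats. `chromotile` fills that gap: it tiles each
chromosome into non-overlapping windows, computes for every window the
percentage of bases covered by each requested feature type (after merging
overlapping intervals, optionally per strand), and renders the result as
a compact multi-track SVG "heat strip" figure plus a tab-separated
density table. It is aimed at anyone who wants a one-figure answer to
"where along my chromosomes are the genes / repeats / ncRNAs, and how
dense are they?" — annotation curators, repeat biologists, comparative
genomicists.

## The statistic

For a window *w* of span |*w*| bp and a feature type *t* with merged
interval set *M<sub>t</sub>* (the union of all intervals of that type on
the chosen strand track, so overlapping annotations count once):

> density(*w*, *t*) = round( 100 · |*M<sub>t</sub>* ∩ *w*| / |*w*| )

with `round` either `floor` (default) or `ceil`. Ceil matters for sparse
features: a window covered at 0.5 % reports 0 under floor but 1 under
ceil, keeping rare elements visible. Strand handling is one of `minus`,
`plus`, `both` (two strips), `fused` (union of both strands plus
unstranded features, one strip) or `all` (minus, plus and fused — three
strips). A GC% strip can be computed from sequence embedded in the GFF's
`##FASTA` section; Ns are excluded from the denominator. Densities map to
colours through numbered, user-editable colour scales (see
`src/chromotile/data/colour_scales.tsv`), including a low-density scale
(id 10: 0 % grey, 1–9 % blue→red, ≥10 % dark red) and a GC scale (id 12:
<30 % grey, 30–49 % green→red, ≥50 % dark red).

## Worked example

```sh
python examples/gene_density_map.py
```

prints (output of the script as shipped):

```
parsed 400 features on 2 chromosomes
chr1 gene (fused) densities: [73, 99, 95, 63, 78, 82, 100, 100, 44, 72, 73, 95]
each value is the percent of that 5 kb window covered by >=1 gene;
image: 650 x 364 px -> scratch_example/toy.svg
```

Each number is the percentage of one 5 kb window of chr1 covered by at
least one gene (plus- and minus-strand genes fused); the SVG shows the
same values as one coloured cell per window, and `toy.csv` holds every
(seqid, window, type, strand, density) row. The other examples
demonstrate the GC strip with N-exclusion (`gc_content_track.py`) and
why ceil rounding keeps sub-percent features visible
(`low_density_features.py`).

The same pipeline runs from the shell:

```sh
chromotile -i genome.gff3 -o egn \
  -ty 'gene = fused;exon = fused;ncRNA = fused = 10' \
  -gc 12 -sc 40000 -ba white -str_s 15 -str_w 25 -sp 35 -sh 50 \
  -title "Density Map of Gene, Exon, ncRNA and GC%" -la=-15 -ro ceil
```

writing `egn.svg` and `egn.csv`. `-sc` fixes the window length in bp;
`-a <px>` instead derives it so the longest chromosome fits a maximum
picture height. `-re regions.bed` restricts the plot to BED regions.
`--help` lists the full option surface.

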