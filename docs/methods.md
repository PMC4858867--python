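# Methods

## Model

A chromosome of length *L* is partitioned into ⌈*L*/*W*⌉ adjacent,
non-overlapping windows of *W* bp (1-based inclusive coordinates; only
the final window may be shorter). For each requested feature type the
intervals of the selected strand track are collected, sorted by start and
merged into a union — overlapping and touching intervals collapse, so a
base annotated several times counts once and densities cannot exceed
100 %. The density of a window is `100 * covered / span`, rounded with
`floor` (default) or `ceil` to an integer percent. The denominator is the
*actual* span, so a truncated final window still reports a value in
[0, 100]. Rounding is done in integer arithmetic (`(100*c)//s` and its
negation for ceil), so bin boundaries are exact — there is no float
round-off at the 0/1 boundary that the two rounding modes are designed to
distinguish.

Strand tracks: `minus` and `plus` take only features with that strand;
`fused` takes the union of both strands *plus* unstranded features
(strand `.`, `?` or anything else in GFF column 7); `both` = minus and
plus as two tracks; `all` = minus, plus and fused as three. Fused is a
union, not a sum: a base covered on both strands counts once. Unstranded
features contribute only to fused tracks; when the mode has no fused
track they are dropped with a warning.

GC%: `100 * (G+C) / (A+C+G+T)` per window, case-insensitive, with N (and
any other symbol) excluded from the denominator; an all-N window reports
0 rather than NaN so it stays drawable. The sequence comes from the
GFF's `##FASTA` section; requesting GC without one is an error.

## Coordinate conventions

GFF features are 1-based inclusive (GFF standard); BED regions are
0-based half-open (BED standard) and converted to 1-based inclusive on
ingest. All three GFF dialects (2, 2.5, 3) are handled by one tolerant
reader because they differ only in the column-9 attribute syntax, which
this tool never reads. Sequence length precedence:
`##sequence-region` pragma, then embedded FASTA length, then the maximum
feature end; a pragma/FASTA contradiction is an error, and features
running past the declared end are clipped with a warning.

## Window sizing

The window length is either fixed (`-sc`, bp) or derived from a maximum
picture height (`-a`, px): `W = ceil(max_length / (max_px - chrome))`,
where *chrome* is the fixed vertical overhead (margins, title, sequence
labels, track labels) implied by the graphical options. This guarantees
the longest chromosome needs at most `max_px - chrome` one-pixel rows.
The result is used exactly (no rounding to "nice" values) and echoed in
the CSV as a `# window_size=` comment. If both options are given the
fixed size wins with a warning; if neither is given, auto sizing with a
1000 px budget is used. When `-w` (picture height) is also set it does
not change *W*; it only rescales the drawn cell height so the image is
exactly that tall.

## Numerical and algorithmic choices

* Merge: numpy argsort plus a running maximum of interval ends; group
  boundaries fall where the next start exceeds the running end + 1, so
  touching intervals are merged into canonical form (coverage is
  identical either way).
* Per-window coverage: a prefix-sum/`searchsorted` evaluation of
  C(x) = covered bases in [1, x]; window coverage is C(end) − C(start−1).
  This is exact integer arithmetic and O((n + w) log n), which keeps
  million-feature genomes tractable on one core. The test suite
  cross-checks it against a per-base boolean-array oracle on 200
  randomized fixtures — the oracle is obviously correct but only viable
  on small sequences.
* Colour bins are integer-inclusive ranges validated at load time to
  cover 0–100 with no gaps or overlaps, so every rounded density maps to
  exactly one colour.
* SVG geometry is a pure function of the tracks and options; coordinates
  are formatted with a fixed 3-decimal, locale-free formatter, making
  repeated renders byte-identical. Chromosomes are vertical columns
  left-to-right (position 1 at the top, ruler in Mbp on the left); each
  (feature type, strand track) pair is one strip of one cell per window.

## Synthetic data

The generator emulates the *shape* of an annotation file — seeded,
uniformly placed features of given types (lengths uniform in 50–2000 bp,
strands +/− with a 5 % unstranded fraction), `##sequence-region`
pragmas, and an embedded FASTA of i.i.d. bases with a chosen GC
fraction. It deliberately does not emulate feature hierarchies,
clustered placement (telomere/centromere structure) or realistic length
distributions. Passing tests therefore demonstrate that the windowing,
merging, rounding, strand and rendering semantics are correct on any
interval data; they say nothing about the biological plausibility of a
particular genome's density landscape, which the tool only displays.

Test problem sizes: the oracle sweep uses 200 fixtures of up to 100 kb
and 1000 features with window sizes {100, 1000, 7919} (the prime
exercises truncated final windows); the smoke test runs one million
features on five 10 Mb sequences through the whole pipeline.

## Design choices where the behaviour was open

* One multi-sequence GFF and multiple single-sequence files are both
  accepted; records from later files merge by seqid.
* The interactive picture-size confirmation prompts only when stdin is a
  TTY; non-interactive runs log the computed dimensions and proceed
  (`-for/--force` suppresses the prompt entirely).
* The catalog numbering of the gradient scales (ids 1–9, 11) is
  implementation-defined; only the low-density (10) and GC (12)
  archetypes have externally fixed semantics. The default global scale
  is id 1 (deciles blue→red). All RGB values live in a shipped TSV so
  users can override any scale without code changes.
* One window is one drawn cell; when the picture height forces cells
  below one pixel the cells are scaled geometrically rather than the
  densities being recomputed at pixel resolution.
* A per-scale legend block is drawn at the right edge and can be
  disabled with `--no_legend`.

## Limitations

* No feature hierarchies (gene→mRNA→exon resolution), no GTF, no
  column-9 attribute parsing.
* No sliding/overlapping windows, no per-base wiggle output, and no
  count-based densities — coverage only.
* SVG output only; rasterize externally if needed.
* Interval merging means two adjacent distinct features are
  indistinguishable from one long feature at the density level.
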