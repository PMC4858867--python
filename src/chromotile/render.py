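"""Deterministic image geometry and SVG output.

Chromosomes are drawn as vertical columns left-to-right; within a
chromosome, one heat strip (column of coloured window cells) per
(feature type, strand track) pair, top = position 1. A vertical ruler in
Mbp sits at the left when requested; the sequence name is printed above
each chromosome group and a rotated (ftype, strand) label below each
strip. Geometry is a pure function of the tracks and options: rendering
the same inputs twice yields byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from lxml import etree

from .colorscale import ColourScale, map_density
from .errors import ChromotileError, ConfigError
from .intervals import DensityTrack

SVG_NS = "http://www.w3.org/2000/svg"

#: width reserved for the ruler (ticks + Mbp labels) when shown
RULER_WIDTH = 50
#: width reserved for the legend column when shown
LEGEND_WIDTH = 150
_LEGEND_SWATCH = 10
_LEGEND_GAP = 26


@dataclass(frozen=True)
class RenderOptions:
    """Graphical options; defaults give a compact, readable figure."""

    title: str = ""
    win_size: int | None = None  # fixed picture height in px
    show_scale: int | None = None  # max ruler ticks, None = no ruler
    strand_width: int = 20
    strand_space: int = 5
    space_chr: int = 30
    lmargin: int = 50
    rmargin: int = 50
    tmargin: int = 50
    bmargin: int = 50
    background: str = "white"
    label_strand_rotation: int = 0
    ft_family: str = "sans-serif"
    ft_size: int = 12
    legend: bool = True

    @property
    def title_height(self) -> int:
        return self.ft_size + 10 if self.title else 0

    @property
    def header_height(self) -> int:
        return self.ft_size + 6  # seqid labels above the strips

    @property
    def footer_height(self) -> int:
        return 70  # rotated track labels below the strips

    @property
    def vertical_chrome(self) -> int:
        return (
            self.tmargin
            + self.bmargin
            + self.title_height
            + self.header_height
            + self.footer_height
        )


@dataclass(frozen=True)
class LayoutSpec:
    """Computed pixel geometry of the whole image."""

    image_width: float
    image_height: float
    plot_top: float
    cell_height: float
    chrom_origins: tuple[tuple[str, float], ...]  # (seqid, x of group origin)
    track_rects: tuple[tuple[float, float, float, float], ...]  # x, y, w, h per track
    ruler_x: float | None
    ruler_ticks: tuple[tuple[float, str], ...]  # (y px, label)
    title_pos: tuple[float, float] | None
    legend_x: float | None


def ruler_ticks(seq_length: int, max_ticks: int) -> list[tuple[int, str]]:
    """Round tick positions (bp) and Mbp labels, at most ``max_ticks`` of them.

    Spacing is the smallest member of the 1-2-5 decade series that keeps
    the tick count (including the tick at 0) within the budget.
    """
    if max_ticks < 2:
        raise ConfigError(f"need at least 2 ruler ticks, got {max_ticks}")
    spacing = None
    mag = 1
    while spacing is None:
        for mult in (1, 2, 5):
            step = mult * mag
            if seq_length // step + 1 <= max_ticks:
                spacing = step
                break
        mag *= 10
    ticks = []
    pos = 0
    while pos <= seq_length:
        ticks.append((pos, f"{pos / 1e6:g}"))
        pos += spacing
    return ticks


def compute_layout(
    tracks: Sequence[DensityTrack],
    opts: RenderOptions,
    scales: Sequence[ColourScale] = (),
) -> LayoutSpec:
    """Pure geometry: where every strip, tick and label goes.

    Width grows linearly with strips (``strand_width`` each, separated by
    ``strand_space`` within a chromosome and ``space_chr`` between
    chromosomes); height is the window count of the tallest chromosome
    times the cell height, plus fixed margins/labels. With ``win_size``
    set, the cell height is chosen so the image is exactly that tall.
    """
    if not tracks:
        raise ChromotileError("no density tracks to lay out")
    max_windows = max(len(t.windows) for t in tracks)
    if opts.win_size is not None:
        available = opts.win_size - opts.vertical_chrome
        if available <= 0:
            raise ConfigError(
                f"picture height {opts.win_size}px leaves no room for the plot"
            )
        cell_height = available / max_windows
    else:
        cell_height = 1.0

    # group tracks by seqid, preserving first-appearance order
    order: list[str] = []
    for t in tracks:
        if t.seqid not in order:
            order.append(t.seqid)

    ruler_x = None
    x = float(opts.lmargin)
    if opts.show_scale is not None:
        ruler_x = x + RULER_WIDTH - 8
        x += RULER_WIDTH
    plot_top = float(opts.tmargin + opts.title_height + opts.header_height)

    chrom_origins: list[tuple[str, float]] = []
    rects: list[tuple[float, float, float, float]] = [None] * len(tracks)  # type: ignore
    for seqid in order:
        idx = [i for i, t in enumerate(tracks) if t.seqid == seqid]
        chrom_origins.append((seqid, x))
        for j, i in enumerate(idx):
            if j:
                x += opts.strand_space
            h = len(tracks[i].windows) * cell_height
            rects[i] = (x, plot_top, float(opts.strand_width), h)
            x += opts.strand_width
        x += opts.space_chr
    x -= opts.space_chr  # no trailing chromosome gap

    legend_x = None
    legend_h = 0.0
    if opts.legend:
        legend_x = x + opts.space_chr
        x = legend_x + LEGEND_WIDTH
        if scales:
            distinct = {s.id: s for s in scales}
            legend_h = sum(
                opts.ft_size + 6 + len(s.bins) * (_LEGEND_SWATCH + 1) + _LEGEND_GAP
                for s in distinct.values()
            )
    image_width = x + opts.rmargin

    plot_h = max_windows * cell_height
    if opts.win_size is not None:
        image_height = float(opts.win_size)
    else:
        image_height = opts.vertical_chrome + max(plot_h, legend_h)

    ticks: list[tuple[float, str]] = []
    if opts.show_scale is not None:
        # ruler spans the longest chromosome; px per bp from its windows
        tallest = max(tracks, key=lambda t: len(t.windows))
        length = sum(w.span for w in tallest.windows)
        bp_per_px = length / (len(tallest.windows) * cell_height)
        for bp, label in ruler_ticks(length, opts.show_scale):
            ticks.append((plot_top + bp / bp_per_px, label))

    title_pos = None
    if opts.title:
        title_pos = (image_width / 2, float(opts.tmargin + opts.ft_size))

    return LayoutSpec(
        image_width=image_width,
        image_height=image_height,
        plot_top=plot_top,
        cell_height=cell_height,
        chrom_origins=tuple(chrom_origins),
        track_rects=tuple(rects),
        ruler_x=ruler_x,
        ruler_ticks=tuple(ticks),
        title_pos=title_pos,
        legend_x=legend_x,
    )


def _fmt(x: float) -> str:
    """Fixed, locale-free coordinate formatting (3 decimals, trimmed)."""
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s else "0"


def render_svg(
    layout: LayoutSpec,
    tracks: Sequence[DensityTrack],
    scales: Sequence[ColourScale],
    opts: RenderOptions,
) -> bytes:
    """Emit the SVG document (bytes, UTF-8). Deterministic for fixed inputs."""
    if len(scales) != len(tracks):
        raise ChromotileError("one colour scale per track required")
    root = etree.Element(
        "svg",
        nsmap={None: SVG_NS},
        width=_fmt(layout.image_width),
        height=_fmt(layout.image_height),
        viewBox=f"0 0 {_fmt(layout.image_width)} {_fmt(layout.image_height)}",
    )
    root.set("version", "1.1")
    font = {"font-family": opts.ft_family, "font-size": str(opts.ft_size)}

    etree.SubElement(
        root,
        "rect",
        x="0",
        y="0",
        width=_fmt(layout.image_width),
        height=_fmt(layout.image_height),
        fill=opts.background,
    )

    if layout.title_pos is not None:
        t = etree.SubElement(
            root,
            "text",
            x=_fmt(layout.title_pos[0]),
            y=_fmt(layout.title_pos[1]),
            fill="black",
            **{"text-anchor": "middle", "font-weight": "bold"},
            **font,
        )
        t.text = opts.title

    if layout.ruler_x is not None and layout.ruler_ticks:
        rx = layout.ruler_x
        y0 = layout.ruler_ticks[0][0]
        y1 = layout.ruler_ticks[-1][0]
        etree.SubElement(
            root, "line",
            x1=_fmt(rx), y1=_fmt(y0), x2=_fmt(rx), y2=_fmt(y1),
            stroke="black", **{"stroke-width": "1"},
        )
        for y, label in layout.ruler_ticks:
            etree.SubElement(
                root, "line",
                x1=_fmt(rx - 4), y1=_fmt(y), x2=_fmt(rx), y2=_fmt(y),
                stroke="black", **{"stroke-width": "1"},
            )
            txt = etree.SubElement(
                root, "text",
                x=_fmt(rx - 6), y=_fmt(y + opts.ft_size / 3),
                fill="black", **{"text-anchor": "end"}, **font,
            )
            txt.text = label
        unit = etree.SubElement(
            root, "text",
            x=_fmt(rx - 6), y=_fmt(y0 - opts.ft_size / 2),
            fill="black", **{"text-anchor": "end"}, **font,
        )
        unit.text = "Mbp"

    # seqid labels above each chromosome group
    seen = set()
    for seqid, gx in layout.chrom_origins:
        if seqid in seen:
            continue
        seen.add(seqid)
        idx = [i for i, t in enumerate(tracks) if t.seqid == seqid]
        x_left = min(layout.track_rects[i][0] for i in idx)
        x_right = max(layout.track_rects[i][0] + layout.track_rects[i][2] for i in idx)
        txt = etree.SubElement(
            root, "text",
            x=_fmt((x_left + x_right) / 2),
            y=_fmt(layout.plot_top - 6),
            fill="black", **{"text-anchor": "middle"}, **font,
        )
        txt.text = seqid

    # density cells + track labels
    for track, scale, rect in zip(tracks, scales, layout.track_rects):
        x, y, w, _h = rect
        etree.SubElement(
            root, "rect",
            x=_fmt(x), y=_fmt(y), width=_fmt(w), height=_fmt(_h),
            fill="none", stroke="#404040", **{"stroke-width": "0.5"},
        )
        for j, value in enumerate(track.values):
            etree.SubElement(
                root, "rect",
                x=_fmt(x),
                y=_fmt(y + j * layout.cell_height),
                width=_fmt(w),
                height=_fmt(layout.cell_height),
                fill=map_density(value, scale),
                **{"class": "cell"},
            )
        ly = y + _h + opts.ft_size + 4
        lx = x + w / 2
        label = etree.SubElement(
            root, "text",
            x=_fmt(lx), y=_fmt(ly),
            fill="black", **{"text-anchor": "middle"}, **font,
        )
        if opts.label_strand_rotation:
            label.set("transform", f"rotate({opts.label_strand_rotation} {_fmt(lx)} {_fmt(ly)})")
        label.text = f"{track.ftype} ({track.track})"

    if layout.legend_x is not None:
        _render_legend(root, layout, scales, opts, font)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _render_legend(root, layout: LayoutSpec, scales, opts, font) -> None:
    """One compact block per distinct scale: swatch column + range labels."""
    distinct: list[ColourScale] = []
    for s in scales:
        if all(s.id != d.id for d in distinct):
            distinct.append(s)
    y = layout.plot_top
    for scale in sorted(distinct, key=lambda s: s.id):
        head = etree.SubElement(
            root, "text",
            x=_fmt(layout.legend_x), y=_fmt(y + opts.ft_size),
            fill="black", **font,
        )
        head.text = f"scale {scale.id}: {scale.name}"
        y += opts.ft_size + 6
        for low, high, colour in scale.bins:
            etree.SubElement(
                root, "rect",
                x=_fmt(layout.legend_x), y=_fmt(y),
                width=_fmt(_LEGEND_SWATCH * 2), height=_fmt(_LEGEND_SWATCH),
                fill=colour, stroke="#404040", **{"stroke-width": "0.25"},
            )
            lab = etree.SubElement(
                root, "text",
                x=_fmt(layout.legend_x + _LEGEND_SWATCH * 2 + 5),
                y=_fmt(y + _LEGEND_SWATCH - 1),
                fill="black",
                **{"font-family": opts.ft_family, "font-size": str(max(opts.ft_size - 4, 6))},
            )
            lab.text = f"{low}" if low == high else f"{low}–{high} %"
            y += _LEGEND_SWATCH + 1
        y += _LEGEND_GAP
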