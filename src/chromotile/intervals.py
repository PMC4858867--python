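"""Interval union, window tiling and per-window density computation.

The density of a feature type in a window is

    density = 100 * (bases covered by >= 1 feature interval) / window span,

rounded down (``floor``, the default) or up (``ceil``) to an integer
percent. Coverage is computed on the union of the intervals of a strand
track, so overlapping annotations never count twice and densities stay in
[0, 100]. Five strand modes decide which tracks are built: ``minus``,
``plus``, ``both`` (minus and plus separately), ``fused`` (union of both
strands plus unstranded features, one track) and ``all`` (minus, plus and
fused — three tracks).

All coordinates are 1-based inclusive base pairs. The merge and coverage
kernels are vectorized numpy (sort + running maximum for the union;
prefix sums + searchsorted for clipped per-window coverage), which keeps
million-feature inputs tractable on one core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ChromotileError, ConfigError
from .gff_io import Feature, MINUS, PLUS, UNSTRANDED, Region, SequenceRecord

log = logging.getLogger("chromotile")

FUSED = "fused"
STRAND_MODES = ("minus", "plus", "both", "fused", "all")
ROUNDINGS = ("floor", "ceil")


@dataclass(frozen=True, slots=True)
class Window:
    """One tiling window, 1-based inclusive."""

    seqid: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(slots=True)
class MergedIntervals:
    """Sorted, non-overlapping union of feature intervals on one track.

    Touching intervals ([1,5],[6,9]) are merged into one — coverage is
    identical either way; merging gives a canonical form.
    """

    seqid: str
    track: str
    starts: np.ndarray  # int64, sorted ascending
    ends: np.ndarray  # int64, ends[i] >= starts[i], starts[i+1] > ends[i] + 1

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    @property
    def total_coverage(self) -> int:
        if len(self.starts) == 0:
            return 0
        return int((self.ends - self.starts + 1).sum())


@dataclass(slots=True)
class DensityTrack:
    """Integer densities (percent) for one (seqid, ftype, strand track)."""

    seqid: str
    ftype: str
    track: str
    windows: list[Window]
    values: list[int]
    coverage: np.ndarray = field(default=None, repr=False)  # covered bases per window

    def __post_init__(self) -> None:
        if len(self.values) != len(self.windows):
            raise ValueError("values/windows length mismatch")
        if any(v < 0 or v > 100 for v in self.values):
            raise ValueError("density outside [0, 100]")


def select_track(
    features: Sequence[Feature], mode: str
) -> list[tuple[str, list[Feature]]]:
    """Partition features into strand tracks according to the mode.

    Returns (track label, features) pairs; track counts per mode are
    minus=1, plus=1, both=2, fused=1, all=3. Unstranded features go to
    fused tracks only; when the mode has no fused track they are dropped
    with a warning.
    """
    if mode not in STRAND_MODES:
        raise ConfigError(
            f"unknown strand mode {mode!r}; valid modes: {', '.join(STRAND_MODES)}"
        )
    minus = [f for f in features if f.strand == MINUS]
    plus = [f for f in features if f.strand == PLUS]
    unstranded = [f for f in features if f.strand == UNSTRANDED]
    fused = list(features)
    if unstranded and mode in ("minus", "plus", "both"):
        log.warning(
            "%d unstranded feature(s) ignored in mode %r (only fused tracks "
            "include them)",
            len(unstranded),
            mode,
        )
    if mode == "minus":
        return [(MINUS, minus)]
    if mode == "plus":
        return [(PLUS, plus)]
    if mode == "both":
        return [(MINUS, minus), (PLUS, plus)]
    if mode == "fused":
        return [(FUSED, fused)]
    return [(MINUS, minus), (PLUS, plus), (FUSED, fused)]


def merge(
    features: Iterable[Feature | tuple[int, int]],
    track: str = FUSED,
    seqid: str | None = None,
) -> MergedIntervals:
    """Union of intervals: sorted by start, overlaps and touching runs merged."""
    starts_l: list[int] = []
    ends_l: list[int] = []
    for f in features:
        if isinstance(f, Feature):
            if seqid is None:
                seqid = f.seqid
            elif f.seqid != seqid:
                raise ChromotileError(
                    f"merge: mixed sequences {seqid!r} and {f.seqid!r}"
                )
            starts_l.append(f.start)
            ends_l.append(f.end)
        else:
            s, e = f
            starts_l.append(int(s))
            ends_l.append(int(e))
    if not starts_l:
        empty = np.empty(0, dtype=np.int64)
        return MergedIntervals(seqid or "", track, empty, empty.copy())
    s = np.asarray(starts_l, dtype=np.int64)
    e = np.asarray(ends_l, dtype=np.int64)
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    run_max = np.maximum.accumulate(e)
    # new group where the next interval starts past the running end + 1
    is_start = np.empty(len(s), dtype=bool)
    is_start[0] = True
    is_start[1:] = s[1:] > run_max[:-1] + 1
    first = np.flatnonzero(is_start)
    last = np.append(first[1:] - 1, len(s) - 1)
    return MergedIntervals(seqid or "", track, s[first], run_max[last])


def tile(
    seqid: str, seq_length: int, window_size: int, region: Region | None = None
) -> list[Window]:
    """Tile [1, seq_length] (or a BED region) into adjacent windows.

    Windows are ``window_size`` bp; only the final one may be shorter. A
    window size exceeding the tiled span yields a single window with a
    warning.
    """
    if window_size < 1:
        raise ConfigError(f"window size must be >= 1, got {window_size}")
    if seq_length < 1:
        raise ConfigError(f"sequence length must be >= 1, got {seq_length}")
    if region is not None:
        lo, hi = region.start + 1, min(region.end, seq_length)
        if lo > hi:
            raise ConfigError(
                f"region [{region.start}, {region.end}) lies outside "
                f"{seqid} (length {seq_length})"
            )
    else:
        lo, hi = 1, seq_length
    if window_size > hi - lo + 1:
        log.warning(
            "window size %d exceeds span %d on %s; using a single window",
            window_size,
            hi - lo + 1,
            seqid,
        )
    return [
        Window(seqid, start, min(start + window_size - 1, hi))
        for start in range(lo, hi + 1, window_size)
    ]


def _cum_coverage(mi: MergedIntervals, x: np.ndarray) -> np.ndarray:
    """Covered bases in [1, x] for each x (vectorized)."""
    n = len(mi.starts)
    lengths = mi.ends - mi.starts + 1
    prefix = np.concatenate(([0], np.cumsum(lengths)))
    k = np.searchsorted(mi.ends, x, side="right")  # intervals ending at or before x
    cov = prefix[k]
    partial = k < n
    ki = np.minimum(k, n - 1)
    add = np.where(partial & (mi.starts[ki] <= x), x - mi.starts[ki] + 1, 0)
    return cov + np.maximum(add, 0)


def window_coverage(mi: MergedIntervals, windows: Sequence[Window]) -> np.ndarray:
    """Bases of the merged set falling inside each window (clipped)."""
    if not windows:
        return np.zeros(0, dtype=np.int64)
    if len(mi.starts) == 0:
        return np.zeros(len(windows), dtype=np.int64)
    a = np.fromiter((w.start for w in windows), dtype=np.int64, count=len(windows))
    b = np.fromiter((w.end for w in windows), dtype=np.int64, count=len(windows))
    return _cum_coverage(mi, b) - _cum_coverage(mi, a - 1)


def _round_density(covered: np.ndarray, spans: np.ndarray, rounding: str) -> np.ndarray:
    if rounding not in ROUNDINGS:
        raise ConfigError(
            f"unknown rounding method {rounding!r}; valid: {', '.join(ROUNDINGS)}"
        )
    if rounding == "floor":
        return (100 * covered) // spans
    return -((-100 * covered) // spans)


def density(
    mi: MergedIntervals,
    windows: Sequence[Window],
    ftype: str,
    rounding: str = "floor",
) -> DensityTrack:
    """Per-window rounded density (percent) of a merged interval set.

    The denominator is the actual window span, so a truncated final
    window still reports a value in [0, 100]. Integer arithmetic makes
    floor/ceil exact (no float round-off at bin edges).
    """
    covered = window_coverage(mi, windows)
    spans = np.fromiter((w.span for w in windows), dtype=np.int64, count=len(windows))
    if len(windows) == 0:
        values: list[int] = []
    else:
        values = _round_density(covered, spans, rounding).tolist()
    return DensityTrack(mi.seqid, ftype, mi.track, list(windows), values, covered)


GC_FTYPE = "GC%"


def gc_track(
    seq: SequenceRecord, windows: Sequence[Window], rounding: str = "floor"
) -> DensityTrack:
    """GC percent per window: 100 * (G+C) / (A+C+G+T), N excluded.

    A window of only Ns (empty denominator) reports 0. Requires the
    sequence to be present on the record.
    """
    if seq.sequence is None:
        raise ChromotileError(
            f"GC track requested for {seq.seqid} but no sequence is available "
            "(no ##FASTA section in the GFF)"
        )
    arr = np.frombuffer(seq.sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    cum_gc = np.concatenate(([0], np.cumsum(is_gc, dtype=np.int64)))
    cum_acgt = np.concatenate(([0], np.cumsum(is_acgt, dtype=np.int64)))
    if not windows:
        return DensityTrack(seq.seqid, GC_FTYPE, FUSED, [], [], np.zeros(0, np.int64))
    a = np.fromiter((w.start for w in windows), dtype=np.int64, count=len(windows))
    b = np.fromiter((w.end for w in windows), dtype=np.int64, count=len(windows))
    b = np.minimum(b, len(arr))
    gc = cum_gc[np.maximum(b, 0)] - cum_gc[np.maximum(a - 1, 0)]
    denom = cum_acgt[np.maximum(b, 0)] - cum_acgt[np.maximum(a - 1, 0)]
    safe = np.maximum(denom, 1)
    values = _round_density(gc, safe, rounding)
    values[denom == 0] = 0
    return DensityTrack(seq.seqid, GC_FTYPE, FUSED, list(windows), values.tolist(), gc)


def auto_window(
    seq_lengths: Sequence[int], max_height_px: int, chrome_px: int = 0
) -> int:
    """Window size such that the longest sequence fits the pixel budget.

    ``chrome_px`` is the fixed vertical overhead (margins, title, labels)
    already committed; the windows of the longest sequence must fit in
    ``max_height_px - chrome_px`` rows of one pixel each.
    """
    if not seq_lengths:
        raise ConfigError("auto window sizing needs at least one sequence")
    available = max_height_px - chrome_px
    if available <= 0:
        raise ConfigError(
            f"maximum picture height {max_height_px}px leaves no room after "
            f"{chrome_px}px of margins and labels"
        )
    longest = max(seq_lengths)
    w = -(-longest // available)  # ceil division
    log.info("auto window size: %d bp (longest sequence %d bp, %d px)", w, longest, available)
    return int(w)
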