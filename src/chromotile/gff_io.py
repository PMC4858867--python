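"""Reading GFF annotation and BED region files; writing the density CSV.

GFF dialects (GFF2, GFF2.5, GFF3) differ only in the column-9 attribute
syntax, which this tool never interprets, so a single tolerant 9-column
reader handles all three: column 3 is the feature type, columns 4-5 are
1-based inclusive coordinates, column 7 the strand, column 9 opaque text.
A ``##FASTA`` directive switches the file into its embedded-sequence
section, which is handed to Bio.SeqIO.

BED regions are 0-based half-open on disk (BED standard) and converted to
1-based inclusive internally at the point of use.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

from Bio import SeqIO

from .errors import ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .intervals import DensityTrack

log = logging.getLogger("chromotile")

#: canonical strand labels
PLUS = "plus"
MINUS = "minus"
UNSTRANDED = "unstranded"

_STRAND_MAP = {"+": PLUS, "-": MINUS}


@dataclass(frozen=True, slots=True)
class Feature:
    """One GFF record: a typed, stranded interval on a sequence.

    ``start``/``end`` are 1-based inclusive base-pair positions.
    """

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    strand: str  # plus / minus / unstranded

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")
        if not self.ftype:
            raise ValueError("empty feature type")


@dataclass(slots=True)
class SequenceRecord:
    """A chromosome (or scaffold): its declared length and optional sequence."""

    seqid: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.seqid}: sequence length {len(self.sequence)} != "
                f"declared length {self.length}"
            )


@dataclass(frozen=True, slots=True)
class Region:
    """A BED interval: 0-based start (inclusive), exclusive end."""

    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"empty or negative region [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start


def parse_gff(
    path: str | Path,
    wanted_types: Iterable[str] = (),
    *,
    require_match: bool = True,
) -> tuple[list[Feature], list[SequenceRecord]]:
    """Parse one GFF file, keeping only features whose type is wanted.

    Parameters
    ----------
    path
        GFF2/GFF2.5/GFF3 file; may contain ``##sequence-region`` pragmas
        and an embedded ``##FASTA`` section.
    wanted_types
        Feature types (GFF column 3) to keep; empty keeps everything.
    require_match
        If true (default), raise when filtering leaves nothing, naming the
        types that were present. The pipeline disables this per file so a
        multi-file run only fails if NO file contributes a feature.

    Returns
    -------
    (features, sequence_records)
        Sequence length precedence is ``##sequence-region`` pragma, then
        embedded FASTA length, then max feature end. A pragma/FASTA length
        mismatch is an error. Features running past the declared length
        are clipped to it with a warning.
    """
    path = Path(path)
    wanted = set(wanted_types)
    features: list[Feature] = []
    seen_types: set[str] = set()
    pragma_lengths: dict[str, int] = {}
    seq_order: list[str] = []
    fasta_lines: list[str] | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if fasta_lines is not None:
                fasta_lines.append(raw)
                continue
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("##FASTA"):
                    fasta_lines = []
                elif line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        try:
                            pragma_lengths[parts[1]] = int(parts[3])
                        except ValueError:
                            raise ParseError(
                                f"{path}:{lineno}: bad ##sequence-region pragma: {line!r}"
                            ) from None
                        if parts[1] not in seq_order:
                            seq_order.append(parts[1])
                continue
            if line.startswith(">"):
                # headerless FASTA section (tolerated in the wild)
                fasta_lines = [raw]
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 8 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, source, ftype = cols[0], cols[1], cols[2]
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{cols[3]!r}/{cols[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}]"
                )
            if not ftype:
                raise ParseError(f"{path}:{lineno}: empty feature type")
            seen_types.add(ftype)
            if seqid not in pragma_lengths and seqid not in seq_order:
                seq_order.append(seqid)
            if wanted and ftype not in wanted:
                continue
            strand = _STRAND_MAP.get(cols[6], UNSTRANDED)
            features.append(Feature(seqid, source, ftype, start, end, strand))

    fasta_records: dict[str, str] = {}
    if fasta_lines:
        for rec in SeqIO.parse(io.StringIO("".join(fasta_lines)), "fasta"):
            fasta_records[rec.id] = str(rec.seq)
            if rec.id not in seq_order:
                seq_order.append(rec.id)

    max_end: dict[str, int] = {}
    for f in features:
        if f.end > max_end.get(f.seqid, 0):
            max_end[f.seqid] = f.end

    records: list[SequenceRecord] = []
    for seqid in seq_order:
        seq = fasta_records.get(seqid)
        if seqid in pragma_lengths:
            length = pragma_lengths[seqid]
            if seq is not None and len(seq) != length:
                raise ParseError(
                    f"{path}: {seqid}: ##sequence-region length {length} "
                    f"contradicts FASTA length {len(seq)}"
                )
        elif seq is not None:
            length = len(seq)
        else:
            length = max_end.get(seqid, 0)
        if length > 0:
            records.append(SequenceRecord(seqid, length, seq))

    lengths = {r.seqid: r.length for r in records}
    clipped = 0
    for i, f in enumerate(features):
        declared = lengths.get(f.seqid, f.end)
        if f.end > declared:
            features[i] = Feature(
                f.seqid, f.source, f.ftype, min(f.start, declared), declared, f.strand
            )
            clipped += 1
    if clipped:
        log.warning("%s: clipped %d feature(s) past declared sequence end", path, clipped)

    if require_match and wanted and not features:
        raise ParseError(
            f"{path}: no features of requested types "
            f"({', '.join(sorted(wanted))}); types seen: "
            f"{', '.join(sorted(seen_types)) or 'none'}"
        )
    return features, records


def parse_bed(path: str | Path) -> list[Region]:
    """Parse a BED3+ file into regions (columns beyond 3 are ignored)."""
    path = Path(path)
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{cols[1]!r}/{cols[2]!r}"
                ) from None
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: empty or invalid region [{start}, {end})"
                )
            regions.append(Region(cols[0], start, end))
    return regions


CSV_COLUMNS = ("seqid", "window_start", "window_end", "ftype", "strand_mode", "density")

#: canonical on-disk order of strand tracks
TRACK_ORDER = {MINUS: 0, PLUS: 1, "fused": 2}


def write_density_csv(
    tracks: Sequence["DensityTrack"],
    path: str | Path,
    *,
    window_size: int | None = None,
) -> None:
    """Write all density tracks as one tab-separated table.

    One row per (sequence, feature type, strand track, window); window
    coordinates are 1-based inclusive to match GFF. Rows are sorted by
    seqid, feature type, strand track (minus, plus, fused) and window
    start. The chosen window size is echoed as a leading comment line.
    """
    rows = []
    for t in tracks:
        for w, v in zip(t.windows, t.values):
            rows.append((t.seqid, w.start, w.end, t.ftype, t.track, v))
    rows.sort(key=lambda r: (r[0], r[3], TRACK_ORDER.get(r[4], 3), r[1]))
    with open(path, "w", newline="") as fh:
        if window_size is not None:
            fh.write(f"# window_size={window_size}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        writer.writerows(rows)
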