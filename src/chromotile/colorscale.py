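"""Numbered colour scales mapping integer densities (0-100 %) to colours.

The catalog ships twelve scales in a human-editable TSV file
(``data/colour_scales.tsv``); each scale is an ordered list of
integer-inclusive density bins ``low:high:#rrggbb`` that must cover 0-100
with no gaps or overlaps. Three archetypes matter most in practice:

* id 1 (default): "deciles" blue→red, one tone step per 10 % of density;
* id 10: low-density — 0 % grey, 1-9 % blue→red gradient in 1 % steps,
  10 % and above dark red (for sparse features such as rolling-circle
  transposons, where everything would otherwise land in the first decile);
* id 12: GC content — below 30 % grey, 30-49 % green→red gradient,
  50 % and above dark red.

Users can point ``--scales_file`` at their own catalog to override any of
them without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigError, ParseError

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass(frozen=True)
class ColourScale:
    id: int
    name: str
    bins: tuple[tuple[int, int, str], ...]  # (low, high, "#rrggbb"), inclusive

    def __post_init__(self) -> None:
        expect = 0
        for low, high, colour in self.bins:
            if low != expect or high < low:
                raise ParseError(
                    f"scale {self.id} ({self.name}): bins must cover 0-100 "
                    f"contiguously; bin [{low},{high}] breaks at {expect}"
                )
            if not _HEX_RE.match(colour):
                raise ParseError(
                    f"scale {self.id}: bad colour {colour!r} (expect #rrggbb)"
                )
            expect = high + 1
        if expect != 101:
            raise ParseError(
                f"scale {self.id} ({self.name}): bins stop at {expect - 1}, "
                "must reach 100"
            )


def _parse_scale_line(lineno: int, line: str, origin: str) -> ColourScale:
    cols = line.split("\t")
    if len(cols) != 3:
        raise ParseError(f"{origin}:{lineno}: expected 3 tab-separated columns")
    try:
        sid = int(cols[0])
    except ValueError:
        raise ParseError(f"{origin}:{lineno}: non-integer scale id {cols[0]!r}") from None
    bins = []
    for part in cols[2].split(","):
        fields = part.split(":")
        if len(fields) != 3:
            raise ParseError(f"{origin}:{lineno}: bad bin {part!r} (low:high:#hex)")
        try:
            bins.append((int(fields[0]), int(fields[1]), fields[2].strip()))
        except ValueError:
            raise ParseError(f"{origin}:{lineno}: non-integer bounds in {part!r}") from None
    return ColourScale(sid, cols[1].strip(), tuple(bins))


def load_scales(path: str | Path | None = None) -> dict[int, ColourScale]:
    """Load a scale catalog; defaults to the one shipped with the package."""
    if path is None:
        text = (
            resources.files("chromotile").joinpath("data/colour_scales.tsv").read_text()
        )
        origin = "colour_scales.tsv"
    else:
        text = Path(path).read_text()
        origin = str(path)
    catalog: dict[int, ColourScale] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        scale = _parse_scale_line(lineno, line, origin)
        if scale.id in catalog:
            raise ParseError(f"{origin}:{lineno}: duplicate scale id {scale.id}")
        catalog[scale.id] = scale
    if not catalog:
        raise ParseError(f"{origin}: no scales defined")
    return catalog


_default_catalog: dict[int, ColourScale] | None = None


def get_scale(scale_id: int, catalog: dict[int, ColourScale] | None = None) -> ColourScale:
    """Look up a scale by its catalog number."""
    global _default_catalog
    if catalog is None:
        if _default_catalog is None:
            _default_catalog = load_scales()
        catalog = _default_catalog
    try:
        return catalog[scale_id]
    except KeyError:
        raise ConfigError(
            f"unknown colour scale {scale_id}; available: "
            f"{', '.join(str(k) for k in sorted(catalog))}"
        ) from None


def map_density(value: int, scale: ColourScale) -> str:
    """Colour of the unique bin containing an integer density 0-100."""
    if not 0 <= value <= 100:
        raise ChromotileInternal(value)
    for low, high, colour in scale.bins:
        if low <= value <= high:
            return colour
    raise AssertionError("bins validated to cover 0-100")  # pragma: no cover


class ChromotileInternal(AssertionError):
    """Density outside [0, 100] reached the colour mapper (upstream bug)."""

    def __init__(self, value: int) -> None:
        super().__init__(f"density {value} outside [0, 100]")
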