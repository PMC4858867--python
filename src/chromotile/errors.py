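"""Exception hierarchy.

Everything user-facing raises :class:`ChromotileError`; the CLI converts
these into a message on stderr and a nonzero exit status.
"""


class ChromotileError(Exception):
    """Base class for all chromotile errors."""


class ParseError(ChromotileError):
    """Malformed input file (GFF, BED or scale-definition line)."""


class ConfigError(ChromotileError):
    """Invalid option value or option combination."""
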