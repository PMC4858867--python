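"""Seeded synthetic GFF3 fixtures for tests, examples and benchmarks.

Emulates the shape of a real annotation file: ``##sequence-region``
pragmas, uniformly placed features of one or more types on random
strands, and an embedded ``##FASTA`` section whose base composition
follows a requested GC fraction. What it deliberately does NOT emulate:
feature hierarchies (gene→mRNA→exon), clustered or centromere-depleted
feature placement, and realistic length distributions — densities here
are spatially homogeneous, which is exactly what makes fixtures easy to
check against a per-base oracle.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

# length range of generated features (bp); uniform draw
_MIN_LEN = 50
_MAX_LEN = 2000
# fraction of features written with strand "." (unstranded)
_UNSTRANDED_FRAC = 0.05
_FASTA_WRAP = 70


def generate_fixture(
    seed: int,
    n_seqs: int = 2,
    seq_length: int = 100_000,
    n_features: int = 500,
    types: tuple[str, ...] = ("gene", "exon"),
    gc_bias: float = 0.5,
    with_sequence: bool = True,
) -> str:
    """Return a deterministic GFF3 document as text.

    Features are distributed uniformly over the ``n_seqs`` sequences of
    equal length; each gets a uniform type from ``types``, a uniform
    start, a length in [50, 2000] (clipped at the sequence end) and a
    strand (+/- with a 5 % unstranded fraction). With ``with_sequence``
    the document ends in a ``##FASTA`` section of i.i.d. bases with
    P(G) = P(C) = gc_bias/2.
    """
    if n_seqs < 1 or seq_length < 1 or n_features < 0:
        raise ValueError("counts must be positive")
    if not 0 <= gc_bias <= 1:
        raise ValueError(f"gc_bias must be in [0, 1], got {gc_bias}")
    if not types:
        raise ValueError("need at least one feature type")
    rng = np.random.default_rng(seed)
    seqids = [f"chr{i + 1}" for i in range(n_seqs)]

    lines = ["##gff-version 3"]
    for sid in seqids:
        lines.append(f"##sequence-region {sid} 1 {seq_length}")

    which = rng.integers(0, n_seqs, size=n_features)
    starts = rng.integers(1, seq_length + 1, size=n_features)
    lengths = rng.integers(_MIN_LEN, _MAX_LEN + 1, size=n_features)
    tidx = rng.integers(0, len(types), size=n_features)
    u = rng.random(size=n_features)
    for i in range(n_features):
        sid = seqids[which[i]]
        start = int(starts[i])
        end = min(start + int(lengths[i]) - 1, seq_length)
        if u[i] < _UNSTRANDED_FRAC:
            strand = "."
        elif u[i] < _UNSTRANDED_FRAC + (1 - _UNSTRANDED_FRAC) / 2:
            strand = "+"
        else:
            strand = "-"
        lines.append(
            f"{sid}\tsynthetic\t{types[tidx[i]]}\t{start}\t{end}\t.\t{strand}\t.\tID=f{i}"
        )

    if with_sequence:
        lines.append("##FASTA")
        p = [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        for sid in seqids:
            lines.append(f">{sid}")
            seq = rng.choice(alphabet, size=seq_length, p=p).tobytes().decode("ascii")
            for j in range(0, seq_length, _FASTA_WRAP):
                lines.append(seq[j : j + _FASTA_WRAP])
    return "\n".join(lines) + "\n"


def write_fixture(path: str | Path, seed: int, **kwargs) -> Path:
    """Generate and write a fixture; returns the path."""
    path = Path(path)
    path.write_text(generate_fixture(seed, **kwargs))
    return path
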