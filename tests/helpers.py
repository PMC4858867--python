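"""Independent per-base oracle used to cross-check the vectorized kernels.

The oracle materializes a boolean array with one entry per base pair, so
it is obviously correct but only viable on small sequences; the
implementation under test never uses it.
"""

from __future__ import annotations

import numpy as np


def bitmap(pairs, length: int) -> np.ndarray:
    """Boolean coverage array indexed 1..length (index 0 unused)."""
    cov = np.zeros(length + 1, dtype=bool)
    for s, e in pairs:
        cov[s : min(e, length) + 1] = True
    return cov


def oracle_window_coverage(pairs, windows, length: int) -> np.ndarray:
    """Covered bases per window, counted base by base."""
    cov = bitmap(pairs, length)
    return np.array([int(cov[w.start : w.end + 1].sum()) for w in windows])


def oracle_total_coverage(pairs, length: int) -> int:
    return int(bitmap(pairs, length).sum())


def oracle_raw_density(pairs, window, length: int) -> float:
    cov = bitmap(pairs, length)
    return 100.0 * cov[window.start : window.end + 1].sum() / window.span
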