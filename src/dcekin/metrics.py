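"""Small reporting helpers: significant-figure rounding and ratio tables.

Used to reproduce the printed distribution-volume and dye-penetration
ratio comparisons (e.g. normalizing per-condition means by the largest
condition to a 0.33 : 0.8 : 1 style proportion).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def round_sig(x: float, n_sig: int = 2) -> float:
    """Round to ``n_sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    digits = n_sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, digits)


def normalize_ratios(values: Sequence[float], reference_index: int = -1,
                     n_sig: int = 2) -> list[float]:
    """Express values as proportions of a reference entry (default: last).

    Each proportion is rounded to ``n_sig`` significant figures, matching
    how such ratio comparisons are conventionally printed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("normalize_ratios requires at least one value")
    ref = arr[reference_index]
    if ref == 0:
        raise ValueError("reference value must be nonzero")
    return [round_sig(float(v / ref), n_sig) for v in arr]
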