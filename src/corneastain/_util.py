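"""Small integer-exact numeric helpers shared across the pipeline.

Every pipeline stage keeps its intermediates as legal 8-bit images, so
rounding back to integers happens after each stage.  Round-half-up on a
non-negative rational num/den is computed in pure integer arithmetic as
``(2*num + den) // (2*den)`` so results are exact and platform independent.
"""

from __future__ import annotations

import numpy as np


def round_half_up_div(num: np.ndarray | int, den: int) -> np.ndarray | int:
    """Round num/den half-up, exactly, for integer num (may be negative)."""
    num = np.asarray(num, dtype=np.int64)
    den = int(den)
    if den <= 0:
        raise ValueError("denominator must be positive")
    # floor((num + den/2) / den) == (2*num + den) // (2*den); numpy floor-divides.
    return (2 * num + den) // (2 * den)


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round floats half-up (0.5 -> 1, 1.5 -> 2), elementwise."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def as_uint8(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and cast to uint8."""
    return np.clip(x, 0, 255).astype(np.uint8)
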