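"""Small shared helpers: reporting-layer rounding and sequence utilities."""
from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (spreadsheet-style).

    Python's built-in ``round`` uses banker's rounding; printed TE/RPKM/ratio
    values follow the half-away-from-zero convention, so 0.125 -> 0.13.
    Applied at the reporting layer only; internal math stays full precision.
    """
    if not math.isfinite(x):
        return x
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
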