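"""Fixed numeric formatting shared by all TSV/SVG writers.

Six significant digits, no exponent styling surprises: output files must be
byte-identical across runs and platforms.
"""

from __future__ import annotations

import math


def fmt(x) -> str:
    """Format a number with 6 significant digits; integers stay integral."""
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, int):
        return str(x)
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if math.isnan(x):
        return "nan"
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"
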