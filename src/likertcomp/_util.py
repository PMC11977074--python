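"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero, elementwise.

    Printed reference values in the psychometrics literature are rounded
    half-away-from-zero (e.g. 14.375 -> 14.38), which differs from Python's
    banker's rounding. Internal arithmetic stays at full precision; this is
    only used when comparing against printed constants or formatting output.
    """
    x = np.asarray(x, dtype=float)
    f = 10.0 ** ndigits
    out = np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f
    if out.ndim == 0:
        return float(out)
    return out
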