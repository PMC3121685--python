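"""Wrap-aware angular arithmetic on a degrees, CCW-positive convention.

All movement directions in this package are degrees counterclockwise from
the +x axis, so 90 deg is "straight ahead" on a tabletop task. Differences
are always reduced to the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np


def wrap_degrees(angle):
    """Reduce an angle (or array of angles) to (-180, 180] degrees."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def angular_difference(a, b):
    """Signed difference a - b wrapped to (-180, 180] degrees."""
    return wrap_degrees(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
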