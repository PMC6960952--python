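"""Gravity-component removal.

A foot-mounted accelerometer at rest reads +g on its vertical axis.  Over a
continuous level-walking record the mean vertical acceleration is the gravity
component (the kinematic part averages out over whole cycles), so subtracting
the whole-record mean removes it.
"""

from __future__ import annotations

import numpy as np

from .exceptions import LengthError


def remove_gravity(az) -> np.ndarray:
    """Subtract the whole-record mean from the vertical acceleration."""
    az = np.asarray(az, dtype=float)
    if az.size == 0:
        raise LengthError("cannot remove gravity from an empty signal")
    return az - az.mean()
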