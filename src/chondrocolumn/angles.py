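"""Shared angle conventions.

All public interfaces use degrees. The tissue frame is 2D with the
proximodistal (PD) axis along +y and the mediolateral (ML) axis along +x.
Orientation measurements on cells and clones are *axial* (undirected):
a direction and its opposite are the same measurement, so axial angles
live on a half-turn and are folded into [0, 90] when measured against a
reference axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "axial_angle_deg",
    "fold_axial_deg",
    "half_turn_deg",
    "unit",
]


def unit(v) -> np.ndarray:
    """Normalize a 2-vector; raise on (near-)zero length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("zero-length or non-finite vector")
    return v / n


def axial_angle_deg(v, axis) -> float:
    """Axial (undirected) angle in degrees between vector ``v`` and ``axis``.

    Folded to [0, 90]: ``axial_angle_deg(v, a) == axial_angle_deg(-v, a)``.
    """
    v = unit(v)
    a = unit(axis)
    c = abs(float(np.dot(v, a)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def fold_axial_deg(angle_deg):
    """Fold angles (degrees, any range) to the axial range [0, 90].

    180-degree periodicity with reflection: 95 -> 85, 135 -> 45, -30 -> 30.
    """
    a = np.mod(np.asarray(angle_deg, dtype=float), 180.0)
    return np.where(a > 90.0, 180.0 - a, a)


def half_turn_deg(angle_deg):
    """Reduce angles (degrees) to the half-turn range [0, 180)."""
    return np.mod(np.asarray(angle_deg, dtype=float), 180.0)
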