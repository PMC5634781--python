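"""Sister-cell pivot kinematics.

After an oriented (mediolateral) division, one sister chondrocyte
rotates around the other so the pair stacks proximodistally. The pivot
angle ω is the angle of the undirected sister-cell axis relative to the
mediolateral (+x) axis, computed from the two-argument arctangent of the
coordinate differences. Raw angles live on a half-turn [0°, 180°); the
series is unwrapped over time (each step within ±90° of the previous
value) so cumulative pivots past 90° are preserved, then normalized to
0° at the first observation.

Outcome classification follows the observed bands: a *complete* pivot
plateaus between 70° and 100°, a *partial* pivot in [30°, 70°), anything
else is *none*. The plateau is estimated as the mean of the last quartile
of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .angles import fold_axial_deg, half_turn_deg
from .synthetic import SisterTrack

__all__ = [
    "PivotSeries",
    "COMPLETE_RANGE_DEG",
    "PARTIAL_RANGE_DEG",
    "raw_pivot_angle",
    "unwrap_half_turn",
    "pivot_angle_series",
    "classify_pivot",
    "division_orientation",
    "summarize_tracks",
]

COMPLETE_RANGE_DEG = (70.0, 100.0)
PARTIAL_RANGE_DEG = (30.0, 70.0)


@dataclass
class PivotSeries:
    """Pivot-angle trajectory of one sister pair."""

    pair_id: str
    t_h: np.ndarray
    omega_raw_deg: np.ndarray   # unwrapped
    omega_deg: np.ndarray       # normalized to 0 at first sample
    final_omega_deg: float
    pivot_class: Optional[str] = None
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_id": self.pair_id,
            "t_h": self.t_h,
            "omega_deg": self.omega_deg,
        })


def raw_pivot_angle(p1, p2) -> float:
    """Angle of the sister-cell axis to the mediolateral (+x) axis.

    Two-argument arctangent of (Δy, Δx) reduced to [0°, 180°) — the axis
    is undirected. Raises for coincident points.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    if np.hypot(*d) < 1e-12:
        raise ValueError("coincident sister positions; angle undefined")
    return float(half_turn_deg(np.degrees(np.arctan2(d[1], d[0]))))


def unwrap_half_turn(raw_deg: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unwrap a sequence of half-turn angles into a continuous trajectory.

    Each step adds the representative of the raw change (mod 180°) with
    the smallest magnitude, so |Δ| ≤ 90° per step and cumulative values
    can pass 90° or 180°. A step of exactly 90° is directionally
    ambiguous; it is resolved toward the smaller absolute cumulative
    change from the starting value, and the ambiguity is reported.
    """
    raw = np.asarray(raw_deg, dtype=float)
    out = np.empty_like(raw)
    out[0] = raw[0]
    ambiguous = False
    for i in range(1, len(raw)):
        step = (raw[i] - out[i - 1] + 90.0) % 180.0 - 90.0
        if np.isclose(abs(step), 90.0, atol=1e-9):
            ambiguous = True
            up, down = out[i - 1] + 90.0, out[i - 1] - 90.0
            step = (90.0 if abs(up - out[0]) <= abs(down - out[0])
                    else -90.0)
        out[i] = out[i - 1] + step
    return out, ambiguous


def pivot_angle_series(track: SisterTrack) -> PivotSeries:
    """Compute the unwrapped, normalized pivot-angle series of a track.

    The normalized series subtracts the first unwrapped value, so it
    always starts at exactly 0°. The final value is the plateau estimate
    (mean of the last quartile of samples; the last sample alone, with a
    low-confidence flag, when there are fewer than four samples).
    """
    raw = np.array([
        raw_pivot_angle(track.p1[i], track.p2[i])
        for i in range(len(track))
    ])
    unwrapped, ambiguous = unwrap_half_turn(raw)
    omega = unwrapped - unwrapped[0]
    flags = ["ambiguous_quarter_turn_step"] if ambiguous else []

    n = len(omega)
    if n >= 4:
        k = max(1, n // 4)
        final = float(np.mean(omega[-k:]))
    else:
        final = float(omega[-1])
        flags.append("short_series_low_confidence")
    return PivotSeries(pair_id=track.pair_id, t_h=track.t_h,
                       omega_raw_deg=unwrapped, omega_deg=omega,
                       final_omega_deg=final, flags=flags)


def classify_pivot(series: PivotSeries,
                   complete_range=COMPLETE_RANGE_DEG,
                   partial_range=PARTIAL_RANGE_DEG) -> str:
    """Classify a pivot by |final ω|: complete, partial, or none.

    Complete when |final ω| falls in ``complete_range`` (closed),
    partial when in ``partial_range`` (closed-open), none otherwise.
    """
    f = abs(series.final_omega_deg)
    if complete_range[0] <= f <= complete_range[1]:
        cls = "complete"
    elif partial_range[0] <= f < partial_range[1]:
        cls = "partial"
    else:
        cls = "none"
    series.pivot_class = cls
    return cls


def division_orientation(track: SisterTrack) -> float:
    """Axial angle of the first-sample sister axis to the ML axis, [0°, 90°].

    0° means a mediolateral division; 90° a proximodistal one.
    """
    return float(fold_axial_deg(
        raw_pivot_angle(track.p1[0], track.p2[0])))


def summarize_tracks(tracks,
                     complete_range=COMPLETE_RANGE_DEG,
                     partial_range=PARTIAL_RANGE_DEG
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair series (long format) and classification summary tables."""
    long_rows, summary_rows = [], []
    for track in tracks:
        series = pivot_angle_series(track)
        cls = classify_pivot(series, complete_range, partial_range)
        long_rows.append(series.to_frame())
        summary_rows.append({
            "pair_id": track.pair_id,
            "condition": track.condition or "",
            "n_samples": len(track),
            "division_orientation_deg": division_orientation(track),
            "final_omega_deg": series.final_omega_deg,
            "pivot_class": cls,
            "flags": ";".join(series.flags),
        })
    long_df = (pd.concat(long_rows, ignore_index=True)
               if long_rows else pd.DataFrame(
                   columns=["pair_id", "t_h", "omega_deg"]))
    return long_df, pd.DataFrame(summary_rows)
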