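"""Intensity-based measurements on two-cell fluorescence frames.

Four measurements, all scale-free or ratio-based so they are invariant
to multiplying intensities by a positive gain:

* **Polyline kymograph profile** — cytoplasmic intensity sampled along a
  polyline between two sister-cell nuclei, normalized by the line
  maximum (F/Fmax). Sisters in contact give a flat profile; separated
  sisters give an inverted-bell profile.
* **Contact statistic** — ``dip = 1 - min`` F/Fmax over the central
  portion of the path; pairs are called in contact while the dip stays
  below a threshold.
* **Junctional fraction** — junctional intensity normalized to the total
  intensity over the sister pair (background-subtracted), and the
  per-time junctional F/Fmax time course.
* **Pearson colocalization** — product-moment correlation of two
  channels over a pixel mask.

Images are 2D arrays indexed [row, col] (pixel frame, origin top-left).
Profile waypoints and region polygons are given in (x, y) pixel
coordinates in that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = [
    "LineProfile",
    "ContactCall",
    "JunctionMeasure",
    "ColocResult",
    "polyline_profile",
    "contact_statistic",
    "junctional_fraction",
    "junction_timecourse",
    "pearson_colocalization",
]


@dataclass
class LineProfile:
    """Intensity sampled along a polyline, with F/Fmax normalization."""

    positions_um: np.ndarray
    intensity: np.ndarray
    f_over_fmax: Optional[np.ndarray]
    flags: list = field(default_factory=list)


@dataclass
class ContactCall:
    t_h: float
    dip: float
    in_contact: bool


@dataclass
class JunctionMeasure:
    t_h: float
    junctional_intensity: float
    total_intensity: float
    ratio: Optional[float]
    f_over_fmax_t: Optional[float] = None
    cumulative_f_over_fmax: Optional[float] = None
    flags: list = field(default_factory=list)


@dataclass
class ColocResult:
    r: Optional[float]
    n_px: int
    defined: bool = True


def _polyline_samples(waypoints: np.ndarray, step_px: float):
    """Sample points and arc-length positions along a polyline."""
    pts, pos, tangents = [], [], []
    s0 = 0.0
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        if length < 1e-9:
            continue
        t_hat = seg / length
        n = max(2, int(np.ceil(length / step_px)) + 1)
        ts = np.linspace(0.0, length, n)
        if pts:  # drop duplicated joint point
            ts = ts[1:]
        pts.append(a[None, :] + ts[:, None] * t_hat[None, :])
        pos.append(s0 + ts)
        tangents.append(np.tile(t_hat, (len(ts), 1)))
        s0 += length
    if not pts:
        raise ValueError("polyline has zero length")
    return np.vstack(pts), np.concatenate(pos), np.vstack(tangents)


def polyline_profile(frame: np.ndarray, waypoints,
                     width_px: int = 1,
                     step_px: float = 0.5,
                     pixel_size_um: float = 1.0) -> LineProfile:
    """Intensity profile along a polyline, averaged across a band.

    ``waypoints`` are (x, y) pixel coordinates (≥ 2 points, inside the
    frame). Intensity is bilinearly interpolated at half-pixel steps
    along the path and averaged across ``width_px`` parallel lines
    perpendicular to it. The profile is normalized by its maximum
    (F/Fmax); an all-zero line leaves ``f_over_fmax`` as None, flagged.
    """
    frame = np.asarray(frame, dtype=float)
    wp = np.atleast_2d(np.asarray(waypoints, dtype=float))
    if len(wp) < 2:
        raise ValueError("polyline needs at least two waypoints")
    h, w = frame.shape
    if np.any(wp[:, 0] < 0) or np.any(wp[:, 0] > w - 1) or \
            np.any(wp[:, 1] < 0) or np.any(wp[:, 1] > h - 1):
        raise ValueError("waypoints fall outside the frame")

    pts, pos, tans = _polyline_samples(wp, step_px)
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    acc = np.zeros(len(pts))
    for off in offsets:
        q = pts + off * normals
        # map_coordinates wants (row, col) = (y, x)
        acc += ndimage.map_coordinates(
            frame, [q[:, 1], q[:, 0]], order=1, mode="nearest")
    intensity = acc / len(offsets)

    fmax = float(intensity.max(initial=0.0))
    flags = []
    if fmax <= 0:
        f = None
        flags.append("zero_intensity_profile")
    else:
        f = intensity / fmax
    return LineProfile(positions_um=pos * pixel_size_um,
                       intensity=intensity, f_over_fmax=f, flags=flags)


def contact_statistic(profile: LineProfile,
                      interior_fraction: float = 0.5,
                      dip_threshold: float = 0.5,
                      t_h: float = 0.0) -> ContactCall:
    """Contact call from the dip of an F/Fmax profile.

    The interior is the central ``interior_fraction`` of the path
    (excluding the nuclear endpoints); ``dip = 1 - min`` interior
    F/Fmax, in [0, 1]. The pair is in contact iff dip ≤ threshold.
    """
    if profile.f_over_fmax is None:
        raise ValueError("profile has undefined F/Fmax (zero intensity)")
    pos = profile.positions_um
    span = pos[-1] - pos[0]
    mid = (pos[0] + pos[-1]) / 2.0
    half = interior_fraction * span / 2.0
    sel = (pos >= mid - half) & (pos <= mid + half)
    if not np.any(sel):
        raise ValueError("interior window contains no samples")
    dip = 1.0 - float(np.min(profile.f_over_fmax[sel]))
    return ContactCall(t_h=t_h, dip=dip, in_contact=dip <= dip_threshold)


def _region_mask(shape, region) -> np.ndarray:
    """Boolean mask from an (x, y) polygon vertex list or a boolean array."""
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != tuple(shape):
            raise ValueError("mask shape does not match frame")
        return region
    verts = np.atleast_2d(region.astype(float))
    if verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("region polygon needs >= 3 (x, y) vertices")
    # polygon2mask expects (row, col) vertices
    return polygon2mask(tuple(shape), verts[:, ::-1])


def junctional_fraction(frame: np.ndarray, junction_region,
                        pair_region, t_h: float = 0.0) -> JunctionMeasure:
    """Junctional / total intensity ratio for one sister pair.

    Regions are polygons ((x, y) pixel vertices) or boolean masks; the
    junction region must lie inside the pair region. Intensities are
    background-subtracted using the median outside the pair region. A
    non-positive total is flagged undefined.
    """
    frame = np.asarray(frame, dtype=float)
    jmask = _region_mask(frame.shape, junction_region)
    pmask = _region_mask(frame.shape, pair_region)
    if not np.all(pmask[jmask]):
        raise ValueError("junction region must lie inside the pair region")
    background = float(np.median(frame[~pmask])) if np.any(~pmask) else 0.0
    junctional = float(np.sum(frame[jmask] - background))
    total = float(np.sum(frame[pmask] - background))
    flags = []
    if total <= 0:
        ratio = None
        flags.append("non_positive_total_intensity")
    else:
        ratio = junctional / total
    return JunctionMeasure(t_h=t_h, junctional_intensity=junctional,
                           total_intensity=total, ratio=ratio, flags=flags)


def junction_timecourse(frames: np.ndarray, junction_regions,
                        t_h: Optional[Sequence[float]] = None,
                        pair_regions=None) -> list[JunctionMeasure]:
    """Junctional F/Fmax over a time course.

    Per time point, the junctional intensity (background-subtracted when
    ``pair_regions`` is given, raw sum otherwise) is divided by its
    maximum over the course. The running (cumulative) sum of F/Fmax is
    emitted as a secondary series.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with >= 2 time points")
    nt = frames.shape[0]
    if t_h is None:
        t_h = np.arange(nt, dtype=float)
    if not hasattr(junction_regions, "__len__") or \
            isinstance(junction_regions, np.ndarray) and \
            junction_regions.ndim == 2:
        junction_regions = [junction_regions] * nt
    if len(junction_regions) != nt:
        raise ValueError("one junction region per time point required")

    raw = np.empty(nt)
    for i in range(nt):
        jmask = _region_mask(frames.shape[1:], junction_regions[i])
        if pair_regions is not None:
            preg = (pair_regions[i]
                    if hasattr(pair_regions, "__len__")
                    and not (isinstance(pair_regions, np.ndarray)
                             and pair_regions.ndim == 2)
                    else pair_regions)
            pmask = _region_mask(frames.shape[1:], preg)
            bg = float(np.median(frames[i][~pmask]))
        else:
            bg = 0.0
        raw[i] = float(np.sum(frames[i][jmask] - bg))

    fmax = raw.max()
    out = []
    if fmax <= 0:
        for i in range(nt):
            out.append(JunctionMeasure(
                t_h=float(t_h[i]), junctional_intensity=raw[i],
                total_intensity=np.nan, ratio=None, f_over_fmax_t=None,
                flags=["zero_maximum_intensity"]))
        return out
    f = raw / fmax
    csum = np.cumsum(f)
    for i in range(nt):
        out.append(JunctionMeasure(
            t_h=float(t_h[i]), junctional_intensity=raw[i],
            total_intensity=np.nan, ratio=None,
            f_over_fmax_t=float(f[i]),
            cumulative_f_over_fmax=float(csum[i])))
    return out


def pearson_colocalization(ch1, ch2, mask=None) -> ColocResult:
    """Pearson correlation between two channels over a pixel mask.

    1 is perfect colocalization, -1 perfect anti-correlation. A constant
    channel makes the coefficient undefined (flagged, r is None).
    """
    a = np.asarray(ch1, dtype=float).ravel()
    b = np.asarray(ch2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("channels must have equal size")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != a.shape:
            raise ValueError("mask must match channel size")
        a, b = a[m], b[m]
    if len(a) < 3:
        raise ValueError("need at least three masked pixels")
    sa, sb = np.std(a), np.std(b)
    if sa < 1e-300 or sb < 1e-300:
        return ColocResult(r=None, n_px=len(a), defined=False)
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return ColocResult(r=max(-1.0, min(1.0, r)), n_px=len(a))
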