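"""Clone-level morphology quantification.

Implements the column-classification scheme for multicolor clonal
analysis of growth-plate cartilage:

* **Φ (phi)** — axial angle between each cell's minor axis and the
  tissue proximodistal axis, folded to [0°, 90°]. The within-clone
  standard deviation of Φ classifies a clone as *stacked* (SD ≤ 12°) or
  *arbitrary*.
* **θ (theta)** — for stacked clones, the axial angle between the
  segment from the topmost cell to each other cell and the proximodistal
  axis. The SD of θ classifies *single* (≤ 12°) vs *multi* column width.
* **Column orientation** — the axial angle between the major principal
  axis of the clone's outline polygon (radius-expanded convex hull of
  centroids) and the proximodistal axis.

All angles are degrees. The default proximodistal axis is +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .angles import axial_angle_deg, unit

__all__ = [
    "CloneRecord",
    "PD_AXIS",
    "measure_phi",
    "phi_angles",
    "classify_clone_arrangement",
    "measure_theta",
    "classify_column_width",
    "column_polygon",
    "column_orientation",
    "summarize_clones",
]

PD_AXIS = np.array([0.0, 1.0])

DEFAULT_SD_THRESHOLD_DEG = 12.0
DEFAULT_CELL_RADIUS_UM = 5.0


@dataclass
class CloneRecord:
    """Classification outputs for one clone."""

    clone_id: str
    n_cells: int
    phi_deg: np.ndarray
    phi_sd_deg: float
    arrangement: str                      # "stacked" | "arbitrary"
    theta_deg: Optional[np.ndarray] = None
    theta_sd_deg: Optional[float] = None
    width_class: Optional[str] = None     # "single" | "multi"
    orientation_deg: Optional[float] = None
    flags: list = field(default_factory=list)


def measure_phi(minor_axis, pd_axis=PD_AXIS) -> float:
    """Angle Φ between a cell's minor axis and the proximodistal axis.

    Axial: Φ(v) == Φ(-v), folded to [0°, 90°]. Raises on a zero vector.
    """
    return axial_angle_deg(minor_axis, pd_axis)


def phi_angles(cells: pd.DataFrame, pd_axis=PD_AXIS) -> np.ndarray:
    """Vectorized Φ for every row of a cell table."""
    v = cells[["minor_axis_dx", "minor_axis_dy"]].to_numpy(dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length minor axis in cell table")
    a = unit(pd_axis)
    c = np.abs(v @ a) / norms
    return np.degrees(np.arccos(np.clip(c, 0.0, 1.0)))


def _sample_sd(x: np.ndarray) -> float:
    # unbiased (n-1) denominator; clones are small
    return float(np.std(x, ddof=1))


def classify_clone_arrangement(
        cells: pd.DataFrame,
        threshold_deg: float = DEFAULT_SD_THRESHOLD_DEG,
        pd_axis=PD_AXIS) -> CloneRecord:
    """Classify one clone as stacked vs arbitrary from the SD of Φ.

    Requires more than two cells (the measurement is defined on clones
    with > 2 cells); stacked iff sample SD(Φ) ≤ ``threshold_deg``.
    """
    if len(cells) <= 2:
        raise ValueError(
            f"clone {_clone_id(cells)!r} has {len(cells)} cells; "
            "arrangement classification requires more than two cells")
    phi = phi_angles(cells, pd_axis)
    sd = _sample_sd(phi)
    return CloneRecord(
        clone_id=_clone_id(cells),
        n_cells=len(cells),
        phi_deg=phi,
        phi_sd_deg=sd,
        arrangement="stacked" if sd <= threshold_deg else "arbitrary",
    )


def _clone_id(cells: pd.DataFrame) -> str:
    if "clone_id" in cells.columns and len(cells):
        ids = cells["clone_id"].unique()
        if len(ids) > 1:
            raise ValueError(f"cell table mixes clones: {list(ids)}")
        return str(ids[0])
    return "clone"


def _topmost_index(xy: np.ndarray, cell_ids: Sequence,
                   pd_axis=PD_AXIS) -> int:
    """Topmost = maximal proximodistal coordinate (projection on pd_axis).

    Ties broken by smaller mediolateral coordinate, then cell_id, so the
    choice is deterministic.
    """
    a = unit(pd_axis)
    ml = np.array([a[1], -a[0]])  # mediolateral direction
    pd_coord = xy @ a
    ml_coord = xy @ ml
    order = sorted(
        range(len(xy)),
        key=lambda i: (-pd_coord[i], ml_coord[i], str(cell_ids[i])))
    return order[0]


def measure_theta(cells: pd.DataFrame, pd_axis=PD_AXIS) -> np.ndarray:
    """θ for each non-topmost cell of a stacked clone.

    θ_i is the axial angle in [0°, 90°] between the segment from the
    topmost cell to cell i and the proximodistal axis.
    """
    if len(cells) < 2:
        raise ValueError("theta requires at least two cells")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    top = _topmost_index(xy, cells["cell_id"].to_numpy()
                         if "cell_id" in cells.columns
                         else np.arange(len(cells)), pd_axis)
    thetas = []
    for i in range(len(xy)):
        if i == top:
            continue
        seg = xy[i] - xy[top]
        if np.linalg.norm(seg) < 1e-12:
            raise ValueError("coincident cell centroids in clone")
        thetas.append(axial_angle_deg(seg, pd_axis))
    return np.array(thetas)


def classify_column_width(
        record: CloneRecord, cells: pd.DataFrame,
        threshold_deg: float = DEFAULT_SD_THRESHOLD_DEG,
        pd_axis=PD_AXIS) -> CloneRecord:
    """Fill θ and the single/multi width class on a stacked clone record.

    Single iff sample SD(θ) ≤ ``threshold_deg``. A clone with a single θ
    value (two cells) has no SD; it is classed single by convention and
    flagged low-confidence.
    """
    if record.arrangement != "stacked":
        raise ValueError("width classification is defined for stacked clones")
    theta = measure_theta(cells, pd_axis)
    record.theta_deg = theta
    if len(theta) < 2:
        record.theta_sd_deg = 0.0
        record.width_class = "single"
        record.flags.append("width_low_confidence")
    else:
        record.theta_sd_deg = _sample_sd(theta)
        record.width_class = ("single"
                              if record.theta_sd_deg <= threshold_deg
                              else "multi")
    return record


def column_polygon(cells: pd.DataFrame,
                   cell_radius_um: float = DEFAULT_CELL_RADIUS_UM) -> Polygon:
    """Clone outline: convex hull of centroids expanded by the cell radius.

    The expansion makes the outline a closed, simple polygon even for
    collinear or two-cell clones (a stadium shape). Raises when all
    centroids coincide.
    """
    if len(cells) < 2:
        raise ValueError("polygon requires at least two cells")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if np.allclose(xy, xy[0], atol=1e-9):
        raise ValueError("all centroids coincident; polygon undefined")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    poly = hull.buffer(cell_radius_um, quad_segs=64)
    if not isinstance(poly, Polygon) or not poly.is_valid:
        raise ValueError("failed to build a simple clone polygon")
    return poly


def _polygon_second_moments(poly: Polygon):
    """Area, centroid, and second central area moments of a polygon.

    Green's-theorem formulas over the exterior ring; holes are not
    expected for radius-expanded hulls.
    """
    x, y = np.asarray(poly.exterior.coords.xy)
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    cross = x0 * y1 - x1 * y0
    area = 0.5 * np.sum(cross)
    cx = np.sum((x0 + x1) * cross) / (6.0 * area)
    cy = np.sum((y0 + y1) * cross) / (6.0 * area)
    xr0, xr1 = x0 - cx, x1 - cx
    yr0, yr1 = y0 - cy, y1 - cy
    crossr = xr0 * yr1 - xr1 * yr0
    mu20 = np.sum((xr0 ** 2 + xr0 * xr1 + xr1 ** 2) * crossr) / 12.0
    mu02 = np.sum((yr0 ** 2 + yr0 * yr1 + yr1 ** 2) * crossr) / 12.0
    mu11 = np.sum((xr0 * yr1 + 2 * xr0 * yr0 + 2 * xr1 * yr1
                   + xr1 * yr0) * crossr) / 24.0
    sgn = np.sign(area)
    return abs(area), (cx, cy), sgn * mu20, sgn * mu02, sgn * mu11


def column_orientation(poly: Polygon, pd_axis=PD_AXIS,
                       isotropy_rtol: float = 1e-3
                       ) -> tuple[float, bool]:
    """Axial angle of the polygon's major principal axis to the PD axis.

    The major axis is the principal axis of the polygon's area (second
    central moments). Returns ``(angle_deg, defined)``; a (near-)isotropic
    polygon such as a circle has no major axis, in which case the angle
    is 0° and ``defined`` is False.
    """
    area, _, mu20, mu02, mu11 = _polygon_second_moments(poly)
    if area <= 0:
        raise ValueError("degenerate polygon")
    aniso = np.hypot(mu20 - mu02, 2.0 * mu11)
    if aniso <= isotropy_rtol * (mu20 + mu02):
        return 0.0, False
    ang = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    major = np.array([np.cos(ang), np.sin(ang)])
    return axial_angle_deg(major, pd_axis), True


def summarize_clones(cells: pd.DataFrame,
                     threshold_deg: float = DEFAULT_SD_THRESHOLD_DEG,
                     cell_radius_um: float = DEFAULT_CELL_RADIUS_UM,
                     pd_axis=PD_AXIS,
                     min_cells: int = 3) -> pd.DataFrame:
    """Per-clone summary table over a full cell table.

    Clones with fewer than ``min_cells`` cells are skipped (the
    arrangement measurement needs more than two cells). Columns:
    clone_id, n_cells, phi_mean_deg, phi_sd_deg, arrangement,
    theta_sd_deg, width_class, orientation_deg, orientation_defined.
    """
    out = []
    for clone_id, grp in cells.groupby("clone_id", sort=True):
        if len(grp) < min_cells:
            continue
        rec = classify_clone_arrangement(grp, threshold_deg, pd_axis)
        row = {
            "clone_id": clone_id,
            "n_cells": rec.n_cells,
            "zone": grp["zone"].iloc[0] if "zone" in grp.columns else "",
            "phi_mean_deg": float(np.mean(rec.phi_deg)),
            "phi_sd_deg": rec.phi_sd_deg,
            "arrangement": rec.arrangement,
            "theta_sd_deg": np.nan,
            "width_class": "",
            "orientation_deg": np.nan,
            "orientation_defined": False,
        }
        if rec.arrangement == "stacked":
            rec = classify_column_width(rec, grp, threshold_deg, pd_axis)
            row["theta_sd_deg"] = rec.theta_sd_deg
            row["width_class"] = rec.width_class
        poly = column_polygon(grp, cell_radius_um)
        ang, defined = column_orientation(poly, pd_axis)
        row["orientation_deg"] = ang
        row["orientation_defined"] = defined
        out.append(row)
    return pd.DataFrame(out)
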