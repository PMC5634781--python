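"""Synthetic growth-plate tissue, pivot tracks, and intensity frames.

Everything the downstream analysis consumes can be generated here with a
known ground truth: per-cell observation tables with clone labels and
minor-axis orientations, sister-pair coordinate tracks through a pivot,
and rendered two-cell fluorescence frames (disk bodies, cytoplasmic
bridge, junctional band).

The generator encodes the contrast between growth-plate zones: in the
proliferative zone clonally related chondrocytes stack into columns whose
cells' minor axes cluster tightly about the proximodistal axis, while
resting-zone clones are loose clusters with near-uniform orientation.
Perturbation presets (``scenario_preset``) bundle parameter choices that
reproduce the qualitative phenotypes of planar-cell-polarity loss/gain
and N-cadherin blockade: misoriented divisions, failed pivots, sister-cell
separation, and junctional decay.

Coordinates are micrometres in the tissue frame (proximodistal = +y,
mediolateral = +x). Every generator takes an explicit seed; fixed seed
means byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .angles import fold_axial_deg

__all__ = [
    "TissueParams",
    "PivotScenario",
    "FrameSpec",
    "ScenarioBundle",
    "SisterTrack",
    "generate_tissue",
    "simulate_pivot_track",
    "render_pair_frames",
    "generate_coloc_pair",
    "scenario_preset",
    "PRESET_NAMES",
]

CELL_TABLE_COLUMNS = [
    "cell_id",
    "clone_id",
    "zone",
    "t_h",
    "x_um",
    "y_um",
    "minor_axis_dx",
    "minor_axis_dy",
]


@dataclass(frozen=True)
class TissueParams:
    """Parameters for one synthetic tissue field.

    ``orientation_spread_deg`` is the within-clone SD of the minor-axis
    angle about the clone's own stack axis; ``clone_tilt_sd_deg`` is the
    SD of the per-clone stack tilt away from the proximodistal axis.
    Together they reproduce the observed structure of proliferative
    clones: cell orientation varies a few degrees inside a clone while
    whole columns are tilted by ~10 degrees on average. Resting-zone
    clones ignore both and draw near-uniform axial orientations.
    """

    n_clones: int = 20
    cells_per_clone: tuple[int, int] = (5, 12)
    zone: str = "proliferative"
    orientation_spread_deg: float = 3.0
    column_width: int = 1
    cell_spacing_um: float = 10.0
    clone_tilt_sd_deg: float = 15.0
    stack_tilt_deg: Optional[float] = None  # fix the tilt of every clone
    stack_tilt_uniform: bool = False  # arbitrary stack orientation
    position_jitter_um: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.orientation_spread_deg < 0:
            raise ValueError("orientation_spread_deg must be >= 0")
        lo, hi = self.cells_per_clone
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_clone must be a range with lo >= 1")
        if self.zone not in ("resting", "proliferative"):
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.column_width < 1:
            raise ValueError("column_width must be >= 1")
        if self.cell_spacing_um <= 0:
            raise ValueError("cell_spacing_um must be > 0")


@dataclass(frozen=True)
class PivotScenario:
    """One sister-pair pivot trajectory.

    The inter-cell axis starts at ``division_angle_deg`` from the
    mediolateral axis (0 = mediolateral division, optionally jittered
    uniformly by ±``division_jitter_deg``) and progresses smoothly by
    ``final_pivot_deg`` over the first ``rise_fraction`` of the time
    course, then plateaus. If ``separates`` is set, the pivot freezes at
    ``separation_time_h`` and the inter-cell distance grows afterwards.
    """

    division_angle_deg: float = 0.0
    division_jitter_deg: float = 0.0
    final_pivot_deg: float = 85.0
    duration_h: float = 10.0
    sample_interval_h: float = 1.0
    noise_sd_deg: float = 0.0
    separates: bool = False
    separation_time_h: float = 3.0
    separation_rate_um_per_h: float = 1.5
    pair_distance_um: float = 8.0
    rise_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.sample_interval_h <= 0:
            raise ValueError("sample_interval_h must be > 0")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        if not (0 < self.rise_fraction <= 1):
            raise ValueError("rise_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FrameSpec:
    """Rendering parameters for two-cell fluorescence frames.

    Cell bodies are uniform disks; the region between them (within one
    cell radius of the inter-cell segment but outside both bodies) is
    filled at ``bridge_level`` while the cells are in contact and at
    ``background_level`` once separated. ``junction_level`` > 0 adds a
    thin band across the interface midline. Intensities are arbitrary
    units; additive Gaussian noise with SD ``noise_sd``.
    """

    image_size_px: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.5
    cell_radius_um: float = 4.0
    background_level: float = 10.0
    cell_level: float = 100.0
    bridge_level: float = 80.0
    junction_level: float = 0.0
    junction_halfwidth_um: float = 0.75
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px must be positive")
        for name in ("background_level", "cell_level", "bridge_level",
                     "junction_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0 or self.cell_radius_um <= 0:
            raise ValueError("pixel_size_um and cell_radius_um must be > 0")


@dataclass
class SisterTrack:
    """Time-indexed coordinates of two sister cells.

    ``t_h`` strictly increasing, ``p1``/``p2`` of shape (n, 2) in µm.
    """

    pair_id: str
    t_h: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    condition: Optional[str] = None

    def __post_init__(self):
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.p1 = np.atleast_2d(np.asarray(self.p1, dtype=float))
        self.p2 = np.atleast_2d(np.asarray(self.p2, dtype=float))
        if self.t_h.ndim != 1 or len(self.t_h) < 2:
            raise ValueError("track needs >= 2 samples")
        if np.any(np.diff(self.t_h) <= 0):
            raise ValueError("t_h must be strictly increasing")
        for name, arr in (("p1", self.p1), ("p2", self.p2)):
            if arr.shape != (len(self.t_h), 2):
                raise ValueError(f"{name} must have shape (n_samples, 2)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.t_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_id": self.pair_id,
            "t_h": self.t_h,
            "x1_um": self.p1[:, 0],
            "y1_um": self.p1[:, 1],
            "x2_um": self.p2[:, 0],
            "y2_um": self.p2[:, 1],
        })


@dataclass(frozen=True)
class ScenarioBundle:
    """A named phenotype preset: tissue + pivot + frame parameters."""

    name: str
    tissue: TissueParams
    pivot: PivotScenario
    frame: FrameSpec
    junction_halflife_h: Optional[float] = None  # None = persistent band


# ---------------------------------------------------------------------------
# cell tables


def _clone_positions(rng, n_cells: int, width: int, spacing: float,
                     tilt_deg: float, jitter: float) -> np.ndarray:
    """Stack ``n_cells`` into ``width`` parallel columns along a tilted axis."""
    tilt = np.radians(tilt_deg)
    u = np.array([np.sin(tilt), np.cos(tilt)])   # stack axis (PD tilted)
    v = np.array([np.cos(tilt), -np.sin(tilt)])  # lateral
    rows = int(np.ceil(n_cells / width))
    pts = []
    for i in range(n_cells):
        r, c = divmod(i, width)
        # center the lateral offsets so width-2 stacks straddle the axis
        lat = (c - (width - 1) / 2.0) * spacing
        pts.append(-r * spacing * u + lat * v)
    pts = np.array(pts)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    return pts[:rows * width][:n_cells]


def _resting_positions(rng, n_cells: int, spacing: float) -> np.ndarray:
    """Loose non-overlapping cluster for a resting-zone clone."""
    pts = [np.zeros(2)]
    tries = 0
    while len(pts) < n_cells:
        cand = rng.uniform(-1, 1, size=2) * spacing * max(
            2.0, np.sqrt(n_cells))
        if all(np.linalg.norm(cand - p) >= spacing * 0.9 for p in pts):
            pts.append(cand)
        tries += 1
        if tries > 10_000:
            raise RuntimeError(
                "could not place resting clone without overlap; "
                "reduce cells_per_clone or cell_spacing_um")
    return np.array(pts)


def generate_tissue(params: TissueParams) -> pd.DataFrame:
    """Generate a per-cell observation table for one synthetic tissue.

    Returns a DataFrame with columns ``cell_id, clone_id, zone, t_h,
    x_um, y_um, minor_axis_dx, minor_axis_dy``. Clones are laid out on a
    coarse grid with enough pitch that clones never overlap.

    Proliferative clones: each clone draws a stack tilt (normal with SD
    ``clone_tilt_sd_deg``, or uniform on (-90, 90] if
    ``stack_tilt_uniform``, or fixed at ``stack_tilt_deg``); cells stack
    along that axis in ``column_width`` columns, and each cell's minor
    axis is the stack axis plus normal noise with SD
    ``orientation_spread_deg``. Resting clones: scattered positions,
    minor-axis angle uniform on the half-turn.
    """
    if params.n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(params.seed)
    lo, hi = params.cells_per_clone

    # grid pitch: worst-case clone extent plus margin
    extent = (hi + 2) * params.cell_spacing_um * max(2, params.column_width)
    n_side = int(np.ceil(np.sqrt(params.n_clones)))

    rows = []
    for ci in range(params.n_clones):
        gx, gy = divmod(ci, n_side)
        anchor = np.array([gx * extent, gy * extent])
        n_cells = int(rng.integers(lo, hi + 1))
        clone_id = f"clone_{ci:04d}"

        if params.zone == "proliferative":
            if params.stack_tilt_deg is not None:
                tilt = float(params.stack_tilt_deg)
            elif params.stack_tilt_uniform:
                tilt = float(rng.uniform(-90.0, 90.0))
            else:
                tilt = float(rng.normal(0.0, params.clone_tilt_sd_deg))
            pts = anchor + _clone_positions(
                rng, n_cells, params.column_width, params.cell_spacing_um,
                tilt, params.position_jitter_um)
            ang = np.radians(tilt + rng.normal(
                0.0, params.orientation_spread_deg, size=n_cells)) \
                if params.orientation_spread_deg > 0 else \
                np.full(n_cells, np.radians(tilt))
            # minor axis measured from the PD (+y) axis
            axes = np.column_stack([np.sin(ang), np.cos(ang)])
        else:
            pts = anchor + _resting_positions(
                rng, n_cells, params.cell_spacing_um)
            ang = rng.uniform(0.0, np.pi, size=n_cells)
            axes = np.column_stack([np.sin(ang), np.cos(ang)])

        for j in range(n_cells):
            rows.append({
                "cell_id": f"{clone_id}_c{j:03d}",
                "clone_id": clone_id,
                "zone": params.zone,
                "t_h": 0.0,
                "x_um": pts[j, 0],
                "y_um": pts[j, 1],
                "minor_axis_dx": axes[j, 0],
                "minor_axis_dy": axes[j, 1],
            })
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# pivot tracks


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_pivot_track(s: PivotScenario,
                         pair_id: str = "pair_0") -> SisterTrack:
    """Simulate sister-cell coordinates through a pivot.

    The inter-cell axis angle (from the mediolateral +x axis) follows a
    smoothstep ramp from the division angle to division + final pivot,
    reaching the plateau at ``rise_fraction * duration_h`` so the final
    value is held exactly in the noise-free case. Additive normal noise
    on the angle at every sample. With ``separates``, the angle freezes
    at the separation time and the inter-cell distance grows linearly
    afterwards; otherwise the distance is constant.
    """
    rng = np.random.default_rng(s.seed)
    t = np.arange(0.0, s.duration_h + 0.5 * s.sample_interval_h,
                  s.sample_interval_h)
    start = s.division_angle_deg
    if s.division_jitter_deg > 0:
        start = start + rng.uniform(-s.division_jitter_deg,
                                    s.division_jitter_deg)

    t_eff = np.minimum(t, s.separation_time_h) if s.separates else t
    rise_end = s.rise_fraction * s.duration_h
    ang = start + s.final_pivot_deg * _smoothstep(t_eff / rise_end)
    if s.noise_sd_deg > 0:
        ang = ang + rng.normal(0.0, s.noise_sd_deg, size=ang.shape)

    dist = np.full_like(t, s.pair_distance_um)
    if s.separates:
        dist = dist + s.separation_rate_um_per_h * np.maximum(
            0.0, t - s.separation_time_h)

    rad = np.radians(ang)
    axis = np.column_stack([np.cos(rad), np.sin(rad)])
    half = (dist / 2.0)[:, None] * axis
    return SisterTrack(pair_id=pair_id, t_h=t, p1=-half, p2=half)


# ---------------------------------------------------------------------------
# frame rendering


def _dist_to_segment(px, py, a, b):
    """Pointwise distance from pixel grids to segment a-b (all in px units)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.hypot(px - a[0], py - a[1]), np.zeros_like(px)
    tpar = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    tc = np.clip(tpar, 0.0, 1.0)
    cx = a[0] + tc * ab[0]
    cy = a[1] + tc * ab[1]
    return np.hypot(px - cx, py - cy), tpar


def track_pixel_coords(track: SisterTrack,
                       spec: FrameSpec) -> np.ndarray:
    """Pixel (x, y) coordinates of both cells per frame, shape (T, 2, 2).

    Uses the same centering as ``render_pair_frames``: the track's
    bounding box is centered in the image, tissue y (proximodistal, up)
    maps to image y downward.
    """
    h, w = spec.image_size_px
    all_xy = np.vstack([track.p1, track.p2])
    center = (all_xy.min(axis=0) + all_xy.max(axis=0)) / 2.0
    out = np.empty((len(track), 2, 2))
    for i, pts in enumerate(zip(track.p1, track.p2)):
        for j, p in enumerate(pts):
            out[i, j, 0] = (p[0] - center[0]) / spec.pixel_size_um \
                + (w - 1) / 2.0
            out[i, j, 1] = (h - 1) / 2.0 \
                - (p[1] - center[1]) / spec.pixel_size_um
    return out


def render_pair_frames(track: SisterTrack, spec: FrameSpec,
                       junction_scale: Optional[np.ndarray] = None,
                       contact_slack: float = 1.05) -> np.ndarray:
    """Render a (T, H, W) float32 stack of two-disk frames from a track.

    The track is centered in the frame; a coordinate that would place a
    cell body outside the image raises. Bodies are disks at
    ``cell_level``; the interior between them renders at ``bridge_level``
    while the centre distance is within ``contact_slack * 2r`` and at
    background once separated. The junction band (when
    ``junction_level > 0`` and the pair is in contact) overwrites a thin
    strip across the interface midline, scaled per-frame by
    ``junction_scale``.
    """
    h, w = spec.image_size_px
    n = len(track)
    if junction_scale is None:
        junction_scale = np.ones(n)
    junction_scale = np.asarray(junction_scale, dtype=float)
    if junction_scale.shape != (n,):
        raise ValueError("junction_scale must have one entry per time point")

    r_px = spec.cell_radius_um / spec.pixel_size_um
    px = track_pixel_coords(track, spec)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rng = np.random.default_rng(spec.seed)
    stack = np.empty((n, h, w), dtype=np.float32)
    hw_px = spec.junction_halfwidth_um / spec.pixel_size_um

    for i in range(n):
        a = px[i, 0]
        b = px[i, 1]
        for p in (a, b):
            if not (r_px <= p[0] <= w - 1 - r_px
                    and r_px <= p[1] <= h - 1 - r_px):
                raise ValueError(
                    f"cell body at frame {i} falls outside the image; "
                    "enlarge image_size_px or shrink pixel_size_um")
        d_seg, tpar = _dist_to_segment(xx, yy, a, b)
        d1 = np.hypot(xx - a[0], yy - a[1])
        d2 = np.hypot(xx - b[0], yy - b[1])
        body = (d1 <= r_px) | (d2 <= r_px)
        sep = float(np.hypot(*(b - a)))
        in_contact = sep <= contact_slack * 2.0 * r_px

        img = np.full((h, w), spec.background_level, dtype=float)
        interior = (d_seg <= r_px) & ~body
        if in_contact:
            img[interior] = spec.bridge_level
        img[body] = spec.cell_level
        # junctional material decays via junction_scale rather than
        # vanishing at geometric separation: residual signal sits at the
        # (former) interface midline between the bodies
        if spec.junction_level * junction_scale[i] > 0:
            along = np.abs(tpar - 0.5) * sep  # px distance from midpoint
            band = (along <= hw_px) & (d_seg <= r_px)
            img[band] = spec.junction_level * junction_scale[i]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[i] = img
    return stack


# ---------------------------------------------------------------------------
# colocalization channels


def generate_coloc_pair(r_target: float, n_px: int,
                        seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two intensity vectors whose sample Pearson r converges to r_target.

    Gaussian channels (arbitrary units, mean 50, SD 10) with the second
    built from the first by the Cholesky construction; |r_target| = 1
    reduces to an exact affine relation.
    """
    if not -1.0 <= r_target <= 1.0:
        raise ValueError("r_target must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_px)
    z2 = rng.standard_normal(n_px)
    mix = r_target * z1 + np.sqrt(max(0.0, 1.0 - r_target ** 2)) * z2
    return 50.0 + 10.0 * z1, 50.0 + 10.0 * mix


# ---------------------------------------------------------------------------
# phenotype presets

PRESET_NAMES = ("wild_type", "pcp_loss", "pcp_gain", "ncad_block")


def scenario_preset(name: str, seed: int = 0) -> ScenarioBundle:
    """Parameter bundle for one of the four qualitative phenotypes.

    - ``wild_type``: mediolateral division, full pivot into a single
      proximodistal column, persistent cytoplasmic bridge and junctional
      band.
    - ``pcp_loss`` (dominant-negative receptor): division angle
      randomized, but sisters stay associated and pivot fully, giving
      stacked clones with arbitrary stack orientation.
    - ``pcp_gain`` (receptor overexpression): randomized division angle,
      sisters separate a few hours after cytokinesis, pivot aborts, and
      the junctional band decays (half-life ~5 h).
    - ``ncad_block`` (adhesion blockade): division is still mediolateral
      but sisters separate and no complete pivot occurs.
    """
    frame = FrameSpec(junction_level=150.0, noise_sd=2.0, seed=seed)
    if name == "wild_type":
        return ScenarioBundle(
            name=name,
            tissue=TissueParams(zone="proliferative",
                                orientation_spread_deg=3.0,
                                column_width=1, seed=seed),
            pivot=PivotScenario(division_angle_deg=0.0,
                                division_jitter_deg=10.0,
                                final_pivot_deg=85.0, noise_sd_deg=3.0,
                                seed=seed),
            frame=frame,
            junction_halflife_h=None)
    if name == "pcp_loss":
        return ScenarioBundle(
            name=name,
            tissue=TissueParams(zone="proliferative",
                                orientation_spread_deg=3.0,
                                column_width=1, stack_tilt_uniform=True,
                                seed=seed),
            pivot=PivotScenario(division_angle_deg=45.0,
                                division_jitter_deg=45.0,
                                final_pivot_deg=85.0, noise_sd_deg=3.0,
                                seed=seed),
            frame=frame,
            junction_halflife_h=None)
    if name == "pcp_gain":
        return ScenarioBundle(
            name=name,
            tissue=TissueParams(zone="proliferative",
                                orientation_spread_deg=30.0,
                                column_width=1, seed=seed),
            pivot=PivotScenario(division_angle_deg=45.0,
                                division_jitter_deg=45.0,
                                final_pivot_deg=85.0, noise_sd_deg=3.0,
                                separates=True, separation_time_h=3.0,
                                seed=seed),
            frame=frame,
            junction_halflife_h=5.0)
    if name == "ncad_block":
        # the adhesion-blockade experiment images nuclei/cytoplasm only,
        # so no junctional channel is rendered
        return ScenarioBundle(
            name=name,
            tissue=TissueParams(zone="proliferative",
                                orientation_spread_deg=3.0,
                                column_width=1, seed=seed),
            pivot=PivotScenario(division_angle_deg=0.0,
                                division_jitter_deg=10.0,
                                final_pivot_deg=85.0, noise_sd_deg=3.0,
                                separates=True, separation_time_h=3.0,
                                seed=seed),
            frame=replace(frame, junction_level=0.0),
            junction_halflife_h=None)
    raise ValueError(
        f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


def preset_with_seed(bundle: ScenarioBundle, seed: int) -> ScenarioBundle:
    """Copy of a bundle with every component reseeded."""
    return ScenarioBundle(
        name=bundle.name,
        tissue=replace(bundle.tissue, seed=seed),
        pivot=replace(bundle.pivot, seed=seed),
        frame=replace(bundle.frame, seed=seed),
        junction_halflife_h=bundle.junction_halflife_h)
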