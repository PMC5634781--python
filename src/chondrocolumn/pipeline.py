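"""End-to-end composition of the three analysis tracks.

``run_pipeline`` chains clonal-architecture classification, pivot
kinematics, and intensity dynamics over one set of inputs (a cell table,
sister tracks, and optionally rendered frame stacks) and returns a
report bundle of tidy tables plus a manifest that makes the run
reproducible. ``simulate_inputs`` builds those inputs from a phenotype
preset; ``compare_conditions`` runs the statistical battery between two
report bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .circstats import AngleSample, ks_normality, watson_u2, wilcoxon_rank_sum
from .intensity import (contact_statistic, junction_timecourse,
                        polyline_profile)
from .morphology import summarize_clones
from .pivot import summarize_tracks
from .synthetic import (FrameSpec, ScenarioBundle, SisterTrack,
                        generate_tissue, preset_with_seed,
                        render_pair_frames, scenario_preset,
                        simulate_pivot_track, track_pixel_coords)

logger = logging.getLogger("chondrocolumn")

__all__ = [
    "PipelineInputs",
    "ReportBundle",
    "simulate_inputs",
    "run_pipeline",
    "run_preset",
    "compare_conditions",
]


@dataclass
class PipelineInputs:
    cells: Optional[pd.DataFrame] = None
    tracks: list = field(default_factory=list)
    stacks: list = field(default_factory=list)   # parallel to tracks, optional
    frame_spec: Optional[FrameSpec] = None
    condition: str = ""


@dataclass
class ReportBundle:
    clone_summary: pd.DataFrame
    pivot_long: pd.DataFrame
    pivot_summary: pd.DataFrame
    contact: pd.DataFrame
    junction: pd.DataFrame
    manifest: dict

    def write(self, output_dir) -> Path:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.clone_summary.to_csv(out / "clone_summary.csv", index=False)
        self.pivot_long.to_csv(out / "pivot_series.csv", index=False)
        self.pivot_summary.to_csv(out / "pivot_summary.csv", index=False)
        self.contact.to_csv(out / "contact_calls.csv", index=False)
        self.junction.to_csv(out / "junction_timecourse.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str))
        return out


def junction_decay_scale(t_h: np.ndarray,
                         halflife_h: Optional[float]) -> np.ndarray:
    """Exponential junction decay profile; all-ones when persistent."""
    t_h = np.asarray(t_h, dtype=float)
    if halflife_h is None:
        return np.ones_like(t_h)
    return 0.5 ** (t_h / halflife_h)


def simulate_inputs(bundle: ScenarioBundle, n_pairs: int = 8,
                    seed: int = 0, render: bool = True) -> PipelineInputs:
    """Generate one condition's inputs from a phenotype preset.

    The tissue uses ``seed``; pair k uses ``seed + 1000 + k`` so pairs
    are independent but reproducible. Frames are rendered per pair with
    the preset's junction decay applied.
    """
    bundle = preset_with_seed(bundle, seed)
    cells = generate_tissue(bundle.tissue)
    tracks, stacks = [], []
    for k in range(n_pairs):
        sc = dataclasses.replace(bundle.pivot, seed=seed + 1000 + k)
        track = simulate_pivot_track(sc, pair_id=f"{bundle.name}_{k:03d}")
        track.condition = bundle.name
        tracks.append(track)
        if render:
            scale = junction_decay_scale(track.t_h,
                                         bundle.junction_halflife_h)
            spec = dataclasses.replace(bundle.frame, seed=seed + 2000 + k)
            stacks.append(render_pair_frames(track, spec,
                                             junction_scale=scale))
    return PipelineInputs(cells=cells, tracks=tracks, stacks=stacks,
                          frame_spec=bundle.frame, condition=bundle.name)


def _junction_band_polygon(a: np.ndarray, b: np.ndarray,
                           hw_px: float, r_px: float) -> np.ndarray:
    """Rectangle across the interface midline, (x, y) pixel vertices."""
    axis = b - a
    norm = np.hypot(*axis)
    u = axis / norm
    v = np.array([-u[1], u[0]])
    m = (a + b) / 2.0
    return np.array([m + hw_px * u + r_px * v,
                     m + hw_px * u - r_px * v,
                     m - hw_px * u - r_px * v,
                     m - hw_px * u + r_px * v])


def _contact_and_junction(track: SisterTrack, stack: np.ndarray,
                          spec: FrameSpec, config: RunConfig):
    px = track_pixel_coords(track, spec)
    r_px = spec.cell_radius_um / spec.pixel_size_um
    hw_px = spec.junction_halfwidth_um / spec.pixel_size_um
    contact_rows = []
    junction_regions = []
    for i in range(len(track)):
        prof = polyline_profile(stack[i], [px[i, 0], px[i, 1]],
                                width_px=3, pixel_size_um=spec.pixel_size_um)
        call = contact_statistic(prof,
                                 interior_fraction=config.interior_fraction,
                                 dip_threshold=config.dip_threshold,
                                 t_h=float(track.t_h[i]))
        contact_rows.append({
            "pair_id": track.pair_id, "t_h": call.t_h,
            "dip": call.dip, "in_contact": call.in_contact,
        })
        junction_regions.append(
            _junction_band_polygon(px[i, 0], px[i, 1], hw_px, r_px))
    junction_rows = []
    if spec.junction_level > 0:
        measures = junction_timecourse(stack, junction_regions,
                                       t_h=track.t_h)
        for m in measures:
            junction_rows.append({
                "pair_id": track.pair_id, "t_h": m.t_h,
                "f_over_fmax": m.f_over_fmax_t,
                "cumulative_f_over_fmax": m.cumulative_f_over_fmax,
            })
    return contact_rows, junction_rows


def run_pipeline(config: RunConfig,
                 inputs: PipelineInputs) -> ReportBundle:
    """Run every applicable stage over one condition's inputs.

    Empty inputs produce an empty report (with a warning), not a
    failure. Any stage error is re-raised with the stage name and the
    offending clone/pair identifier.
    """
    clone_summary = pd.DataFrame()
    if inputs.cells is not None and len(inputs.cells):
        try:
            clone_summary = summarize_clones(
                inputs.cells,
                threshold_deg=config.phi_sd_threshold_deg,
                cell_radius_um=config.cell_radius_um)
        except Exception as exc:
            raise RuntimeError(f"clone_morphology stage failed: {exc}") \
                from exc
    else:
        logger.warning("no cell table supplied; clone stage skipped")

    pivot_long = pd.DataFrame(columns=["pair_id", "t_h", "omega_deg"])
    pivot_summary = pd.DataFrame()
    if inputs.tracks:
        try:
            pivot_long, pivot_summary = summarize_tracks(
                inputs.tracks,
                complete_range=config.complete_pivot_range_deg,
                partial_range=config.partial_pivot_range_deg)
        except Exception as exc:
            raise RuntimeError(f"pivot_kinematics stage failed: {exc}") \
                from exc
    else:
        logger.warning("no tracks supplied; pivot stage skipped")

    contact_rows, junction_rows = [], []
    if inputs.stacks and inputs.frame_spec is not None:
        for track, stack in zip(inputs.tracks, inputs.stacks):
            try:
                c, j = _contact_and_junction(track, stack,
                                             inputs.frame_spec, config)
            except Exception as exc:
                raise RuntimeError(
                    f"intensity stage failed on pair "
                    f"{track.pair_id!r}: {exc}") from exc
            contact_rows.extend(c)
            junction_rows.extend(j)

    manifest = {
        "package": "chondrocolumn",
        "version": __version__,
        "condition": inputs.condition,
        "config": config.to_dict(),
        "n_cells": 0 if inputs.cells is None else int(len(inputs.cells)),
        "n_clones": int(clone_summary.shape[0]),
        "n_pairs": len(inputs.tracks),
        "numpy_version": np.__version__,
    }
    return ReportBundle(
        clone_summary=clone_summary,
        pivot_long=pivot_long,
        pivot_summary=pivot_summary,
        contact=pd.DataFrame(contact_rows,
                             columns=["pair_id", "t_h", "dip", "in_contact"]),
        junction=pd.DataFrame(junction_rows,
                              columns=["pair_id", "t_h", "f_over_fmax",
                                       "cumulative_f_over_fmax"]),
        manifest=manifest)


def run_preset(name: str, config: Optional[RunConfig] = None,
               n_pairs: int = 8, seed: Optional[int] = None,
               render: bool = True) -> ReportBundle:
    """Convenience: simulate a preset condition and analyse it."""
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    bundle = scenario_preset(name, seed=seed)
    inputs = simulate_inputs(bundle, n_pairs=n_pairs, seed=seed,
                             render=render)
    return run_pipeline(config, inputs)


def compare_conditions(a: pd.Series | np.ndarray, b,
                       test: str = "wilcoxon", seed: int = 0,
                       kind: str = "axial") -> dict:
    """Statistical comparison of one measured column between conditions.

    ``test`` is "watson_u2" for orientation columns (axial by default)
    or "wilcoxon" for scalar columns; the Wilcoxon path first runs the
    KS normality gate on each sample and reports its recommendation.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if test == "watson_u2":
        res = watson_u2(AngleSample(tuple(x), kind=kind),
                        AngleSample(tuple(y), kind=kind), seed=seed)
        return {"test": res.method, "statistic": res.statistic,
                "p_value": res.p_value, "n1": res.n1, "n2": res.n2}
    if test == "wilcoxon":
        gates = []
        for s in (x, y):
            if len(s) >= 5:
                gates.append(ks_normality(s).recommendation)
        res = wilcoxon_rank_sum(x, y)
        return {"test": res.method, "statistic": res.statistic,
                "p_value": res.p_value, "n1": res.n1, "n2": res.n2,
                "normality_gate": gates}
    raise ValueError(f"unknown test {test!r}")
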