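"""Synthetic-tissue generator: determinism, ground-truth structure,
frame rendering, and colocalization channels."""

import numpy as np
import pandas as pd
import pytest

from chondrocolumn import (FrameSpec, PivotScenario, TissueParams,
                           generate_coloc_pair, generate_tissue,
                           pearson_colocalization, phi_angles,
                           pivot_angle_series, render_pair_frames,
                           scenario_preset, simulate_pivot_track,
                           summarize_clones)
from chondrocolumn.synthetic import PRESET_NAMES, preset_with_seed


def test_fixed_seed_byte_identical():
    a = generate_tissue(TissueParams(n_clones=12, seed=42))
    b = generate_tissue(TissueParams(n_clones=12, seed=42))
    pd.testing.assert_frame_equal(a, b)
    ta = simulate_pivot_track(PivotScenario(noise_sd_deg=4.0, seed=9))
    tb = simulate_pivot_track(PivotScenario(noise_sd_deg=4.0, seed=9))
    assert np.array_equal(ta.p1, tb.p1) and np.array_equal(ta.p2, tb.p2)
    spec = FrameSpec(noise_sd=3.0, seed=5)
    fa = render_pair_frames(ta, spec)
    fb = render_pair_frames(tb, spec)
    assert np.array_equal(fa, fb)


def test_different_seeds_differ():
    a = generate_tissue(TissueParams(n_clones=5, seed=1))
    b = generate_tissue(TissueParams(n_clones=5, seed=2))
    assert not a.equals(b)


def test_zero_clones_rejected():
    with pytest.raises(ValueError):
        generate_tissue(TissueParams(n_clones=0))
    with pytest.raises(ValueError):
        TissueParams(orientation_spread_deg=-1.0)


def test_no_noise_degenerate_phi_exactly_zero():
    params = TissueParams(n_clones=5, orientation_spread_deg=0.0,
                          column_width=1, clone_tilt_sd_deg=0.0,
                          position_jitter_um=0.0, seed=0)
    cells = generate_tissue(params)
    assert np.allclose(phi_angles(cells), 0.0, atol=1e-12)


def test_phi_sd_converges_to_spread_in_large_clone():
    # one 200-cell clone with a fixed stack tilt away from the fold points
    params = TissueParams(n_clones=1, cells_per_clone=(200, 200),
                          orientation_spread_deg=3.0, stack_tilt_deg=30.0,
                          seed=11)
    cells = generate_tissue(params)
    sd = np.std(phi_angles(cells), ddof=1)
    assert abs(sd - 3.0) / 3.0 < 0.20


def test_proliferative_low_spread_classifies_stacked():
    summary = summarize_clones(generate_tissue(
        TissueParams(n_clones=40, orientation_spread_deg=3.0, seed=3)))
    assert (summary.arrangement == "stacked").mean() >= 0.95


def test_resting_clones_have_wide_phi_spread():
    summary = summarize_clones(generate_tissue(
        TissueParams(n_clones=40, zone="resting", seed=4)))
    assert (summary.phi_sd_deg > 12.0).mean() > 0.8


def test_clones_do_not_overlap():
    cells = generate_tissue(TissueParams(n_clones=16, seed=5))
    for _, a in cells.groupby("clone_id"):
        for _, b in cells.groupby("clone_id"):
            if a.clone_id.iloc[0] >= b.clone_id.iloc[0]:
                continue
            pa = a[["x_um", "y_um"]].to_numpy()
            pb = b[["x_um", "y_um"]].to_numpy()
            dmin = np.min(np.linalg.norm(
                pa[:, None, :] - pb[None, :, :], axis=-1))
            assert dmin > 10.0  # never closer than one cell spacing


def test_width_two_clones_mostly_multi():
    summary = summarize_clones(generate_tissue(
        TissueParams(n_clones=50, column_width=2, seed=6)))
    stacked = summary[summary.arrangement == "stacked"]
    assert (stacked.width_class == "multi").mean() >= 0.90


def test_separation_grows_distance_after_onset():
    track = simulate_pivot_track(PivotScenario(
        separates=True, separation_time_h=3.0, noise_sd_deg=0.0))
    d = np.linalg.norm(track.p2 - track.p1, axis=1)
    before = d[track.t_h <= 3.0]
    after = d[track.t_h > 3.0]
    assert np.allclose(before, before[0])
    assert np.all(np.diff(after) > 0)


def test_noisy_pivot_recovered_across_seeds():
    finals = [pivot_angle_series(simulate_pivot_track(PivotScenario(
        final_pivot_deg=50.0, noise_sd_deg=3.0, seed=s))).final_omega_deg
        for s in range(20)]
    assert abs(np.mean(finals) - 50.0) <= 5.0


# --- frame rendering -------------------------------------------------------

def test_uniform_bridge_gives_flat_center_line(quiet_frame_spec):
    from chondrocolumn import contact_statistic, polyline_profile, \
        track_pixel_coords
    spec = quiet_frame_spec
    spec = FrameSpec(bridge_level=spec.cell_level, noise_sd=0.0)
    track = simulate_pivot_track(PivotScenario(noise_sd_deg=0.0))
    stack = render_pair_frames(track, spec)
    px = track_pixel_coords(track, spec)
    prof = polyline_profile(stack[0], [px[0, 0], px[0, 1]])
    call = contact_statistic(prof)
    assert call.dip == pytest.approx(0.0, abs=1e-9)


def test_separated_bodies_background_gap():
    from chondrocolumn import contact_statistic, polyline_profile, \
        track_pixel_coords
    spec = FrameSpec(image_size_px=(160, 160), background_level=0.0,
                     noise_sd=0.0)
    track = simulate_pivot_track(PivotScenario(
        separates=True, separation_time_h=1.0, noise_sd_deg=0.0,
        separation_rate_um_per_h=2.5))
    stack = render_pair_frames(track, spec)
    px = track_pixel_coords(track, spec)
    i = len(track) - 1
    prof = polyline_profile(stack[i], [px[i, 0], px[i, 1]])
    call = contact_statistic(prof)
    assert call.dip == pytest.approx(1.0, abs=1e-6)
    assert not call.in_contact


def test_total_intensity_matches_analytic_sum():
    """Bodies tangent (d = 2r): closed-form region areas predict the sum."""
    spec = FrameSpec(image_size_px=(160, 160), pixel_size_um=0.25,
                     noise_sd=0.0)
    track = simulate_pivot_track(PivotScenario(noise_sd_deg=0.0))
    stack = render_pair_frames(track, spec)
    r = spec.cell_radius_um / spec.pixel_size_um
    d = 8.0 / spec.pixel_size_um
    a_union = 2 * np.pi * r ** 2            # tangent disks
    a_interior = 2 * r * d - np.pi * r ** 2  # stadium minus the disks
    h, w = spec.image_size_px
    a_bg = h * w - a_union - a_interior
    expected = (spec.cell_level * a_union
                + spec.bridge_level * a_interior
                + spec.background_level * a_bg)
    assert stack[0].sum() == pytest.approx(expected, rel=0.03)


def test_bodies_outside_frame_rejected():
    spec = FrameSpec(image_size_px=(24, 24))
    track = simulate_pivot_track(PivotScenario(noise_sd_deg=0.0))
    with pytest.raises(ValueError, match="outside"):
        render_pair_frames(track, spec)


def test_junction_band_raises_junctional_fraction():
    from chondrocolumn import junctional_fraction, track_pixel_coords
    from chondrocolumn.pipeline import _junction_band_polygon
    track = simulate_pivot_track(PivotScenario(noise_sd_deg=0.0))
    with_band = FrameSpec(junction_level=200.0, noise_sd=0.0)
    no_band = FrameSpec(junction_level=0.0, noise_sd=0.0)
    px = track_pixel_coords(track, with_band)
    r_px = with_band.cell_radius_um / with_band.pixel_size_um
    hw_px = with_band.junction_halfwidth_um / with_band.pixel_size_um
    jreg = _junction_band_polygon(px[0, 0], px[0, 1], hw_px, r_px)
    from shapely.geometry import LineString
    pair = np.array(LineString([tuple(px[0, 0]), tuple(px[0, 1])])
                    .buffer(1.3 * r_px).exterior.coords)
    m1 = junctional_fraction(render_pair_frames(track, with_band)[0],
                             jreg, pair)
    m0 = junctional_fraction(render_pair_frames(track, no_band)[0],
                             jreg, pair)
    assert m1.ratio > m0.ratio


# --- colocalization channels ----------------------------------------------

@pytest.mark.parametrize("target", [1.0, -1.0])
def test_coloc_extremes_exact(target):
    ch1, ch2 = generate_coloc_pair(target, 2000, seed=0)
    assert pearson_colocalization(ch1, ch2).r == pytest.approx(
        target, abs=1e-12)


def test_coloc_converges_to_target():
    ch1, ch2 = generate_coloc_pair(0.5, 100_000, seed=1)
    assert pearson_colocalization(ch1, ch2).r == pytest.approx(0.5, abs=0.02)


def test_coloc_target_out_of_range():
    with pytest.raises(ValueError):
        generate_coloc_pair(1.5, 100, seed=0)


# --- presets ----------------------------------------------------------------

def test_presets_exist_and_unknown_rejected():
    for name in PRESET_NAMES:
        bundle = scenario_preset(name, seed=3)
        assert bundle.name == name
    with pytest.raises(ValueError, match="unknown preset"):
        scenario_preset("nonsense")


def test_preset_reseeding():
    b = scenario_preset("wild_type", seed=0)
    b2 = preset_with_seed(b, 7)
    assert b2.tissue.seed == 7 and b2.pivot.seed == 7 and b2.frame.seed == 7
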