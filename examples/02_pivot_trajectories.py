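"""Track sister-cell pivot angles omega(t) and classify the outcome.

Simulates a wild-type-like pivot (mediolateral division, ~85 deg
rotation over ten hours) and a separating pair whose pivot aborts, then
computes the normalized omega series for each.
"""

from chondrocolumn import (PivotScenario, classify_pivot,
                           division_orientation, pivot_angle_series,
                           simulate_pivot_track)

for label, scenario in [
    ("full pivot", PivotScenario(final_pivot_deg=85.0, noise_sd_deg=3.0,
                                 seed=2)),
    ("separating", PivotScenario(final_pivot_deg=85.0, noise_sd_deg=3.0,
                                 separates=True, separation_time_h=3.0,
                                 seed=2)),
]:
    track = simulate_pivot_track(scenario)
    series = pivot_angle_series(track)
    cls = classify_pivot(series)
    print(f"{label}: division at "
          f"{division_orientation(track):5.1f} deg from ML axis, "
          f"final omega {series.final_omega_deg:6.1f} deg -> {cls}")
    print("   omega(t):", " ".join(f"{w:6.1f}" for w in series.omega_deg))

# A complete pivot plateaus in the 70-100 deg band (one sister rotated
# around the other into a proximodistal stack); separation freezes the
# angle mid-course, so no complete pivot is called.
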