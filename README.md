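# chondrocolumn

Quantitative analysis of clonal architecture and cell rearrangement in
growth-plate cartilage.

During long-bone elongation, proliferative chondrocytes divide roughly
orthogonal to the proximodistal (PD) axis and then rearrange — one
sister cell pivots around the other — so that clones stack into PD-
oriented columns. This package implements the measurement pipeline for
that process, for developmental biologists quantifying multicolor
clonal-labeling and live-imaging experiments:

- **Clone morphology** — Φ, the axial angle between each cell's minor
  axis and the PD axis, folded to [0°, 90°]; clones with within-clone
  SD(Φ) ≤ 12° are *stacked*, otherwise *arbitrary*. For stacked clones,
  θ (the angle of the segment from the topmost cell to each other cell
  vs the PD axis) with SD(θ) ≤ 12° distinguishes *single* from *multi*
  columns; the clone outline's major principal axis (second central
  area moments of the radius-expanded convex hull) gives the column
  orientation.
- **Pivot kinematics** — ω(t), the angle of the undirected sister-cell
  axis to the mediolateral axis, ω = atan2(Δy, Δx) on a half-turn,
  unwrapped over time and normalized to 0° at the first observation.
  Complete pivots plateau in [70°, 100°], partial in [30°, 70°).
- **Intensity dynamics** — polyline kymograph F/Fmax profiles between
  sister nuclei with a contact "dip" statistic; junctional/total
  intensity ratios; junctional F/Fmax time courses; Pearson
  colocalization between channels.
- **Statistics** — Watson's U² two-sample test for orientations (axial
  data doubled to the circle; seeded permutation/enumeration null),
  Wilcoxon rank-sum, and a one-sample KS normality gate.
- **Synthetic tissue** — a generator for cell tables, pivot tracks, and
  rendered two-cell frames with known ground truth, including presets
  for wild-type and perturbation phenotypes (`wild_type`, `pcp_loss`,
  `pcp_gain`, `ncad_block`).

## Worked example

```python
from chondrocolumn import (TissueParams, generate_tissue,
                           summarize_clones, PivotScenario,
                           simulate_pivot_track, pivot_angle_series,
                           classify_pivot)

cells = generate_tissue(TissueParams(n_clones=30, seed=1))
summary = summarize_clones(cells)
print(f"stacked fraction {(summary.arrangement == 'stacked').mean():.2f}, "
      f"mean within-clone SD(phi) {summary.phi_sd_deg.mean():.1f} deg")

track = simulate_pivot_track(PivotScenario(final_pivot_deg=85.0,
                                           noise_sd_deg=3.0, seed=2))
series = pivot_angle_series(track)
print(f"final omega {series.final_omega_deg:.1f} deg "
      f"-> {classify_pivot(series)}")
```

prints

```
stacked fraction 1.00, mean within-clone SD(phi) 2.6 deg
final omega 85.1 deg -> complete
```

Every proliferative clone stacks (its cells' minor axes deviate from
the PD axis by a common tilt with only ~3° of within-clone spread), and
the simulated sister pair pivots by ~85°, inside the 70–100° band that
defines a complete pivot into a single column. The `examples/`
directory has one short script per capability; a thin CLI
(`chondrocolumn simulate|classify-clones|pivot|kymograph|coloc|compare|report`)
wraps the same functions for shell use.

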