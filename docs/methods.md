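# Methods

## Coordinate conventions

All geometry is 2D, in the section/imaging plane. The tissue frame is
micrometres with the proximodistal (PD) axis along +y and the
mediolateral (ML) axis along +x; the image frame is pixels with origin
top-left and y downward, converted via `pixel_size_um` with y negated.
Interfaces exchange degrees; internals use radians. Cell and clone
orientations are *axial* quantities (a direction and its opposite are
the same measurement): they live on a half-turn and are folded to
[0°, 90°] against a reference axis. The pivot angle ω is also measured
on a half-turn but is *unwrapped* over time so cumulative rotations
past 90° are preserved.

## Clone morphology

Φ is the axial angle between a cell's minor axis (supplied as a vector
in the cell table; no ellipse fitting is performed here) and the PD
axis. A clone is classified from the sample SD of Φ over its cells
(n−1 denominator — clones are small, so the unbiased estimator
matters): stacked iff SD(Φ) ≤ 12°, the threshold used throughout the
field for this assay; classification requires more than two cells.
Equality at the threshold counts toward the stacked/single class.

θ is measured from the topmost cell — maximal PD coordinate, i.e. the
largest projection onto the PD axis, with ties broken by smaller ML
coordinate and then by cell id for determinism — as the axial angle of
each topmost→cell segment to the PD axis. The segment reading (rather
than an orientation difference between cells) matches how the
measurement is drawn in practice: lines from the top cell to each
neighbour. SD(θ) ≤ 12° calls a single column; a clone contributing only
one θ (two cells) is classed single by convention and flagged
low-confidence.

The clone outline is the convex hull of centroids buffered by the cell
radius (default 5 µm, configurable) — a proxy for a hand-drawn border
that is well defined even for collinear or two-cell clones. Column
orientation is the axial angle between the outline's major principal
axis (from the second central area moments, computed by Green's-theorem
formulas over the exterior ring) and the PD axis. A (near-)isotropic
outline, with moment anisotropy below 1e-3 of the moment sum, has no
major axis; orientation is reported as 0° and flagged undefined. Zone
summaries of Φ are emitted both pooled across cells and averaged per
clone, since either convention is defensible and they differ slightly.

## Pivot kinematics

ω is the two-argument arctangent of (Δy, Δx) between sister centroids,
reduced to [0°, 180°). Series are unwrapped by choosing, at each step,
the representative of the raw change (mod 180°) with the smallest
magnitude, so |Δω| ≤ 90° per step; a step of exactly 90° is
directionally ambiguous and is resolved toward the smaller cumulative
excursion from the starting value, with a flag. The normalized series
subtracts the first unwrapped value (the division orientation at the
first observation), so it starts at exactly 0°.

The final pivot angle is a plateau estimate: the mean of the last
quartile of samples (the published trajectories plateau well before the
end of the recording). With fewer than four samples the last sample is
used and flagged. Classification by |final ω|: complete in [70°, 100°]
(the empirical band for pivots into single columns), partial in
[30°, 70°) (anchored to the observed ~50° partial pivot), none
otherwise; both bands are config-exposed.

## Intensity measurements

Profiles are sampled along a polyline at half-pixel steps with bilinear
interpolation, averaged across a perpendicular band (`width_px`
parallel lines at 1 px spacing), and normalized by the line maximum
(F/Fmax). The contact statistic takes the central 50% of the path
(excluding the bright nuclear endpoints), and reports
dip = 1 − min F/Fmax; pairs are called in contact while dip ≤ 0.5.
"Flat" vs "inverted bell" is not quantified in the assay this
operationalizes, so the dip threshold and interior fraction are this
package's choices, exposed in `RunConfig`; on rendered ground truth the
two classes separate by a wide margin (dip ≈ 0.2–0.35 vs ≈ 0.9), so the
call is insensitive to the exact threshold.

Junctional fractions subtract a background estimated as the median
intensity outside the pair region (the assay itself does not state its
background handling), then divide summed junctional by summed pair
intensity. The junctional time course divides per-time junctional
intensity by its maximum over the course; because "cumulative F/Fmax"
admits two readings, the per-time series is primary and a running sum
is additionally emitted. Pearson colocalization is the standard
product-moment coefficient over masked pixels; a constant channel makes
it undefined and is flagged rather than returned as 0.

All intensity statistics are invariant to a positive gain.

## Statistics

Watson's U² = (n₁n₂/N²)·Σₖ(dₖ − d̄)², with dₖ the difference of
empirical cumulative fractions at the k-th pooled point; the mean
centering makes the statistic invariant to the circle's cut point.
Axial samples are doubled (2θ mod 360°) before testing, the standard
treatment for orientation data. Significance comes from relabeling the
pooled sample: exhaustive enumeration of all C(N, n₁) splits when that
count is ≤ 50 000 (exact p), otherwise seeded random permutations with
the add-one correction. Ties are handled by holding the cumulative
difference constant within a tied group (midrank-style) and flagged.
The permutation p-value is discrete at clone-level sample sizes, hence
super-uniform (conservative) under the null rather than exactly
uniform; the tests check validity (never anti-conservative) and the
type-I error at α = 0.05.

Wilcoxon rank-sum and the one-sample KS test delegate to scipy.stats
(`mannwhitneyu` with exact small-sample p-values when there are no
ties; `kstest` against a normal law with the sample's own mean and SD).
The KS gate's parameters are estimated from the sample, which makes it
conservative (Lilliefors caveat); this is flagged in the result rather
than corrected, and its `recommendation` field selects the
nonparametric path.

## Synthetic tissue generator

The generator produces the statistical structure the analysis assumes,
not photorealistic microscopy: no PSF, z-stacks, or tissue mechanics.

**Cell tables.** Clones sit on a coarse grid with pitch exceeding the
worst-case clone extent, so clones never overlap. A proliferative clone
draws a stack tilt from N(0, `clone_tilt_sd_deg`) (default 15°) and
stacks its cells along that axis in `column_width` parallel columns at
`cell_spacing_um` (default 10 µm, about one cell diameter); each cell's
minor-axis angle is the stack tilt plus N(0, `orientation_spread_deg`)
noise (default 3°, the observed within-clone spread). The two-scale
model is deliberate: a single spread parameter cannot produce both the
~3° within-clone SD and the ~12° zone-level mean Φ that characterize
proliferative tissue; a 15° tilt SD gives a folded-normal mean cell
obliquity of ≈ 12°. Resting clones are loose non-overlapping clusters
with minor-axis angles uniform on the half-turn (mean Φ ≈ 45°).
Multi-column ensembles used for orientation summaries get a wider tilt
SD (28°), reflecting the weaker PD alignment of laterally intercalated
stacks (folded mean ≈ 22°). Half-degree positional jitter is added for
realism.

**Pivot tracks.** The sister-axis angle follows a smoothstep ramp from
the (optionally jittered) division angle by `final_pivot_deg` over the
first `rise_fraction` (default 0.75) of the time course, then holds —
so the last-quartile plateau estimator recovers the programmed final
angle exactly in the noise-free case. Angular noise is additive
Gaussian per sample; no quantitative jitter model exists for the real
trajectories, so its magnitude (3–5°) is a free parameter. With
`separates`, the angle freezes at `separation_time_h` and the
inter-cell distance grows at 1.5 µm/h. Default sampling matches the
live-imaging cadence: one frame per hour for 10 h.

**Frames.** Cell bodies are uniform disks (ellipticity matters only for
orientation, which the cell table carries as a vector); the region
within one radius of the inter-cell segment but outside both bodies is
a cytoplasmic bridge while the centers are within ~2 radii, background
after separation. An optional thin junction band crosses the interface
midline, scaled per frame by an exponential decay profile (half-life
5 h in the decaying preset); the residual band tracks the midpoint so
decay and separation can be modelled independently. Additive Gaussian
noise completes the frame.

**Presets.** `wild_type`: mediolateral division (±10° jitter), full 85°
pivot, persistent bridge and junction. `pcp_loss`: stacked clones with
uniformly random stack tilt, random division angle, full pivot.
`pcp_gain`: 30° orientation spread (arbitrary clones), random division
angle, separation at 3 h aborting the pivot, junction half-life 5 h.
`ncad_block`: mediolateral division but separation at 3 h, no junction
channel imaged. Seeds are mandatory arguments everywhere; a fixed seed
reproduces outputs byte-identically.

What passing tests on this generator show — and what they do not: the
pipeline recovers the parameters and orderings it was pointed at under
a known noise model; real micrographs add segmentation error,
out-of-plane motion, uneven illumination, and tracking failures that
the generator does not emulate, so recovery rates here are upper
bounds.

## Problem sizes and numerical choices

Classification-recovery experiments use 200 clones of 10–18 cells
(typical proliferative column sizes; SD estimates over fewer than ~8
cells are too noisy for reliable threshold classification, which is
also why the assay requires clones of more than two cells). Pivot
ensembles use 50 seeds; contact ensembles 20 seeds per condition;
type-I calibration 500 replicates of an exact-enumeration test at
n = 8 + 8. Degenerate inputs fail loudly and specifically: zero-length
axes, coincident sisters, empty interiors, constant channels, and
all-zero profiles are rejected or flagged rather than silently coerced.
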