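# Methods

## The cylinder model and the leaf elevation index

A rosette plant is idealized as a cylinder of radius *r* and height *h*.
As leaves elevate, the projected rosette shrinks and the apex rises, so the
angle

LEI = arctan(*h* / *r*) · 180/π   (degrees, in [0, 90))

tracks the leaf elevation status of the *whole plant* without identifying,
tracking or measuring any individual leaf. LEI is a proxy statistic, not a
leaf angle: two useful identities are that LEI is strictly increasing in
*h* and decreasing in *r*, and that LEI(h, r) + LEI(r, h) = 90°.

*r* comes from the top view: the binary silhouette is summarized by its
**equal-moment ellipse** (the ellipse whose second-order central moments
match the mask's; full axes are 4·√eigenvalue of the pixel-coordinate
covariance). Because real rosettes are not round, the mean of the major and
minor axes is used as the diameter, so r = (major + minor)/4. The moment
ellipse was chosen over a contour-based fit because it is deterministic,
needs no contour extraction or least-squares step, and reproduces a filled
disc's diameter exactly.

*h* comes from the side view: the distance in rows from a configured soil
reference row (`line_position`) up to the highest plant pixel. Pixels at or
below the soil line are ignored by default (`clip_below_line=True`) so pot
rim and soil reflections cannot contribute. The highest-pixel rule (rather
than a bounding-box property) was adopted because it is monotone — adding
plant material above the current top can only increase height — and is
insensitive to how the silhouette fragments into leaves.

Pixel values are converted to millimetres by per-camera factors
(`mm_per_px_top`, `mm_per_px_side`), obtained once by photographing a length
standard (`calibrate(px, mm) = mm/px`). Both factors must be strictly
positive and finite.

## Segmentation

Plant pixels are separated from the dark background by thresholding the
excess-green index ExG = 2G − R − B on [0,1]-scaled channels (range
[−2, 2]): a pure green pixel scores 2, any gray 0. The index is clipped at
`max_value` before comparison with `threshold`. The index function is
pluggable; ExG is the default because it is the standard choice for green
vegetation on soil and needs no training or per-frame adaptation.

Cleanup: everything outside the optional ROI rectangle is discarded,
interior holes are filled, and 8-connected components with area <
`size` px are removed. *All* surviving components are kept — in side view a
rosette legitimately fragments into separate leaves, and keeping only the
largest component would bias the height toward the tallest single leaf
cluster. Hole filling treats background as 4-connected (the standard dual of
8-connected foreground). Cleanup is idempotent, and raising the threshold
can only shrink the mask.

Parameters are per-series constants tuned once on exemplary frames, not
auto-estimated per image: time-lapse chambers have constant illumination,
and a fixed threshold keeps measurements comparable across the series.
Defaults (`threshold=0.3`, `max_value=2.0`, `size=50`) segment the synthetic
scenes exactly at zero noise and tolerate Gaussian channel noise up to
sd ≈ 0.05 with sub-degree LEI error.

## Time-course assembly and aggregation

Frames are paired by (plant, time point); a pair missing either view yields
a logged warning and no record, never an exception mid-batch. Capture jitter
within ±10% of the sampling interval (default 30 min) is snapped to the
grid; frames further off are flagged and excluded from pairing. Duplicate
(plant, view, time) claims are an error naming both files.

Group trajectories: per time point, the mean LEI over the plants present and
SEM = sample sd (n−1 denominator) / √n. With a single plant at a time point
the SEM is reported as 0 and the course is flagged (`n1_sem`) rather than
erroring. The **group mean** is then shifted by its value at the treatment
onset time point, so mean ΔLEI(onset) = 0 exactly; normalization is
shift-invariant and idempotent. Per-plant normalization (each plant shifted
by its own onset value before averaging) is available as an option; it also
pins the onset mean at 0 but collapses the onset SEM. The onset reference is
the single onset frame, not an average of pre-onset frames. Plants may drop
out of individual time points (corrupt frames); n is reported per time point.

## Synthetic scenes and response simulation

The generator renders what the cylinder model assumes, with exact closed-form
truth. Given leaf length L, elevation angle θ and top-silhouette
minor/major ratio e:

- top view: filled ellipse with semi-axes L·cosθ and e·L·cosθ (mm);
- side view: filled isoceles triangle with apex L·sinθ above the soil row
  and half-base L·cosθ; nothing is drawn at or below the soil row. Only the
  apex enters the height measurement, so the triangle shape is a
  segmentation workload, not a bias.
- truth: r = L·cosθ·(1+e)/2, h = L·sinθ, and lei_true always evaluated
  through the LEI formula itself — with e = 1, lei_true = θ identically;
  with e < 1 the two deliberately differ.

Silhouettes are hard-edged by default so pixel-count oracles are exact
(optional soft edges for robustness tests); a silhouette that would exceed
its frame raises an error rather than clipping silently. Apex placement
rounds to the nearest row, bounding the height error at half a pixel.

Simulated trajectories follow

LEI_i(t) = baseline + b_i + A·σ(k·(s − t50))·D(s) + osc·sin(2πt/period) + ε_it

with s = t − onset, σ the logistic function, D(s) an exponential decay
applied after `decay.start` (else 1), b_i ~ N(0, plant_sd²) a stable
between-plant offset, ε ~ N(0, frame_sd²) frame jitter; values are clipped
to [0, 89]°. One seed drives all randomness; identical seeds give
bit-identical truth tables.

Default study conditions mirror a small-chamber time course: 3 plants per
group, 36 h at 30-min intervals (73 time points), leaf length 20 mm,
0.2 mm/px from 256×256 frames, soil row 220. Preset models encode the
qualitative genotype contrasts (numbers are fixtures for that ordering, not
measured values): `wt_low` rises ~25° reaching its maximum about 10 h after
onset and persists; `wt_high` does not respond (2° circadian oscillation,
24-h period, only); `pif4pif5_low` rises more slowly (max ~15 h) and less
(~12°); `pif7_low` rises at the wild-type rate but decays back to baseline
by ~20 h (decay start 10 h, τ ≈ 4.7 h). Between-plant sd defaults to 2°,
frame sd to 1°.

What the generator does **not** emulate: leaf-level 3D structure, petiole
vs blade geometry, occlusion, growth over the series, specular highlights,
shadows, or nonstationary illumination. Passing the synthetic benchmarks
therefore demonstrates correctness of the measurement chain under the
cylinder model's own assumptions, not segmentation robustness on field
photographs.

## Numerical choices

- Image convention: row 0 at the top, rows increase downward; pixel centers
  at integer coordinates; half-open intervals for ROI cropping.
- Ellipse orientation: angle of the major axis vs the column axis,
  counter-clockwise with y up, wrapped to (−π/2, π/2]. A collinear mask has
  minor axis 0 and is flagged degenerate (still usable: the radius rule only
  needs major + minor); a mask with both axes 0 aborts that record only.
- Moments are computed by vectorized sums over pixel coordinates; agreement
  with a naive double loop is maintained to 1e-9 on masks up to 200×200.
- Empty segmentation results are flagged, not raised, so batch analysis
  skips the time point and continues.
- Timestamp snapping tolerance: 10% of the sampling interval.
- SEM at n = 1 reports 0 with a flag (an honest "no spread information"
  marker that keeps the table rectangular).

## Problem sizes used in checks

The shipped verification suite uses: 50 random masks up to 200×200 for the
moment oracle; 10 shape sizes (15–60 px semi-axis) × 5 rotations for axis
recovery; elevation angles 10–80° × eccentricities {0.8, 1.0} with noise
sd 0 and 0.05 for end-to-end recovery; and two full simulate→analyze round
trips (3 plants × 73 time points × 2 views per preset). These sizes give
stable worst-case errors while keeping a complete run in well under a
minute on one CPU.

## Known limitations

- The ExG threshold assumes a green plant on a dark, low-green background;
  anthocyanin-rich or chlorotic tissue and green-tinged backgrounds need a
  different index (the index function is pluggable).
- LEI conflates leaf elevation with rosette compaction: any process that
  shrinks the projected rosette at constant height raises LEI.
- Height uses the single highest pixel, so a single mis-segmented bright
  pixel above the plant inflates h; the `size` filter is the main guard.
- The soil line is a per-camera constant; pot settling or soil-level drift
  over long series is not tracked.
- No significance testing between groups is performed; the output is the
  normalized trajectory table.
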