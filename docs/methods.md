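# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs.

## Synthetic phantom clips

**What is emulated.** A clinical SWE export is a multiframe RGB DICOM: a
greyscale B-mode stack at 11 Hz with a colour elastogram overlay that
updates at the elastography sampling rate (1.2–2.0 Hz), so each elastogram
is repeated over ~5–9 consecutive frames. The generator reproduces exactly
this structure: `round(duration × 11)` frames; elastogram *i* covering
frame timestamps in the half-open window `[i/rate, (i+1)/rate)` (a 1e-9
guard absorbs binary floating-point jitter at tick boundaries); void
(no-estimate) pixels rendered zero-chroma so the B-mode shows through;
saturated pixels (field > 9.9 m/s) painted with the top colour of the
scale. Durations are restricted to the two protocol lengths, 20 s and 30 s.

**Ground-truth fields.** Three field kinds: constant, a linear
top-to-bottom gradient (depth dependence), and a rectangular stiff/soft
patch. The void pattern is drawn afresh for every elastogram from smoothed
Gaussian noise thresholded at exactly the requested fraction — real
shear-wave tracking dropouts vary over time — which also keeps consecutive
elastograms pixel-distinct even without velocity noise. Saturation is a
static patch (over-range tissue stays over-range). Velocity noise
(default SD 0.05 m/s, a conservative estimate of frame-to-frame
measurement jitter) is redrawn per elastogram and clipped away from the
saturation threshold so noise never flips a saturation flag.

**What is not emulated.** No acoustics, speckle decorrelation, probe
motion, depth-dependent attenuation, or vendor post-processing. Passing
the phantom tests therefore demonstrates that the *extraction and
statistics* are correct, not that the decoder is robust to every artefact
of real clips.

**Geometry defaults.** 96×176 px frames at 0.2 mm/px with the overlay at
rows [20, 76), cols [14, 160) — an 11.2 × 29.2 mm elastogram, comfortably
holding the 2×7 grid of 4 mm squares below the 1 mm discard strip while
keeping a 20-s clip around 11 MB in memory.

**Ground truth is returned, never re-derived:** the generator hands back
the exact field, per-elastogram validity/saturation masks, and the
frame→elastogram index, so every downstream test has an oracle that is
independent of the code under test.

## Colour scale

The vendor's LUT is unpublished. The package ships a default ramp of 256
control points (deep blue → cyan → green → yellow → dark red) spanning
[0, 10) m/s, arc-length parameterised in RGB so consecutive entries stay
well separated, verified pairwise distinct, minimum chroma 140. The
quantisation step is 10/256 ≈ 0.039 m/s; encode+decode round-trips are
therefore exact to within half a step (≈0.02 m/s) by construction. Any
table of ≥2 (colour, velocity) control points can be substituted, e.g. one
sampled from a device's on-screen colour bar; an `unblend` option inverts
a stated alpha blend over a stated background before lookup for exports
that store the composited screen.

Decoding maps each coloured pixel (chroma = max(R,G,B)−min(R,G,B) above 8)
to its nearest control point in RGB, refined by projecting onto the
segment towards the nearer neighbouring control point with linear velocity
interpolation. Grey pixels are void; decoded velocities above 9.9 m/s are
flagged saturated.

## Overlay detection and deduplication

The overlay box is the bounding box of pixels exceeding the chroma
threshold in at least one frame; among several connected candidates the
largest by area wins, and the box is held constant for the clip (the
transducer is strapped in place). Deduplication collapses consecutive
frames with identical overlay pixels; with a constant, void-free,
noise-free phantom consecutive elastograms are genuinely indistinguishable
and the count collapses to 1 — with any void or noise, the deduped count
equals the embedded count.

## Grid metrics and quality control

Conventions (row-major, origin top-left, 0-based, half-open): the top
`ceil(1 mm / row spacing)` rows are discarded (never keep artefact strip);
squares are `round(4 mm / spacing)` px per side, tiled 7 columns × 2 rows
(A above B) from the top-left of the retained region (`anchor="center"`
centres the grid horizontally); leftover margins are unused. Statistics
per square: max, mean, median, SD (n−1 denominator; defined as 0 for a
single pixel), IQR with linear-interpolation quantiles, % coloured pixels,
saturation count/%. Saturated pixels stay in the statistics — saturation
is reported, not filtered. QC cutoffs are read literally: "less than 50%"
excludes strictly below 50.0%; "more than 50% of the squares" discards at
8+ of 14 excluded squares (7/14 retains).

## Aggregation

Trial value = median over squares of the per-square temporal medians
(computed over QC-retained elastograms in which the square was included).
Repetitions collapse by median (mean by configuration) — robust and
consistent with the nonparametric analysis; a missing/invalid repetition
is simply dropped, and zero valid repetitions propagate a missing value.
The activation ratio is oriented single-leg-stance / baseline, so values
above 1 mean stiffness rises with activation; a direction flag yields the
reciprocal. Group-level ratio medians are medians of per-participant
ratios, not ratios of group medians.

## Statistics

* **Kruskal–Wallis**: tie-corrected H, chi-square approximation with k−1
  df (scipy); completely identical data short-circuit to H = 0, p = 1. An
  exact mode enumerates all assignments of pooled values to the group
  sizes (practical to total n ≈ 12) for small-sample checks.
* **Pairwise Wilcoxon rank-sum**: rank sum W of the first group, normal
  approximation with tie-corrected variance and no continuity correction
  (the "asymptotic" convention of R's coin package); run only after a
  significant omnibus test (strict p < 0.05). No multiplicity adjustment
  by default, matching the analysis plan; Bonferroni and Holm are opt-in.
* **Spearman**: average ranks for ties, asymptotic p, complete-case pairs.
  Bands on |ρ|: > 0.75 good-to-excellent; 0.50–0.75 moderate-to-good
  (0.50 and 0.75 included); 0.25–0.50 fair (0.25 included); below 0.25
  none.
* **ICC**: the two-way, absolute-agreement, average-of-k estimator
  `(MSR − MSE) / (MSR + (MSC − MSE)/n)` — the quantity SPSS reports under
  "two-way mixed, absolute agreement, average measures", despite the
  naming clash with the Shrout–Fleiss "(3,k)" consistency label; the model
  string in the result records the exact formula and a `consistency`
  variant is available. CI per McGraw & Wong (F-based with Satterthwaite
  df), cross-checked against pingouin. SEM = pooled SD × √(1 − ICC) with
  pooled SD = √(mean within-repetition between-subject variance).
* **Power**: ANOVA — smallest total N with noncentral-F power
  (λ = f²N, df 2 and N−3) ≥ 0.80. Wilcoxon–Mann–Whitney — the Pitman-ARE
  method for normal parents: two-sided noncentral-t power of the
  two-sample t-test evaluated at the *effective* sample size N·(3/π)
  (fractional df), searching the smallest even N; with ARE = 1 this
  degenerates to the exact t-test sample size. The naive alternative
  (inflate the final t-test N by π/3) overshoots by one even step and
  does not reproduce standard software output.

## Simulated cohort

Trial values are condition medians (defaults: the package's reference
median table for gastrocnemius medialis and vastus lateralis across the
four tasks and both planes) plus a per-participant offset
(between-subject SD 0.25 m/s) plus trial noise (within-subject SD
0.15 m/s, chosen to sit between the simulated SEMs and the observed
condition IQRs of resting muscle), truncated at 0.05 m/s. Group sizes
default to 21/21/20 with matched muscle assignment across groups;
baseline is recorded once, every other task three times, in both planes —
20 trials per participant, 1240 for 62 participants. Questionnaire tables
draw KOOS subscores, the S6+S7 perceived-stiffness items, TSK, age and
BMI from per-group normal profiles clipped to instrument ranges.

The additive-Gaussian model has no skew, floor/ceiling effects, missing
clips, or task-dependent variance heterogeneity; it validates plumbing and
statistical calibration, not distributional realism.

## Problem sizes in the test suite

The property suite runs phantoms at 20 s / 1.2 Hz (24 elastograms) where a
full clip is needed, enumeration oracles at total n ≤ 10, type-I-error
calibration over 2,000 null simulations, ICC recovery at n = 200 and CI
coverage over 500 simulations at n = 30, and the end-to-end recovery on a
scaled cohort (1 participant per group, one muscle, baseline + single-leg
stance, both planes, 24 clips). The end-to-end check asserts exact
equality with the LUT-quantised seeded median — the strongest statement an
8-bit colour channel permits — plus closeness within half a quantisation
step of the continuous value.

## Known limitations

Decoding real vendor exports requires LUT calibration from the on-screen
colour bar (sample the bar's pixels, pair them with its axis labels, pass
them as control points; invert the stated overlay opacity via `unblend`).
The overlay box is assumed static per clip; moving-probe recordings are
out of scope, as are adaptive ROIs following muscle contours, speckle
tracking and motion compensation. The effective elastography rate of real
devices can vary within a clip (long clips may hold fewer elastograms
than duration × nominal rate); the generator uses a constant rate.
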