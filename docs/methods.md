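# Methods

`glycovivo` quantifies three read-outs of endothelial glycocalyx (GCX)
integrity from intravital fluorescence microscopy of skin microvessels
observed through a dorsal skinfold chamber, together with the statistical
policy used to compare scheduled time points, and a synthetic-data generator
that provides ground truth for every stage.

## Thickness index (TI)

The GCX is visualised as a bright band along the vessel wall after
intravenous FITC-WGA lectin.  The measurement operates on an oriented
rectangular ROI, by default 40 x 200 px, placed manually over one wall with
the 200-px long axis following the flow direction.  With `Imax` and `Imin`
the extreme gray levels inside the ROI, the threshold is

    Th = F * (Imax - Imin) + Imin,      F = 0.7 by default.

Pixels at or above `Th` are taken as the GCX band; the count divided by the
200-px axis length is the mean band thickness in pixels (`ti_px`), converted
to micrometres through the pixel calibration (default 0.377 um/px, i.e. a
200-px axis spans 75.4 um).  `ti_um` is the headline unit.

Numerical choices:

* **Comparison convention.** `>= Th` is used (configurable to `>`); the
  binarize-then-invert phrasing of the manual protocol does not fix the tie
  side.
* **Threshold precision.** `Th` is kept unrounded; rounding to integer gray
  levels is a config option (off by default).
* **Flat ROI.** If `Imax == Imin` the ROI carries no band evidence; the
  result is flagged degenerate and TI reported as NaN rather than the full
  ROI area.
* **Resampling.** Oriented ROIs are extracted with nearest-neighbour
  sampling so the 8-bit histogram feeding `Th` is preserved; bilinear
  interpolation would smooth the extremes the formula depends on.
* **Failure mode without a band.** The F-fraction threshold assumes the
  band is the brightest structure in the ROI.  If no band exists (fully
  degraded GCX), the lumen becomes the bright class and is counted,
  overestimating TI grossly.  Wall ROIs are only meaningful on a visible
  band; the emulation therefore draws true thicknesses conditioned on a
  resolvable band (>= 0.25 um, just under one pixel at default calibration).

A documented inconsistency in the published values used as default
parameters: the accompanying description reports GCX *thinning* at 24 h
post-endotoxin while the printed TI values *rise* (arteriole 1.28 +/- 0.27
to 1.79 +/- 0.62 um).
This package defines TI as directly proportional to band thickness and uses
the printed values verbatim as generator parameters; it does not attempt to
reconcile the direction.

## Leukocyte-endothelium interactions

Cells observed for a 15-s window are classified from their tracks:

* **adhering** — maximum displacement from the starting position stays
  within `displacement_epsilon` (default 2 um, well below one cell diameter)
  over the whole window;
* **rolling** — otherwise, mean along-axis speed (net along-axis
  displacement / track duration) below `rolling_fraction` (default 0.5) of
  the free-flow reference speed, which is supplied per video because
  centreline speed varies between vessels;
* **flowing** — everything faster;
* tracks spanning less than `min_coverage` (default 0.8) of the window are
  *indeterminate*.

The human raters of the original protocol used no numeric thresholds;
`displacement_epsilon` and `rolling_fraction` make the definitions
operational and are exposed in config.  Counts are calibrated to a reference
segment of 100 um length and 100 um diameter.  The calibration phrase is
ambiguous between a length-only and a length-and-diameter correction; both
are implemented, the two-factor form `raw * (100/L) * (100/D)` is the
default, and results record which was used.

The dual-channel criterion makes the "yellow cell" merge explicit: a cell
detected in the lectin frame is tight-adherent iff a rhodamine-channel
detection captured 8 s later lies within `match_radius` (default 5 um) of
its position; otherwise transient.

## Permeability index

After intravenous TMR-labelled 75-kDa dextran, three square interstitial
ROIs (30 x 30 um, i.e. 80 px at default calibration) adjacent to the vessel
are followed every 30 min for up to 120 min.  The index of an ROI at time t
is its mean gray level minus a control value.  The control is not defined in
the source protocol; the default takes the same ROI's mean at t = 0 (making
the index identically 0 there), and an externally supplied control (e.g. a
remote background ROI) is the config alternative.  The index is invariant to
global background shifts by construction.

The across-time trend is assessed with the same one-way ANOVA policy as the
tabular endpoints (a regression slope test would be the natural alternative;
ANOVA was chosen for consistency with the global statistics policy).  When
the default t = 0 control is used, the t = 0 group is identically zero and
is dropped from the ANOVA; note that the remaining per-ROI indices share the
subtracted t = 0 term, which makes the test conservative in that
configuration.  The type-I calibration reported by the acceptance machinery
therefore uses the external-control configuration, where observations are
independent across time points.

## Group statistics

Every endpoint is summarised as mean +/- SD (n-1 denominator) per scheduled
hour and tested with a fixed-effects one-way ANOVA across hours followed by
Dunnett's two-sided many-to-one comparisons against the 0-h control at
familywise alpha = 0.05.  The ANOVA is computed by direct sum-of-squares
decomposition (the all-identical degenerate case returns F = 0, p = 1 with a
flag); Dunnett adjusted p-values come from the multivariate-t reference
distribution (`scipy.stats.dunnett`, seeded for reproducibility), which
handles unbalanced groups; with a single comparison the adjusted p is
evaluated in closed form as the pooled two-sided t-test.  Post-hoc
comparisons are run only when the global ANOVA rejects, with an override to
force them.  Repeated measurements from the same animal are treated as
independent — a known simplification of the original design.

## Synthetic data: what it emulates and what it does not

* **Vessel scenes.** A straight vessel (diameter 20-50 um; a warning is
  emitted outside that selection range) rendered at a configurable axis
  angle: dark background (gray 10), brighter lumen (80), and a band of the
  true GCX thickness at 200 on each wall, plus additive Gaussian noise
  clipped to [0, 255] (Poisson shot noise optional).  The band occupies the
  half-open radial shell [r, r + t), so an integer-pixel band is exactly
  that many pixels thick perpendicular to an axis-aligned vessel, and the
  ground-truth mask marks exactly the band pixels.  Curvature, point-spread
  blur, photobleaching and motion are deliberately absent: the aim is a
  scene whose true thickness is knowable, not photorealism.  Recovery tests
  on these scenes validate the measurement chain (geometry, thresholding,
  counting, calibration); they do not certify performance on real images
  with focus gradients or wall curvature.
* **Tracks.** Adhering cells jitter around a fixed point with per-sample
  offsets norm-clipped to 1.5 x `jitter_sd` (bounding any displacement by
  3 x `jitter_sd`); rolling cells advance at
  `rolling_speed_fraction x centerline_speed` (defaults 0.2 x 100 um/s);
  flowing cells at the centreline speed.  Lateral positions stay inside the
  vessel; along-axis positions start inside the segment and may traverse
  beyond it, as real cells cross the field during 15 s — confining a
  100-um/s cell to a 100-um segment for the full window would be
  impossible.  Sampling is 2 Hz by default (31 samples); the classifier
  works on whatever sampling a track provides.
* **Leak series.** Every pixel has expectation
  `baseline + leak_rate * t` with i.i.d. Gaussian noise; frames are laid
  out to hold the configured ROIs with margins.  Real extravasation is
  spatially heterogeneous; the simulator tests the index arithmetic and the
  trend test, not spatial structure.
* **Cohorts.** Per hour, `n_per_time` independent normal draws with the
  configured mean/SD, truncated at zero for concentrations and thickness
  indices (rejection sampling; the truncation effect is negligible at the
  default parameters).  Default parameters use the published group values
  where printed (syndecan-1 1.85 +/- 0.48 ng/mL at 0 h, 3.83 +/- 1.09 at
  24 h, n = 3; TI arteriole 1.28 +/- 0.27 vs 1.79 +/- 0.62, venule
  1.05 +/- 0.39 vs 1.51 +/- 0.56, n = 21) and plausible values matching the
  described time-course shape elsewhere (syndecan-1 and TI back at control
  by 48 h; body weight ~24 g baseline, minimum at 48 h, restored by 168 h;
  mean blood pressure ~98 mmHg baseline, minimum at 24 h, restored by
  72 h).  These invented values are fixed in `config.py`.

Every generator is a pure function of its spec and seed; identical inputs
give bit-identical outputs, and the end-to-end emulation writes
byte-identical CSVs under a fixed seed.

## Emulation problem sizes

The full emulation renders 21 vessels per class per scheduled hour
(168 images of 151 x 211 px), 12 track measurements per hour with expected
class counts scaled to the vessel area, and 3/6 leakage locations at
0 h/24 h with three ROIs each — matching the measurement counts of the
emulated protocol.  Calibration runs use 1000-2000 replicates for rejection
rates (Monte-Carlo SE about 0.5-0.7 percentage points at alpha = 0.05).

## Known limitations

* No automatic vessel-wall detection or ROI placement; anchors and angles
  are inputs, as in the manual protocol.
* No cell detection or tracking from raw video; tracks and detections are
  inputs.
* The statistical layer ignores the repeated-measures structure
  (measurements nested in animals).
* TI accuracy degrades for bands thinner than ~1 px and the method is
  undefined without a visible band (see failure mode above).
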