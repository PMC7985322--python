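# Methods

punctakit quantifies the disruption (or blocked formation) of biomolecular
condensates in live-cell fluorescence timelapses, and ships a synthetic movie
generator so that every statistic in the pipeline can be validated by
parameter recovery against exact ground truth.  This note records the models,
the conventions, and the design decisions that the numbers depend on.

## The measurement model

A condensate-forming ("scaffold") protein partitions between a bright dense
phase (the condensates) and a dilute cytosolic/nucleoplasmic pool.  All
statistics are computed from background-subtracted pixel intensities inside a
cell mask:

- **Condensate fraction.**  With a condensate mask of `Area_dense` pixels,

      fraction = Area_dense · (MeanI_dense − MeanI_dilute) / TotalIntegratedDensity

  where `MeanI_dilute` is the mean over the cell mask minus the condensate
  mask and the denominator is the background-subtracted integrated density of
  the whole cell.  Subtracting the dilute mean makes the numerator the *excess*
  signal stored in the dense phase, so the fraction is invariant to adding a
  constant to every pixel (with a matched background estimate) and to positive
  rescaling.

- **Disruption efficiency.**  `100·(F_pre − F_post)/F_pre` between a
  pre-treatment and a post-treatment frame.  Negative values (growth) are
  reported and flagged, never clipped.

- **Dense/dilute ratio** `MeanI_dense/MeanI_dilute` (pre-treatment,
  background-subtracted): a per-cell proxy for the partition coefficient,
  regressed against efficiency to ask whether strongly partitioned
  condensates resist disruption.

- **Condensate intensity ratio.**  Integrated intensity over the condensate
  mask divided by total cell integrated density (both background-subtracted);
  unlike the fraction, the numerator keeps the dilute signal under the mask.
  Used for endpoint formation/blocking comparisons, per cell or aggregated
  over a merged multi-cell field.

- **Uptake percent.**  Mean background-subtracted cargo signal in treated
  cells as a percent of untreated cells (endocytosis read-out).

## Segmentation

Z-stacks are reduced by maximal projection.  Thresholds follow the ImageJ
auto-threshold conventions the field uses: a 256-bin histogram spanning the
per-image `[min, max]` range; the returned threshold is a bin edge; masks are
`pixels > threshold`; ties break toward the lower threshold.  Otsu's method
maximizes between-class variance; the maximum-entropy method maximizes
Kapur's sum of class entropies (empty-class candidates skipped); the Mean
method returns the image mean (used for cell footprints).  Both histogram
criteria are verified against exhaustive-search oracles, and Otsu masks
against scikit-image's implementation.  Cell masks are morphologically closed
(disk of radius 2) and hole-filled; condensate objects smaller than
`min_object_px` (default 4 px) are removed to suppress shot-noise specks.

Two timelapse conventions are provided because published workflows rarely
state which they used:

- `reference_frame` (default 0): the condensate *threshold* is computed on
  the pre-treatment frame and held for the whole movie.  Per-frame
  re-thresholding of a dissolving movie hallucinates foreground after the
  condensates are gone.
- `freeze_mask` (pipeline default): the reference frame's condensate *mask*
  is additionally held fixed.  This is the correct observable for kinetics:
  signal inside a fixed dense-phase region decays exactly with the underlying
  kinetics, whereas a per-frame mask shrinks as droplets dim past the
  threshold, censoring the tail and biasing tau low by tens of percent (and
  saturating measured efficiencies at 100%).  Parameter-recovery tests
  quantify both effects.

Per-frame masks remain the right choice for endpoint statistics on
independent images, and are what `segment_stack` returns by default.

## Kinetics

The condensate timecourse (fraction or condensate-integrated intensity) is
fitted by bounded least squares (`scipy.optimize.least_squares`, tau > 0,
relative tolerance 1e-8, ≤ 1000 evaluations) to one of

    sigmoid:      v(t) = base + amplitude / (1 + exp((t − t_half)/tau))
    exponential:  v(t) = base + amplitude · exp(−(t − t_start)/tau)

`tau` is the characteristic time.  The logistic uses tau as the exponential
rate parameter (midpoint slope −amplitude/4tau; 10–90% fall time =
2 ln(9)·tau ≈ 4.39·tau for conversion to rise-time conventions).
Initialization is derivative-free: base/amplitude from the series extremes,
t_half from the interpolated half-crossing, tau from the 25–75% crossing span
divided by 2 ln 3.  Frames before the treatment onset are included in sigmoid
fits (they pin the upper plateau) and excluded from exponential fits, whose
origin `t_start` is held at the onset.  Degenerate series return
`converged=False` with a diagnostic — never a fabricated tau.  Standard
errors come from the Gauss–Newton covariance at the solution; tau fold
changes between two fits propagate them to first order.

Noiseless self-consistency is exact to better than 1e-3 s.  A simulation
study (5% amplitude noise, 60 frames) shows the sigmoid tau estimator is
unbiased with ~10% spread; accuracy claims in the tests are set at the rates
that design actually supports.  Published analyses are ambiguous about
whether oligomeric-cluster data were fitted with exponentials or sigmoids;
both are provided and the exponential is verified to be the tail limit of the
sigmoid (agreement within 5% for t ≫ t_half).

## FRAP normalization

The bleached-region integrated density is divided by the background-free
whole-cell integrated density at every frame; this ratio cancels global
acquisition photobleaching.  The ratio trace r(t) is mapped to [0, 1] with 0
at the bleach time point and 1 at the pre-bleach average:

    normalized(t) = (r(t) − r(bleach)) / (mean_prebleach(r) − r(bleach)).

Overshoot outside [0, 1] is noise and left unclipped.  The bleached region is
a fixed mask drawn at the bleach frame.  Bleach depths outside the 60–85%
calibration band typical of spot-bleaching protocols are flagged.  The
long-time plateau estimates the mobile fraction; a convenience
single-exponential recovery fit (plateau = mobile fraction, tau = exchange
time) reuses the kinetics fitter and is labeled as going beyond plain
normalized-curve read-outs.

## The simulator

Scenes are a single elliptical cell (optional nested nucleus) over a dark
background, with non-overlapping anti-aliased disc condensates placed fully
inside the cell by rejection sampling (bounded retries, explicit failure).
Anti-aliasing (linear edge ramp, ~1 px) gives the sub-pixel edges that stress
thresholding the way real droplets do.

**Intensity model.**  `dilute_level` is the expected photons/pixel in the
cytosol at t = 0 and `partition_coefficient` the dense/dilute ratio, so the
initial dense excess is `E0 = dilute·(P − 1)` per fully covered pixel (an
explicit `dense_level` override covers degenerate scenes such as a zero
dilute pool).  During dissolution the excess follows a kinetics factor f(t):
constant; exponential decay from the onset; or a pure logistic with midpoint
3·tau after onset (within 5% of 1 at onset, so the rendered curve is exactly
the model the fitter assumes).  Lost dense signal is returned uniformly to
the dilute pool inside the cell, so the total expected photon count is
conserved to machine precision — as it is in a cell that dissolves its
condensates without degrading the protein.  The default mode dims droplets
in place at fixed footprint (the quantified observable is intensity);
a radius-shrinkage mode is provided since real condensates may do either.
The expected condensate fraction has the closed form

    fraction(t) = E0 · f(t) · A_drop / (dilute·A_cell + E0·A_drop),

recorded per frame as ground truth together with the true masks, tau,
partition coefficient, and (for decay movies) the true efficiency between
first and last frames.

**Noise.**  Poisson shot noise with gain g (`counts = g·Poisson(expected/g)`)
plus Gaussian read noise, applied last; `noise_gain = read_noise_sd = 0`
renders the expectation exactly.  Defaults (dilute 40, P = 6, gain 1, read
sd 2) put the dense-pixel SNR above 10.  One master seed drives everything;
droplet geometry and each frame's noise use fixed derived substreams
(`SeedSequence([seed, 0])`, `SeedSequence([seed, 1, frame])`), so identical
config + seed is bit-identical and changing the frame count never reshuffles
earlier frames.

**FRAP movies.**  On a static scene, the bleach pulse multiplies the region
by (1 − depth).  Recovery equilibrates the region toward the *post-bleach
cell-average concentration* — not its absolute pre-bleach photon count —
because after the pulse the cell's fluorescent pool is permanently
diminished; full exchange restores the region to the same region/total ratio
as before.  Only `mobile_fraction` of the deficit exchanges, with time
constant `exchange_tau_s`, and the recovered signal is withdrawn uniformly
from the rest of the cell (conservative exchange).  Under this convention
the normalized plateau equals the mobile fraction exactly, which is what
makes mobile-fraction recovery a sharp test.  An optional whole-field
exponential `acquisition_bleach_tau_s` exercises the normalization's
global-bleach cancellation (off by default).

**Endpoint pairs.**  `matched_blocked_config` builds a droplet-free
counterpart with the dilute level raised to match total expected cell
fluorescence; ground truth records each scene's condensate intensity ratio
over the full droplet support.

**What the simulator does not emulate.**  No optical PSF or out-of-focus
light, no 3-D rendering (Z planes only as trivially stackable layers), no
droplet motion, fusion, or ripening, no cell movement or photophysics beyond
the global bleach factor, and droplets never overlap.  A green
parameter-recovery test therefore establishes that the analysis is correct
for well-resolved, well-separated condensates in a stationary cell — not
that it is robust to blur, drift, or dense droplet fields.

## Numerical conventions and degenerate inputs

- Histogram thresholds on a constant image raise a degenerate-histogram
  error; empty cell or condensate masks are flagged warnings, not failures.
- `fraction_pre ≤ 0` or a nonpositive total integrated density raise
  undefined-statistic errors rather than emitting NaN.
- Background defaults to the mean outside the 2-px-dilated cell mask; a full
  frame cell mask requires an explicit background value.
- All thresholds, background estimates, and fit initializations are logged at
  INFO, since results hinge on these normally unstated choices.

## Known limitations

- Aggregate dense-phase statistics only: no per-droplet tracking or instance
  segmentation; multi-cell fields are analyzed as one aggregate unless a cell
  instance mask is supplied.
- The dense/dilute ratio underestimates the true partition coefficient when
  droplet edge pixels straddle the mask boundary.
- FRAP analysis is normalization plus plateau/exponential summaries; no
  diffusion-equation modeling or bleach-profile correction.
- The frozen-mask kinetics observable assumes condensates do not move on the
  timescale of the movie.
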