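# Methods notes

This note records the models behind each analysis stage, the parameters
that matter, and the design choices made where more than one reasonable
definition exists.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Calcium-trace model and analysis

### Normalization

Raw fluorescence per ROI is normalized as ΔF/F₀ = (F − F₀)/F₀, with F₀ the
per-ROI mean over the protocol's baseline window (DRG protocol 0–300 s of a
350 s recording; rat mixed-glia protocol 0–500 s of 700 s; the bovine
variants 0–100 s).  Windows are half-open `[start, end)` at the 1 Hz
default sampling.  The normalization exists to cancel the multiplicative
indicator loading efficiency, so the whole metric set is invariant under
F → c·F; this invariance is asserted in the tests rather than assumed.
ROIs with F₀ ≤ 0 cannot be normalized and are excluded with a log entry,
never imputed.  The derivative dΔF/F₀ is the first-order forward
difference divided by the sampling interval; the sample between t and
t+1 s is stamped t+1 (the instant the rise has been realized).  No
smoothing is applied before differentiation.

### Peak calling

Candidate events are local maxima of dΔF/F₀ (strictly greater than both
neighbours; a plateau contributes its first sample) inside the analysis
window, pooled across all ROIs of the recording.  The detection threshold
is the 95th percentile (configurable) of the pooled candidate heights; an
event is retained when its height is strictly above it.  The pool is
dominated by noise ripples — differenced white noise has a local maximum
roughly every 2.7 samples — so the percentile acts as a per-recording
adaptive noise floor and genuine transients, whose rise derivative dwarfs
the noise, populate the retained tail.  Each event's amplitude is the
largest ΔF/F₀ between the derivative onset (start of the positive
derivative run) and the next zero-crossing of the derivative, i.e. the top
of the rise.

A consequence worth knowing: a percentile threshold retains a fixed
fraction of each pool.  Analyzing several recordings with *separate*
thresholds therefore flattens genuine event-rate differences between them
(each recording keeps ~5% of its own candidates).  For multi-well,
multi-group experiments `detect_spontaneous_peaks_pooled` pools the
candidates of all recordings into one shared threshold, which restores
cross-group comparability; `run_experiment` does this by default.  The
single-recording entry point keeps per-recording pooling, appropriate when
a recording is analyzed in isolation.

### Responder classification

An ROI is a stimulus responder when its maximum ΔF/F₀ inside the evoked
window exceeds the classification threshold.  The default threshold is the
95th percentile of the spontaneous event amplitudes pooled across ROIs: an
evoked response must stand out against the recording's own spontaneous
activity.  A literal alternative — 95% of the maximum evoked peak height
across ROIs — is available behind `rule="max_fraction"`; with one dominant
responder it admits almost nothing else, which is why it is not the
default.  KCl protocols label responders `neuron` and the rest
`non_neuron` (only neuronal structures depolarize immediately under high
extracellular potassium); ATP protocols label them `live`/`dead` (glia
without an ATP response are considered dead) and non-responders are
excluded from evoked metrics.

Misclassification under the default rule is dominated by non-responders
that happen to fire a large spontaneous transient inside the evoked
window; at the default simulation conditions this inflates the recovered
responder fraction by ~0.02–0.04, which the recovery tests bound.

### Evoked metrics

Evoked peak height is the evoked-window ΔF/F₀ maximum minus the
pre-stimulus level (mean ΔF/F₀ over the 10 s before the stimulus).  Flux
duration is the full width at half maximum: the length of the maximal
contiguous run of samples containing the peak during which ΔF/F₀ stays
above the pre-stimulus level plus half the peak height.  Frequency is not
meaningful after a strong stimulus (large transients convolve), hence a
width measure; half-max is the conventional threshold-free choice.

## Synthetic recordings

Each ROI's baseline F₀ is lognormal (default mean 100 a.u., CV 0.3),
modelling Fluo-4 loading spread.  Spontaneous transients arrive as a
homogeneous Poisson process — default 5/3 events per 100 s, i.e. five per
300 s baseline, the median spontaneous rate of untreated DRG cultures this
generator emulates — with lognormal amplitudes (default mean 0.5 ΔF/F₀,
CV 0.3; reported medians for such cultures are ~0.3–0.6).  The transient
kernel is a peak-normalized difference of exponentials
(1 − e^(−t/τ_rise))·e^(−t/τ_decay) with τ_rise = 1.5 s, τ_decay = 8 s,
the standard minimal calcium-transient waveform at 1 Hz sampling.  A
configurable fraction of ROIs (exact count, random subset) receives an
evoked transient (default amplitude 1.5) at the protocol's stimulus time.
Gaussian noise (default SD 0.02 ΔF/F₀) is added in normalized units
*before* multiplication by F₀, so loading stays purely multiplicative:
F = F₀·(1 + signal + noise), floored at zero.  One seed drives all draws
in a fixed order (baselines, counts, times, amplitudes, responder subset,
noise), making outputs bit-identical per (config, seed).

What the generator does not emulate: photobleaching, motion, indicator
binding kinetics, bursting/overdispersed event statistics, correlated
noise, and overlapping ROIs.  Passing recovery tests therefore show the
analysis is correct for well-behaved recordings, not that it is robust to
every artefact of real microscopy.

The generator also returns, on request, the expected time of each injected
event's discrete derivative maximum (`expected_derivative_peak_times`):
detectors report derivative-peak times, which lag the continuous event
onset by one to a few samples, so recovery comparisons match like with
like inside the ±2 s tolerance.

## Morphometrics

Shape metrics use `skimage.regionprops` for area, convex area and fitted
ellipse axes.  The perimeter is the length of the marching-squares
boundary contour after a light circular moving average over the contour
vertices (window 7, ≈ 5 px of arc).  Raw pixel-edge counting overstates a
digital disk's perimeter by ~27% and even the sub-pixel contour by ~5%,
which would push the transformation index of a circle visibly above its
analytic minimum of 1; the smoothed contour lands within ~0.5% on a
radius-50 disk while costing a square under 3%.  The elliptical form
factor defaults to the fitted-ellipse axis ratio, with a max/min Feret
(rotating calipers) alternative.

Sholl analysis skeletonizes the mask and, at each radius r = step,
2·step, … (default step 1 µm, max 40 µm), counts the 8-connected
components of skeleton pixels whose distance from the soma lies within
r ± √2/2 pixels.  The annulus half-width is the smallest that a diagonal
pixel chain cannot slip through; neighbouring processes stay separate at
realistic spacings.  Branches closer together than ~2 px at a sampling
radius merge into one crossing — immediately distal to a bifurcation the
two children count as one until they separate, which matches the physical
picture of a branch point.  The soma anchor defaults to the centre of the
largest inscribed disk of the mask and can be overridden.

Synthetic cells are built as exact planar geometry (shapely): a soma disk,
plus radial rectangular processes with optional secondary branches for the
ramified class, rasterized at pixel centres.  Reference metrics come from
the continuous geometry, so pixel-estimator recovery is tested against
analytic truth rather than against another raster estimate.  Synthetic
arbors (n primary branches bifurcating once at a known radius) have a
closed-form Sholl profile: n, then 2n, then 0.

## Immunofluorescence quantification

Stained pixels are those strictly above the threshold — a fixed absolute
value from config, or per-channel Otsu.  Stained intensity is the mean
over stained pixels (a whole-field mean is available); no background
subtraction or flat-field correction is applied.  Every output row records
the threshold and rule used.  Marker ratios divide the two channels'
stained intensities per field; fields whose denominator has no signal are
excluded with a log entry.  Cell positivity compares the mean intensity
inside each cell mask with a threshold, by default a fixed value, or
mean + 2 SD of a negative-control field when one is provided.

## Statistics

The two-level scheme reflects the nesting of such experiments: cells or
fields are technical replicates within a donor; donors are the independent
units.

* Technical level: the gated two-group test runs Shapiro-Wilk on each
  group and uses the two-sample t-test only when both p-values exceed the
  deliberately asymmetric gate of 0.1, otherwise Mann-Whitney.  Pairwise
  contrasts between multiple groups use the Wilcoxon rank-sum test
  (identical to Mann-Whitney; tie-corrected, exact for small untied
  samples via scipy's automatic method).  Responder proportions use the
  plain Pearson 2×2 chi-square: Yates' continuity correction is noticeably
  conservative at n ≈ 100–150 per group and is therefore off by default
  (available via flag); tables with a zero margin raise.
* Donor level: per-donor medians per group, compared across donors with a
  paired t-test.  This uses the data only through the medians (asserted by
  a shuffling test) and is an honest small-n summary, not a mixed model —
  mixed-effects modelling is deliberately out of scope.

Pairwise contrasts are reported unadjusted, each on its own; a Holm
adjustment is available but off by default, and the choice is recorded in
every result.

## Pipeline determinism and sizes

`run_experiment` expands the single top-level seed into one child seed per
(group, donor) stage via `numpy.random.SeedSequence` spawning in a fixed
order (groups sorted, then donors), so stages can be re-simulated in
isolation and a full rerun is bit-identical.  Default problem sizes in the
tests and the acceptance script — 200 ROIs per recording for recovery
measurements (pooled over several seeds), 1000 null simulations per
statistical test, three donors per group — were chosen to make the
measured rates stable to well under the tolerances they are compared at.

## Known limitations

* The pooled-percentile peak caller retains a fixed candidate fraction per
  pool; its absolute event counts are only meaningful when the true event
  rate is of the same order as the retained fraction (see the pooling
  discussion above).  Very sparse recordings will over-detect noise, and
  very dense ones will truncate; relative comparisons under a shared
  threshold remain valid.
* Flux duration assumes a single dominant evoked transient; oscillatory
  evoked responses would be summarized by the width of their largest lobe.
* Sholl crossing counts saturate within ~2 px of the soma and immediately
  distal to bifurcations (see above).
* The statistics module implements the scheme as used in this assay
  family, including its lack of multiplicity correction; users comparing
  many contrasts should enable the Holm option.
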