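# gliakit

Quantification toolkit for in vitro assays of sensory-neuron-to-glia
communication: calcium-transient analysis of 1 Hz time-lapse fluorescence
recordings, glial cell morphometrics, immunofluorescence field
quantification, and the two-level (technical replicate / donor) statistical
comparison scheme such experiments use.  A synthetic-data generator with
known ground truth makes every stage testable without recorded data.

It is aimed at cell biologists and image analysts quantifying cultures of
dorsal root ganglion (DRG) neurons and spinal-cord mixed glia (microglia +
astrocytes) under inflammatory stimulation, but the machinery is generic:
any Fluo-4-style recording with a baseline window and a pharmacological
stimulus (KCl depolarization, ATP), any binary cell mask, any multi-channel
stained field.

## The methods in brief

**Calcium traces.**  Per ROI, raw fluorescence is normalized by its
baseline mean, ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean over the baseline
window, which cancels indicator loading efficiency (every metric is
invariant under F → c·F).  The first derivative dΔF/F₀ is the speed of the
calcium concentration change; spontaneous transients are local maxima of
the derivative exceeding the 95th percentile of all candidate maxima pooled
across the ROIs of the recording — an adaptive noise floor.  Per-ROI
metrics: MFES (maximum fluorescence elevation speed, the largest derivative
in the window), peak frequency (retained event count), peak height (median
event amplitude in ΔF/F₀).  Stimulus responders (neurons under KCl, live
glia under ATP) are ROIs whose evoked-window ΔF/F₀ maximum clears the 95th
percentile of pooled spontaneous peak amplitudes; non-responders are
excluded from evoked metrics (peak height above the pre-stimulus level and
flux duration, the full width at half the evoked peak).

**Morphometrics.**  Area, perimeter, solidity (area / convex area),
transformation index (perimeter² / 4π·area; 1 for a circle), elliptical
form factor (length/breadth of the fitted ellipse), and Sholl profiles
(crossings of the skeletonized mask with concentric circles around the
soma, summarized as maximum intersection number and sum of intersections).

**Immunofluorescence.**  Per channel and field: stained area (pixels above
an absolute or Otsu threshold) and stained intensity (mean over stained
pixels); per-field marker ratios (e.g. CGRP normalized by TUBB3); per-cell
positive proportions against a threshold.

**Statistics.**  Technical level: Shapiro-Wilk-gated two-group test
(both p > 0.1 → two-sample t, else Mann-Whitney), Wilcoxon rank-sum for
named pairwise contrasts, 2×2 chi-square for responder proportions.  Donor
level: per-donor medians compared by a paired t-test.

## Worked example

Simulate a recording of 100 ROIs (spontaneous transients at the default
rate, 80% of ROIs responding to the depolarizing stimulus), then run the
full analysis:

```python
from gliakit.pipeline import analyze_trace_set
from gliakit.synthetic import TraceSimConfig, simulate_trace_set

traces, truth = simulate_trace_set(
    TraceSimConfig(n_rois=100, responder_fraction=0.8, seed=42)
)
table = analyze_trace_set(traces)
print(table[["roi_id", "mfes", "peak_frequency", "peak_height", "roi_class"]].head(5))

neurons = table[table.roi_class == "neuron"]
print(f"responders (neurons): {len(neurons)}/{len(table)}")
print(f"median MFES: {neurons.mfes.median():.3f}  "
      f"median peak frequency: {neurons.peak_frequency.median():.0f}  "
      f"median peak height: {neurons.peak_height.median():.3f}")
```

prints

```
 roi_id     mfes  peak_frequency  peak_height roi_class
      0 0.307541               6     0.321703    neuron
      1 0.266076               3     0.337665    neuron
      2 0.413873               6     0.310896    neuron
      3 0.330849               3     0.446927    neuron
      4 0.449999               5     0.405033    neuron

responders (neurons): 80/100
median MFES: 0.352  median peak frequency: 5  median peak height: 0.355
```

Each row is one cell: `mfes` is its fastest calcium rise (ΔF/F₀ per
second), `peak_frequency` its retained spontaneous transient count over the
300 s baseline, `peak_height` the median transient amplitude, and
`roi_class` the KCl classification.  The classifier recovers the simulated
80% responder fraction exactly here, and the median metrics sit in the
range typical of spontaneously active DRG cultures (heights ≈ 0.3-0.5
ΔF/F₀, ~5 events per 300 s).

A whole multi-group experiment (simulate → analyze → two-level statistics)
runs from a declarative YAML config:

```sh
gliakit run --config experiment.yaml      # see ExperimentConfig for the schema
gliakit simulate traces --seed 1 --out sim/
gliakit traces --protocol drg_rat --in sim/traces.csv --out out/
gliakit shapes --pixel-size 0.5 --in masks/ --out out/
gliakit fields --threshold otsu --in fields/ --out out/
```

## Layout

```
src/gliakit/
  protocols.py       stimulus protocols and dilution arithmetic
  traces.py          ΔF/F₀ normalization, peak calling, responders, metrics
  morphometrics.py   shape descriptors and Sholl analysis
  ifquant.py         stained area / intensity / ratios / positivity
  stats.py           gated tests, rank-sum contrasts, chi-square, donor level
  synthetic.py       ground-truth generators (traces, masks, arbors, fields)
  pipeline.py        experiment orchestration (config, seeds, reports)
  io.py, cli.py      CSV/TIFF/JSON formats and the `gliakit` CLI
docs/methods.md      model and design notes
tests/               unit, property and acceptance tests
```
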