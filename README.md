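# mdca — microdomain calcium analysis

`mdca` is a tested, reusable implementation of the analysis chain used to
quantify astrocyte calcium activity in awake two-photon imaging of the
peri-infarct cortex: preprocessing of 10 Hz / 512 px / 420 µm movie stacks,
size-classified ROI segmentation (somata ≥ 30 µm², microdomains 0.5–10 µm²,
territories), ΔF/F transient detection, mitochondrial domain statistics,
behavior-state-conditioned event rates and behavioral scores, blood-flow
based peri-infarct field selection, and correlation-based neuronal ensemble
detection. Because studies of this kind deposit no raw movies, the package
ships a first-class simulator that generates movies, behavior tracks,
correlated neuron traces and flow maps with known ground truth, and the
whole chain is validated end-to-end against what was planted.

It is written for imaging labs who want the standard astrocyte
microdomain workflow as an inspectable, scriptable library rather than a
chain of GUI steps.

## The analysis in brief

For each ROI the member-pixel fluorescence is averaged into F(t). The
basal fluorescence F₀ is the mean of the contiguous 20-s window with
minimal variance; the normalized trace is

    ΔF/F(t) = (F(t) − F₀) / F₀,

smoothed with a centred 300-ms moving average. The baseline s.d. σ of the
smoothed trace is taken inside the F₀ window, and an event is each maximal
run of frames with ΔF/F > 2σ lasting at least a minimum duration
(default 0.7 s). Per ROI the pipeline reports frequency (events/min), and
mean/peak amplitude and duration per event. ROIs come from 8-connected
components of a thresholded (5 a.u.) detection image, classified purely by
area; cells are grouped by a watershed seeded at the somata, and a cell's
territory is the convex hull of its components. Two-group comparisons use
the two-sided Mann-Whitney U test (exact for small samples, including
ties).

Mitochondrial-indicator movies are analyzed per cell by per-pixel event
detection followed by clustering of event-bearing pixels into domains
(≥ 2 px), reporting events/domain and mean amplitude. Neuronal ensembles
are connected components (size ≥ 2) of the Pearson-correlation graph
thresholded at r > 0.3.

## Worked example

```python
from mdca import RunConfig, SimulationSpec, run_pipeline, group_compare

spec = SimulationSpec(frame_size_px=128, field_of_view_um=105.0,
                      n_cells=6, microdomains_per_cell=10,
                      duration_s=300.0, event_rate_per_min=2.0,
                      event_amplitude_dff=0.4)
result = run_pipeline(RunConfig(seed=1, simulation=spec))

md = result.summary[result.summary.roi_class == "microdomain"]
soma = result.summary[result.summary.roi_class == "soma"]
print(f"{len(result.rois)} ROIs ({len(soma)} somata, {len(md)} microdomains)")
print(f"microdomains: {md.frequency_per_min.mean():.2f} events/min, "
      f"peak dF/F {md.mean_peak_amplitude.mean():.2f}, "
      f"duration {md.mean_duration_s.mean():.2f} s")
```

prints

```
66 ROIs (6 somata, 60 microdomains)
microdomains: 1.87 events/min, peak dF/F 0.41, duration 2.56 s
```

— the simulator planted 2.0 events/min at peak ΔF/F 0.4 in every region,
and the full chain (render → blur → segment → trace → detect) reads them
back within a few percent; the detected duration is longer than the
1.5-s nominal transient because events are scored for as long as the
decaying GCaMP6f-like kernel stays above the 2σ threshold. Comparing this
"pre" recording with a second simulated at 1.2 events/min:

```python
import dataclasses
post = run_pipeline(RunConfig(seed=2, simulation=dataclasses.replace(
    spec, event_rate_per_min=1.2)))
post_md = post.summary[post.summary.roi_class == "microdomain"]
cmp = group_compare(md.frequency_per_min, post_md.frequency_per_min)
print(f"pre vs post: U = {cmp.u_statistic:.0f}, p = {cmp.p_value:.2e}")
# pre vs post: U = 2958, p = 1.03e-09
```

A command-line interface wraps the same functions:

```bash
mdca simulate --seed 1 --out sim/          # movie.tif + ground truth
mdca run --seed 1 --out results/           # full chain, CSV outputs
mdca compare pre/summary.csv post/summary.csv --column frequency_per_min
```

## Layout

- `src/mdca/synth.py` — simulator (layouts, Poisson trains, rendering,
  correlated traces, behavior, flow maps) with ground truth
- `src/mdca/preprocess.py` — rigid motion correction, blur/median/
  background chain, activity masking
- `src/mdca/segment.py` — size-classified segmentation, morphology
- `src/mdca/events.py` — F₀, ΔF/F, 2σ event detection, per-ROI metrics
- `src/mdca/mito.py` — mitochondrial domain maps and statistics
- `src/mdca/behavior.py` — states, alignment, scores, field selection
- `src/mdca/ensembles.py` — correlation matrix, ensemble detection
- `src/mdca/pipeline.py` — orchestration, config, Mann-Whitney comparison
- `docs/methods.md` — model assumptions, parameter choices, limitations
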