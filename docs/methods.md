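# Methods

This note documents the models, parameter choices and numerical decisions
behind `mdca`, and what the synthetic validation does and does not
demonstrate about real recordings.

## Acquisition geometry and units

The nominal recording is a 512 × 512 px frame over a 420 µm × 420 µm
field at 10 Hz, i.e. 0.8203125 µm/px (0.673 µm²/px). Scaled-down test
movies keep this pixel size and shrink the field, because the ROI size
classes are defined in µm² and a coarser pixel could not represent a
0.5 µm² microdomain at all. Behavior video runs at 25 Hz and is aligned
to imaging frames by nearest timestamp.

## Event detection model

Per ROI, member-pixel fluorescence is averaged into F(t). F₀ is the mean
of the contiguous 20-s window of minimal variance (the operational
reading of "a quiet baseline period"), scanned at one-frame stride.
ΔF/F = (F − F₀)/F₀ is smoothed with a centred 300-ms boxcar (3 frames at
10 Hz, edges clamped). The detection s.d. is the s.d. of the smoothed
ΔF/F inside the F₀ window (a whole-trace option exists behind
`sd_scope`), and events are maximal runs above 2 × s.d.

**Minimum event duration.** A fixed-k threshold on smoothed Gaussian
noise produces chance runs at a rate that is *independent of SNR*
(the threshold scales with the noise). Measured on pure noise at 10 Hz:
≈ 0.6 false events per 300-s trace with a 0.5-s minimum, ≈ 0.1 at 0.7 s,
≈ 0.01 at 0.8 s. Astrocyte microdomain transients last seconds — at the
default kinetics an 0.4 ΔF/F transient stays above threshold for ≈ 2 s —
so the default minimum duration is 0.7 s: it suppresses nearly all noise
runs without touching physiological events. Two-frame debouncing is
available by setting `min_duration_s=0.2`.

**Reported quantities.** Frequency is events per minute of trace (or per
minute spent in a behavior state for state-conditioned rates — the
normalization is by state duration, not total time). Amplitudes are
fractional ΔF/F internally; multiply by 100 for %ΔF/F displays. Event
duration is the time above threshold, which exceeds any "nominal"
transient duration by construction.

## Preprocessing chain and which movie feeds which stage

Motion correction is rigid and integer-valued: each frame is aligned to
the temporal-median reference by the shift (|shift| ≤ `max_shift_px`)
maximizing FFT cross-correlation, with ties broken toward zero; border
rows/columns not observed in every frame are cropped, and frames whose
estimate hits the search bound are flagged unreliable. Sub-pixel motion
is not modelled.

Denoising applies a per-frame isotropic Gaussian blur (σ = 2 px), an
optional circular median filter (radius 5 px), and background correction
by subtracting a per-frame low-percentile intensity (default 1st
percentile, clamped at zero).

Two consequences of this chain required explicit design decisions:

1. **The radius-5 median filter and microdomains are incompatible.** A
   median over an 81-px window removes any structure smaller than about
   half the window; microdomains are 1–15 px. The despeckle step is
   therefore exposed with its conventional default in `preprocess_movie`
   but disabled in the pipeline defaults (`median_radius_px = 0`), where
   it would erase the smallest compartments being quantified. It remains
   appropriate for soma-scale maps and QC images.
2. **Background percentiles carry a noise-quantile pedestal.** The 1st
   percentile of dark-pixel noise sits ≈ 2.3σ below the true dark level,
   so percentile subtraction leaves a small positive pedestal. Against
   the absolute 5 a.u. detection threshold this is tolerable (and a low
   percentile is the only estimator robust to arbitrarily large bright
   fractions of the frame), but in a ratio it deflates ΔF/F of dim ROIs
   by up to ~10%. The pipeline therefore uses two movies:
   - *detection movie*: σ = 2 blur + percentile background subtraction;
     its temporal median projection is thresholded at 5 a.u. for
     segmentation (the per-pixel median ignores sparse transients);
   - *quantification movie*: σ = 1 blur, **no** background subtraction.
     On a dark background, blurring rescales F and F₀ by the same
     geometric factor so ΔF/F is preserved exactly, any global offset is
     absorbed into F₀, and the milder blur is matched to the microdomain
     scale (σ = 2 correlates noise over an area larger than a microdomain
     ROI, inflating the noise-driven upward bias of peak amplitudes).

   Traces are averaged over each ROI's *bright core* (pixels ≥ half the
   ROI's peak projection value), which suppresses cross-talk from the
   blurred halos of neighbouring regions; without it, soma amplitudes
   read ≈ 13% low in dense fields.

## Segmentation and morphology

Candidate ROIs are 8-connected components of the thresholded detection
image; classification is a total function of area with closed bounds —
soma ≥ 30 µm², microdomain ∈ [0.5, 10] µm² — and blobs in the unassigned
10–30 µm² gap (or < 0.5 µm²) are kept as "unclassified" and excluded
from event statistics. Cells are grouped by a watershed on the distance
transform seeded at the soma components (every pixel joins its nearest
soma's basin); a cell's territory is the convex hull of its components,
and neighbouring territories may overlap, so they are stored as masks
rather than a flat label image. Morphology reports territory and soma
area, their ratio (territory/soma), bounding-box height and width, and a
Crofton perimeter (less biased than pixel-edge counting). ROIs touching
the frame border are kept.

## Mitochondrial domains

Astrocyte mitochondrial movies are analyzed per cell with a transparent
two-step surrogate for the published domain-clustering machinery: every
sufficiently bright pixel (temporal median > 5 a.u.) inside the cell mask
runs through the same single-trace detector (vectorized across pixels);
event-bearing pixels are clustered into 8-connected components and
components ≥ 2 px become domains. Events/domain is a *count over the
recording* divided by the domain count (the recording length is reported
alongside so it can be re-expressed as a rate), and mean amplitude is the
event-weighted mean peak ΔF/F. Domain counts are invariant to intensity
rescaling above threshold.

## Behavior and field selection

Walking is smoothed centroid speed (0.2-s boxcar) above 0.5 cm/s
sustained ≥ 0.5 s; both values are configuration, since no operational
criterion is standard. Standing (rearing) is not derivable from a 2-D
centroid and is accepted as an annotation channel, matching manual
scoring practice. Scores: foot-fault % = faults/(faults+non-faults)×100
per limb; cylinder score = (R−L)/(R+L+B). Field selection: fractional
flow reduction 1 − post/pre per candidate field; > 35% (strict) → core;
within [15%, 25%] (closed) and adjacent to a core field → peri-infarct
target; otherwise reject; an animal with no target field is excluded, and
an injection-site reduction within [40%, 60%] (closed) marks a usable
stroke model.

## Ensembles

Pairwise Pearson correlation of ΔF/F traces; constant traces are flagged
invalid and excluded (NaN rows). Per-neuron mean correlation is the mean
off-diagonal entry of its row. Ensembles are connected components
(size ≥ 2) of the graph with edges r > 0.3; both the threshold and a
deterministic greedy-modularity refinement (fixed node order, no
randomness) are configuration. Connected components keep the default
path exactly reproducible; the refinement exists for fields where the
threshold graph fuses distinct groups. These choices are one concrete
instantiation of "correlation + network analysis"; results should be read
relative to them.

## Statistics

Two-group comparison is the two-sided Mann-Whitney U. The p-value is
exact by full enumeration of rank assignments whenever
C(n₁+n₂, n₁) ≤ 10⁵ — this handles ties correctly and returns p = 1 for
identical multisets — exact via the U distribution for tie-free samples
with n₁n₂ ≤ 400, and otherwise the normal approximation with tie
correction (which agrees with the exact path to |Δp| ≤ 0.01 by n = 20).

## The simulator and what it does (not) show

The generator renders: somata as discs of radius 4 px (33 µm²) on a
jittered grid; microdomains as discs of radius 1 px (3.4 µm², mid-range
of the class) scattered in each soma's Voronoi basin; per-region
homogeneous Poisson transient trains (default 2 events/min) with a
difference-of-exponentials kernel normalized to unit peak (rise 0.2 s,
decay 1.0 s, GCaMP6f-like — the kinetics are stand-ins, exposed in
configuration); resting brightness 30 counts over a dark (0-count)
background; additive Gaussian noise of σ = 2.4 counts (peak-signal SNR 5
at ΔF/F 0.4; Poisson shot noise behind a flag); and optional integer
rigid jitter (periodic shifts, recorded in ground truth). All randomness
derives from one seed through independent child streams, so identical
specs give bit-identical output.

Two generator choices deserve emphasis:

- **Intensity scale.** The 5 a.u. threshold is an absolute number whose
  meaning depends on the (unspecified) intensity scale of the recording.
  The default brightness places the threshold at ≈ 70% of a
  microdomain's blurred peak — a conservative detection cut — so that
  thresholded blob areas stay close to planted areas and the size
  classes behave as intended.
- **Separation limits.** Under σ = 2 blur and the 5 a.u. cut, two
  radius-1 discs merge into one component below ≈ 6 px centre distance,
  and a microdomain merges with a soma below ≈ 10 px; these measured
  distances are the generator's minimum-separation defaults, and the
  packing routine (round-robin greedy farthest-point placement over
  enumerated candidate pixels) raises an "infeasible packing" error when
  a request cannot honour them. This is the blur's resolution limit, not
  an arbitrary convention.

Problem sizes used in validation: the event-recovery movie is
128 × 128 × 3000 frames (10 Hz, 105 µm field) with 20 cells × 10
microdomains, near the packing limit of that field; mitochondrial
fixtures are 48 × 48 × 6000 frames with six patches; ensembles are 120
neurons × 3000 samples. These sizes keep the full suite fast while
leaving every statistical check well-powered.

The simulator deliberately omits optics (PSF, depth attenuation),
photobleaching, neuropil contamination, non-rigid motion, and
inhomogeneous/bursty event statistics. Passing the validation therefore
shows that the chain is *correct* — it reads back exactly what the model
planted, at realistic noise — not that it is robust to every artifact of
real tissue; on real data the motion-correction residuals, background
structure and overlapping processes will dominate the error budget, and
the configuration points (threshold, percentile, σ, minimum duration)
are the knobs to revisit.

## Known limitations

- Integer-only rigid motion correction; non-rigid and sub-pixel motion
  are out of scope.
- Overlapping cells are not demixed; a pixel belongs to one ROI.
- Overlapping transients within one ROI fuse into a single detected
  event (no deconvolution), biasing frequency down by a few percent at
  2 events/min and the default kinetics.
- The ensemble method is one deterministic instantiation; different
  thresholds or community algorithms give different partitions.
- "Standing" requires an annotation channel; it is not inferred.
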