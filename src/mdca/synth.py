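"""Synthetic two-photon recording generator with exact ground truth.

Emulates the statistical structure the analysis pipeline assumes: astrocyte
fields laid out as somata surrounded by punctate microdomains, each region
emitting spontaneous calcium transients as a homogeneous Poisson process;
rendering to a fluorescence movie with Poisson-Gaussian noise and optional
rigid frame jitter; correlated neuron trace matrices with planted ensembles;
behavior tracks with walking/stationary/standing epochs; and pre/post
blood-flow maps with a planted ischemic core. Every generated object is
paired with the ground truth needed to score the analysis against it.

Geometry and intensity defaults
-------------------------------
The nominal field is 420 um imaged at 512 px (0.82 um/px) and 10 Hz. Somata
are rasterized as discs of radius 5 px (~53 um^2, comfortably above the
30 um^2 soma class bound) and microdomains as discs of radius 1 px
(5 px ~ 3.4 um^2, mid-range for the 0.5-10 um^2 class). Regions sit on a
dark (zero-count) background at a resting brightness of 40 counts, chosen
so that the conventional 5 a.u. detection threshold falls at roughly 70% of
a microdomain's peak after the standard sigma = 2 px spatial blur -- i.e.
the threshold acts as the conservative detection cut it is meant to be,
and thresholded blob areas stay close to the planted areas.

A minimum centre-to-centre separation (default 7 px) keeps the blurred
footprints of neighbouring regions from bridging at that threshold, which
is the resolution limit the sigma = 2 blur imposes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .movie import CalciumMovie, DEFAULT_PIXEL_SIZE_UM

SOMA = "soma"
MICRODOMAIN = "microdomain"


# --------------------------------------------------------------------------
# specification of a simulated recording
# --------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Parameters of one simulated recording.

    Rates, durations and sizes must be strictly positive (counts and the
    jitter bound may be zero); identical seeds produce bit-identical output.
    """

    field_of_view_um: float = 420.0
    frame_size_px: int = 512
    frame_rate_hz: float = 10.0
    duration_s: float = 300.0
    n_cells: int = 10
    microdomains_per_cell: int = 10
    event_rate_per_min: float = 2.0
    event_amplitude_dff: float = 0.4
    event_duration_s: float = 1.5
    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.0
    baseline_counts: float = 30.0
    background_counts: float = 0.0
    noise_sd_counts: float = 2.4
    noise_model: str = "gaussian"  # "gaussian" or "poisson"
    jitter_max_px: int = 0
    soma_radius_px: int = 4
    microdomain_radius_px: int = 1
    min_separation_px: float = 6.0
    soma_clearance_px: float = 9.5
    seed: int = 0

    @property
    def pixel_size_um(self) -> float:
        return self.field_of_view_um / self.frame_size_px

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def validate(self) -> None:
        positive = {
            "field_of_view_um": self.field_of_view_um,
            "frame_rate_hz": self.frame_rate_hz,
            "duration_s": self.duration_s,
            "event_amplitude_dff": self.event_amplitude_dff,
            "event_duration_s": self.event_duration_s,
            "rise_tau_s": self.rise_tau_s,
            "decay_tau_s": self.decay_tau_s,
            "baseline_counts": self.baseline_counts,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.frame_size_px < 32:
            raise ValueError("frame_size_px must be at least 32")
        if self.jitter_max_px < 0:
            raise ValueError("jitter_max_px must be non-negative")
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be non-negative")
        if self.noise_sd_counts < 0:
            raise ValueError("noise_sd_counts must be non-negative")
        if self.background_counts < 0:
            raise ValueError("background_counts must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.microdomains_per_cell < 0:
            raise ValueError("microdomains_per_cell must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class Event:
    """One planted calcium transient."""

    onset_s: float
    duration_s: float
    amplitude_dff: float


@dataclass
class CellLayout:
    """Planted spatial layout: labelled blobs with classes and cell owners."""

    label_image: np.ndarray                 # H x W int32, 0 = background
    roi_class: dict[int, str]               # label -> soma | microdomain
    cell_of: dict[int, int]                 # label -> cell index (0-based)
    soma_centers: np.ndarray                # n_cells x 2 (row, col)
    pixel_size_um: float

    @property
    def labels(self) -> list[int]:
        return sorted(self.roi_class)

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def area_px(self, label: int) -> int:
        return int(np.count_nonzero(self.label_image == label))

    def area_um2(self, label: int) -> float:
        return self.area_px(label) * self.pixel_size_um ** 2

    def territory_labels(self) -> np.ndarray:
        """Voronoi partition of the frame by soma centre (cell index + 1).

        This is the ground-truth cell-grouping map: each planted blob lies
        strictly inside its own cell's basin.
        """
        h, w = self.label_image.shape
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = ((yy[None] - self.soma_centers[:, 0, None, None]) ** 2
              + (xx[None] - self.soma_centers[:, 1, None, None]) ** 2)
        return np.argmin(d2, axis=0).astype(np.int32) + 1


@dataclass
class GroundTruth:
    """Everything the simulator planted, for scoring recovered results."""

    layout: CellLayout
    event_trains: dict[int, list[Event]]    # label -> planted transients
    shifts: Optional[np.ndarray] = None     # T x 2 planted (dy, dx) jitter
    ensemble_labels: Optional[np.ndarray] = None
    flow_drop_map: Optional[np.ndarray] = None
    behavior: Optional[pd.DataFrame] = None

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {"roi_id": label, "onset_s": ev.onset_s,
             "duration_s": ev.duration_s, "amplitude_dff": ev.amplitude_dff}
            for label, train in sorted(self.event_trains.items())
            for ev in train
        ]
        return pd.DataFrame(rows, columns=["roi_id", "onset_s", "duration_s",
                                           "amplitude_dff"])


# --------------------------------------------------------------------------
# layout
# --------------------------------------------------------------------------

def _disc_offsets(radius: int) -> np.ndarray:
    """Integer offsets of the rasterized disc d^2 <= radius^2."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = yy ** 2 + xx ** 2 <= radius ** 2
    return np.stack([yy[keep], xx[keep]], axis=1)


def _grid_shape(n: int, h: int, w: int) -> tuple[int, int]:
    """Rows x cols covering n cells, aspect-matched to the frame."""
    rows = max(1, int(round(np.sqrt(n * h / w))))
    cols = int(np.ceil(n / rows))
    while rows * cols < n:
        cols += 1
    return rows, cols


def generate_cell_layout(spec: SimulationSpec,
                         rng: Optional[np.random.Generator] = None,
                         max_layout_attempts: int = 40) -> CellLayout:
    """Place somata on a jittered grid and microdomains in each cell's basin.

    Somata are discs of ``soma_radius_px``; microdomains discs of
    ``microdomain_radius_px`` scattered inside the Voronoi basin of their
    soma, at least ``soma_clearance_px`` from any soma centre and
    ``min_separation_px`` from every other microdomain (all cells), so that
    no two planted regions merge under the analysis blur. A dense draw may
    paint itself into a corner; up to ``max_layout_attempts`` fresh draws
    are made before the packing is declared infeasible.

    Raises ``ValueError`` naming the violated packing constraint when the
    requested counts cannot be placed.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    error: Exception | None = None
    for _ in range(max_layout_attempts):
        child = rng.spawn(1)[0]
        try:
            return _generate_cell_layout_once(spec, child)
        except ValueError as exc:
            if "infeasible packing" not in str(exc) \
                    or "somata of radius" in str(exc):
                raise
            error = exc
    raise ValueError(str(error))


def _generate_cell_layout_once(spec: SimulationSpec,
                               rng: np.random.Generator) -> CellLayout:
    h = w = spec.frame_size_px
    rows, cols = _grid_shape(spec.n_cells, h, w)
    # somata at the centres of an even grid partition, so every cell owns a
    # full Voronoi basin (corner cells included)
    spacing_y = h / rows
    spacing_x = w / cols
    min_spacing = min(spacing_y, spacing_x)
    if min_spacing < 2 * spec.soma_radius_px + 2:
        raise ValueError(
            f"infeasible packing: {spec.n_cells} somata of radius "
            f"{spec.soma_radius_px} px need centre spacing >= "
            f"{2 * spec.soma_radius_px + 2} px but the {h}x{w} frame "
            f"allows only {min_spacing:.1f} px")

    centers = []
    jitter = max(0.0, min(2.0, (min_spacing - 2 * spec.soma_radius_px - 2) / 2))
    for i in range(spec.n_cells):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * spacing_y + rng.uniform(-jitter, jitter)
        cx = (c + 0.5) * spacing_x + rng.uniform(-jitter, jitter)
        centers.append((int(round(cy)), int(round(cx))))
    soma_centers = np.array(centers, dtype=float)

    label_image = np.zeros((h, w), dtype=np.int32)
    roi_class: dict[int, str] = {}
    cell_of: dict[int, int] = {}
    next_label = 1

    def paint(cy: int, cx: int, radius: int, label: int) -> None:
        offs = _disc_offsets(radius)
        ys = offs[:, 0] + cy
        xs = offs[:, 1] + cx
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        label_image[ys[keep], xs[keep]] = label

    for cell, (cy, cx) in enumerate(centers):
        paint(cy, cx, spec.soma_radius_px, next_label)
        roi_class[next_label] = SOMA
        cell_of[next_label] = cell
        next_label += 1

    md_centers: list[tuple[int, int]] = []
    # blur boundary reflection brightens blobs near the frame border; an
    # edge mirror is tolerable one pixel closer than the corner's double
    # mirror, so exclude a thin border band plus the corner squares
    edge = spec.microdomain_radius_px + 1
    corner = spec.microdomain_radius_px + 2
    yy_all, xx_all = np.mgrid[edge:h - edge, edge:w - edge]
    yy_all = yy_all.ravel().astype(float)
    xx_all = xx_all.ravel().astype(float)
    in_corner = ((np.minimum(yy_all, h - 1 - yy_all) < corner)
                 & (np.minimum(xx_all, w - 1 - xx_all) < corner))
    yy_all = yy_all[~in_corner]
    xx_all = xx_all[~in_corner]
    d2_all = ((yy_all[None, :] - soma_centers[:, 0, None]) ** 2
              + (xx_all[None, :] - soma_centers[:, 1, None]) ** 2)
    nearest = np.argmin(d2_all, axis=0)
    d_sorted = np.sort(np.sqrt(d2_all), axis=0)
    clear = d_sorted[0] >= spec.soma_clearance_px
    # keep blob centres off the exact basin boundary
    if spec.n_cells > 1:
        clear &= d_sorted[1] - d_sorted[0] >= 0.5
    # greedy maximin (farthest-point) placement approaches hexagonal
    # packing density, which random darts cannot reach in tight basins;
    # cells are served round-robin so boundary zones are shared fairly
    cell_cands: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for cell in range(spec.n_cells):
        idx = np.flatnonzero((nearest == cell) & clear)
        cell_cands[cell] = (yy_all[idx], xx_all[idx],
                            np.full(idx.size, np.inf))
    placed_per_cell = [0] * spec.n_cells
    for _round in range(spec.microdomains_per_cell):
        for cell in range(spec.n_cells):
            cys, cxs, dmin = cell_cands[cell]
            if cys.size == 0:
                raise ValueError(
                    "infeasible packing: could not place "
                    f"{spec.microdomains_per_cell} microdomains for cell "
                    f"{cell} with min_separation_px="
                    f"{spec.min_separation_px} and soma_clearance_px="
                    f"{spec.soma_clearance_px} in a {h}x{w} frame")
            if np.isinf(dmin).all():
                pick = int(rng.integers(cys.size))
            else:
                near = np.flatnonzero(dmin >= dmin.max() - 0.5)
                pick = int(near[rng.integers(near.size)])
            my, mx = int(cys[pick]), int(cxs[pick])
            md_centers.append((my, mx))
            paint(my, mx, spec.microdomain_radius_px, next_label)
            roi_class[next_label] = MICRODOMAIN
            cell_of[next_label] = cell
            next_label += 1
            placed_per_cell[cell] += 1
            for other, (oys, oxs, odmin) in cell_cands.items():
                d = np.hypot(oys - my, oxs - mx)
                keep = d >= spec.min_separation_px
                cell_cands[other] = (oys[keep], oxs[keep],
                                     np.minimum(odmin, d)[keep])

    return CellLayout(label_image=label_image, roi_class=roi_class,
                      cell_of=cell_of, soma_centers=soma_centers,
                      pixel_size_um=spec.pixel_size_um)


# --------------------------------------------------------------------------
# event trains and the transient kernel
# --------------------------------------------------------------------------

def generate_event_train(rate_per_min: float, duration_s: float,
                         amplitude_dff: float, event_duration_s: float,
                         rng: np.random.Generator) -> list[Event]:
    """Draw transient onsets from a homogeneous Poisson process.

    The number of events is Poisson with mean ``rate * duration`` and
    onsets are uniform on [0, duration_s), sorted.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be non-negative")
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n))
    return [Event(onset_s=float(t), duration_s=event_duration_s,
                  amplitude_dff=amplitude_dff) for t in onsets]


def transient_kernel(t: np.ndarray, rise_tau_s: float,
                     decay_tau_s: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak.

    ``k(t) = exp(-t/decay) - exp(-t/rise)`` for t >= 0, scaled so its
    maximum is exactly 1; an event of amplitude ``a`` therefore peaks at
    dF/F = a. Degenerates to the alpha function when the taus coincide.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    if abs(rise_tau_s - decay_tau_s) < 1e-12:
        tau = decay_tau_s
        out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
        return out
    tp = (np.log(decay_tau_s / rise_tau_s)
          * rise_tau_s * decay_tau_s / (decay_tau_s - rise_tau_s))
    peak = np.exp(-tp / decay_tau_s) - np.exp(-tp / rise_tau_s)
    out[pos] = (np.exp(-t[pos] / decay_tau_s)
                - np.exp(-t[pos] / rise_tau_s)) / peak
    return out


def dff_trace_from_train(train: list[Event], n_frames: int,
                         frame_rate_hz: float, rise_tau_s: float,
                         decay_tau_s: float) -> np.ndarray:
    """Noiseless dF/F time course of one region from its planted train."""
    t = np.arange(n_frames) / frame_rate_hz
    dff = np.zeros(n_frames)
    for ev in train:
        dff += ev.amplitude_dff * transient_kernel(t - ev.onset_s,
                                                   rise_tau_s, decay_tau_s)
    return dff


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_movie(layout: CellLayout, event_trains: dict[int, list[Event]],
                 spec: SimulationSpec,
                 rng: Optional[np.random.Generator] = None,
                 ) -> tuple[CalciumMovie, np.ndarray]:
    """Render a layout plus event trains into a noisy fluorescence movie.

    The noiseless pixel value is ``background_counts`` outside regions and
    ``baseline_counts * (1 + dF/F(t))`` inside each region, with dF/F(t)
    the region's summed transient kernel. Gaussian noise of sd
    ``noise_sd_counts`` (or Poisson shot noise) is added, then an optional
    per-frame integer rigid jitter of at most ``jitter_max_px`` (periodic
    shift, recorded and returned as the T x 2 planted (dy, dx) array).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    h, w = layout.label_image.shape
    data = np.full((n_frames, h, w), spec.background_counts, dtype=np.float32)
    for label in layout.labels:
        mask = layout.mask(label)
        train = event_trains.get(label, [])
        dff = dff_trace_from_train(train, n_frames, spec.frame_rate_hz,
                                   spec.rise_tau_s, spec.decay_tau_s)
        data[:, mask] = (spec.baseline_counts
                         * (1.0 + dff[:, None])).astype(np.float32)

    if spec.noise_model == "poisson":
        data = rng.poisson(np.maximum(data, 0.0)).astype(np.float32)
    elif spec.noise_sd_counts > 0:
        noise = rng.standard_normal(size=data.shape, dtype=np.float32)
        noise *= spec.noise_sd_counts
        data += noise
        del noise

    shifts = np.zeros((n_frames, 2), dtype=int)
    if spec.jitter_max_px > 0:
        shifts = rng.integers(-spec.jitter_max_px, spec.jitter_max_px + 1,
                              size=(n_frames, 2))
        for t in range(n_frames):
            data[t] = np.roll(data[t], tuple(shifts[t]), axis=(0, 1))

    movie = CalciumMovie(data=data, frame_rate_hz=spec.frame_rate_hz,
                         pixel_size_um=spec.pixel_size_um)
    return movie, shifts


# --------------------------------------------------------------------------
# correlated neuron traces
# --------------------------------------------------------------------------

def generate_correlated_traces(n_neurons: int, n_ensembles: int,
                               within_corr: float, duration_s: float,
                               rng: np.random.Generator,
                               frame_rate_hz: float = 10.0,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Shared-latent traces with planted ensemble structure.

    Each neuron's trace is ``sqrt(rho) * latent[ensemble] +
    sqrt(1 - rho) * private``, with unit-variance Gaussian latents, giving
    expected pairwise correlation ``rho`` within an ensemble and 0 across.
    Returns (n_neurons x T trace matrix, per-neuron ensemble labels).
    """
    if not 0.0 <= within_corr <= 1.0:
        raise ValueError("within_corr must lie in [0, 1]")
    if n_ensembles > n_neurons:
        raise ValueError("n_ensembles cannot exceed n_neurons")
    if n_ensembles < 1:
        raise ValueError("need at least one ensemble")
    n_samples = int(round(duration_s * frame_rate_hz))
    labels = np.repeat(np.arange(n_ensembles),
                       int(np.ceil(n_neurons / n_ensembles)))[:n_neurons]
    latents = rng.standard_normal((n_ensembles, n_samples))
    private = rng.standard_normal((n_neurons, n_samples))
    traces = (np.sqrt(within_corr) * latents[labels]
              + np.sqrt(1.0 - within_corr) * private)
    return traces, labels


# --------------------------------------------------------------------------
# blood-flow maps
# --------------------------------------------------------------------------

def generate_flow_maps(core_drop: float, peri_drop: float,
                       shape: tuple[int, int] = (128, 128),
                       core_center: Optional[tuple[int, int]] = None,
                       core_radius_px: float = 24.0,
                       peri_width_px: float = 20.0,
                       baseline_flow: float = 100.0,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre/post blood-flow maps with a circular core and a peri annulus.

    The fractional drop equals ``core_drop`` inside the core disc,
    ``peri_drop`` in the surrounding annulus of width ``peri_width_px`` and
    0 elsewhere; ``post = pre * (1 - drop)``. Returns (pre, post, drop).
    """
    for name, v in (("core_drop", core_drop), ("peri_drop", peri_drop)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    h, w = shape
    if core_center is None:
        core_center = (h // 2, w // 2)
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.sqrt((yy - core_center[0]) ** 2 + (xx - core_center[1]) ** 2)
    drop = np.zeros(shape, dtype=float)
    drop[d <= core_radius_px] = core_drop
    annulus = (d > core_radius_px) & (d <= core_radius_px + peri_width_px)
    drop[annulus] = peri_drop
    pre = np.full(shape, baseline_flow, dtype=float)
    post = pre * (1.0 - drop)
    return pre, post, drop


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def generate_behavior(duration_s: float, rng: np.random.Generator,
                      sample_rate_hz: float = 25.0,
                      mean_epoch_s: float = 10.0,
                      walk_speed_cm_s: float = 5.0,
                      stand_prob: float = 0.3) -> pd.DataFrame:
    """Simulated open-field behavior: epochs of walking / stationary / standing.

    Epoch durations are exponential with mean ``mean_epoch_s`` (floored at
    1 s); during walking the centroid moves at ``walk_speed_cm_s`` along a
    smoothly wandering heading, otherwise it stays put. A fraction
    ``stand_prob`` of non-walking epochs is labelled standing (rearing is
    scored as an annotation, not derived from the track). Returns a frame
    per sample with columns time_s, state, x_cm, y_cm.
    """
    n = int(round(duration_s * sample_rate_hz))
    dt = 1.0 / sample_rate_hz
    states = np.empty(n, dtype=object)
    i = 0
    walking = bool(rng.integers(0, 2))
    while i < n:
        dur = max(1.0, rng.exponential(mean_epoch_s))
        n_epoch = min(n - i, max(1, int(round(dur * sample_rate_hz))))
        if walking:
            states[i:i + n_epoch] = "walking"
        else:
            label = "standing" if rng.uniform() < stand_prob else "stationary"
            states[i:i + n_epoch] = label
        i += n_epoch
        walking = not walking
    heading = np.cumsum(rng.normal(0.0, 0.3, size=n))
    speed = np.where(states == "walking",
                     np.maximum(0.0, rng.normal(walk_speed_cm_s, 0.5, size=n)),
                     0.0)
    x = np.concatenate([[0.0], np.cumsum(speed * np.cos(heading) * dt)[:-1]])
    y = np.concatenate([[0.0], np.cumsum(speed * np.sin(heading) * dt)[:-1]])
    return pd.DataFrame({"time_s": np.arange(n) * dt, "state": states,
                         "x_cm": x, "y_cm": y})


# --------------------------------------------------------------------------
# full recording
# --------------------------------------------------------------------------

@dataclass
class SimulatedRecording:
    movie: CalciumMovie
    ground_truth: GroundTruth
    spec: SimulationSpec


def simulate_recording(spec: SimulationSpec,
                       with_behavior: bool = False) -> SimulatedRecording:
    """Generate a complete recording: layout, trains, movie and ground truth.

    All randomness flows from ``spec.seed`` through independent child
    streams per component (layout, trains, rendering noise, behavior), so
    the output is bit-identical for identical specs.
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    rng_layout, rng_trains, rng_render, rng_behavior = root.spawn(4)
    layout = generate_cell_layout(spec, rng_layout)
    trains = {
        label: generate_event_train(spec.event_rate_per_min, spec.duration_s,
                                    spec.event_amplitude_dff,
                                    spec.event_duration_s, rng_trains)
        for label in layout.labels
    }
    movie, shifts = render_movie(layout, trains, spec, rng_render)
    behavior = (generate_behavior(spec.duration_s, rng_behavior)
                if with_behavior else None)
    gt = GroundTruth(layout=layout, event_trains=trains, shifts=shifts,
                     behavior=behavior)
    return SimulatedRecording(movie=movie, ground_truth=gt, spec=spec)
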