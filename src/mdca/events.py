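"""dF/F conversion, baseline estimation, and 2 x s.d. event detection.

For each ROI the fluorescence of all member pixels is averaged into a
single time course F(t). The basal fluorescence F0 is the mean of the
contiguous 20-s window with minimal variance ("no fluctuations"
operationalized as the quietest window, scanned at one-frame stride).
dF/F = (F - F0) / F0 is smoothed with a centred 300-ms moving average
(3 frames at 10 Hz); the s.d. of the smoothed trace inside the F0 window
sets the detection threshold, and an event is each maximal run of frames
with dF/F > k * s.d. (k = 2).

A minimum event duration (default 0.7 s) debounces threshold crossings:
with a 2-s.d. cut on a smoothed Gaussian baseline, chance excursions of a
frame or two are common at any signal-to-noise ratio, while astrocyte
transients last on the order of seconds, so very short runs are noise by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import CalciumMovie
from .segment import ROISet

EVENT_COLUMNS = ["roi_id", "onset_s", "offset_s", "duration_s",
                 "peak_amplitude", "mean_amplitude"]
SUMMARY_COLUMNS = ["roi_id", "roi_class", "n_events", "frequency_per_min",
                   "mean_peak_amplitude", "mean_amplitude",
                   "mean_duration_s", "f0", "sd"]


def estimate_f0(trace: np.ndarray, frame_rate_hz: float,
                window_s: float = 20.0) -> tuple[float, slice]:
    """Basal fluorescence from the quietest contiguous ``window_s`` span.

    Scans every window at one-frame stride and returns the mean of the one
    with minimal variance, together with its frame slice. Traces shorter
    than the window are an error.
    """
    trace = np.asarray(trace, dtype=float)
    n = int(round(window_s * frame_rate_hz))
    if trace.size < n:
        raise ValueError(
            f"trace of {trace.size / frame_rate_hz:.1f} s is shorter than "
            f"the {window_s:.0f} s baseline window")
    # sliding mean and variance via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(trace)])
    c2 = np.concatenate([[0.0], np.cumsum(trace ** 2)])
    sums = c1[n:] - c1[:-n]
    sqsums = c2[n:] - c2[:-n]
    means = sums / n
    variances = np.maximum(sqsums / n - means ** 2, 0.0)
    start = int(np.argmin(variances))
    return float(means[start]), slice(start, start + n)


def compute_dff(trace: np.ndarray, f0: float, frame_rate_hz: float,
                smooth_window_s: float = 0.3) -> np.ndarray:
    """(F - F0) / F0, smoothed with a centred moving average.

    The window is ``smooth_window_s`` (300 ms = 3 frames at 10 Hz); edges
    repeat the boundary value. F0 must be positive.
    """
    if f0 <= 0:
        raise ValueError(f"F0 must be positive, got {f0}")
    dff = (np.asarray(trace, dtype=float) - f0) / f0
    size = max(1, int(round(smooth_window_s * frame_rate_hz)))
    if size > 1:
        dff = ndimage.uniform_filter1d(dff, size=size, mode="nearest")
    return dff


def detect_events(dff: np.ndarray, sd: float, frame_rate_hz: float,
                  k: float = 2.0, min_duration_s: float = 0.7,
                  roi_id: int = 0) -> pd.DataFrame:
    """Maximal runs of smoothed dF/F above ``k * sd`` lasting at least
    ``min_duration_s``.

    Onset is the first frame of the run, offset one past the last (so
    duration = run length / frame rate); peak and mean amplitudes are
    taken over the run. A zero s.d. (constant trace) yields no events and
    a warning.
    """
    dff = np.asarray(dff, dtype=float)
    if sd <= 0:
        warnings.warn("baseline s.d. is zero; no events can be detected",
                      stacklevel=2)
        return pd.DataFrame(columns=EVENT_COLUMNS)
    threshold = k * sd
    above = dff > threshold
    if not above.any():
        return pd.DataFrame(columns=EVENT_COLUMNS)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    min_frames = max(1, int(round(min_duration_s * frame_rate_hz)))
    rows = []
    for s, e in zip(starts, ends):
        if e - s < min_frames:
            continue
        segment = dff[s:e]
        rows.append({
            "roi_id": roi_id,
            "onset_s": s / frame_rate_hz,
            "offset_s": e / frame_rate_hz,
            "duration_s": (e - s) / frame_rate_hz,
            "peak_amplitude": float(segment.max()),
            "mean_amplitude": float(segment.mean()),
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@dataclass
class TraceAnalysis:
    """Per-trace event detection output."""

    events: pd.DataFrame
    f0: float
    sd: float
    dff: np.ndarray


def analyze_trace(trace: np.ndarray, frame_rate_hz: float,
                  roi_id: int = 0, k: float = 2.0,
                  min_duration_s: float = 0.7,
                  baseline_window_s: float = 20.0,
                  smooth_window_s: float = 0.3,
                  sd_scope: str = "f0_window",
                  f0: Optional[float] = None) -> TraceAnalysis:
    """Full single-trace chain: F0, smoothed dF/F, s.d., event detection.

    ``sd_scope`` selects whether the detection s.d. is computed inside the
    F0 window (default) or over the whole trace. Passing ``f0`` overrides
    baseline estimation (used with known synthetic baselines); the s.d.
    then still comes from the quietest window.
    """
    f0_est, window = estimate_f0(trace, frame_rate_hz, baseline_window_s)
    if f0 is None:
        f0 = f0_est
    dff = compute_dff(trace, f0, frame_rate_hz, smooth_window_s)
    if sd_scope == "f0_window":
        sd = float(np.std(dff[window]))
    elif sd_scope == "whole_trace":
        sd = float(np.std(dff))
    else:
        raise ValueError(f"unknown sd_scope {sd_scope!r}")
    events = detect_events(dff, sd, frame_rate_hz, k=k,
                           min_duration_s=min_duration_s, roi_id=roi_id)
    return TraceAnalysis(events=events, f0=float(f0), sd=sd, dff=dff)


def extract_traces(movie: CalciumMovie, rois: ROISet,
                   roi_ids: Optional[list[int]] = None,
                   detection_image: Optional[np.ndarray] = None,
                   core_fraction: float = 0.0) -> dict[int, np.ndarray]:
    """Mean fluorescence time course of each ROI's pixels.

    With a ``detection_image`` and ``core_fraction`` > 0 the average is
    restricted to the ROI's bright core -- pixels at or above that
    fraction of the ROI's peak detection-image value. On spatially
    blurred movies this suppresses cross-talk from the halos of
    neighbouring regions, which otherwise dilutes dF/F amplitudes.
    """
    if roi_ids is None:
        roi_ids = [int(i) for i in rois.table["roi_id"]]
    traces = {}
    for roi_id in roi_ids:
        mask = rois.mask(roi_id)
        if not mask.any():
            continue
        if detection_image is not None and core_fraction > 0:
            cut = core_fraction * detection_image[mask].max()
            core = mask & (detection_image >= cut)
            if core.any():
                mask = core
        traces[roi_id] = movie.data[:, mask].mean(axis=1).astype(float)
    return traces


def analyze_traces(traces: dict[int, np.ndarray], frame_rate_hz: float,
                   classes: Optional[dict[int, str]] = None,
                   **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the event chain over many traces.

    Returns (event table, per-ROI summary). The summary includes events
    per minute, the per-ROI means of peak amplitude / mean amplitude /
    duration (NaN when the ROI has no events), and the baseline estimates.
    """
    all_events = []
    summary_rows = []
    for roi_id, trace in sorted(traces.items()):
        duration_s = len(trace) / frame_rate_hz
        if duration_s <= 0:
            raise ValueError("zero-duration trace")
        result = analyze_trace(trace, frame_rate_hz, roi_id=roi_id, **kwargs)
        ev = result.events
        all_events.append(ev)
        summary_rows.append({
            "roi_id": roi_id,
            "roi_class": classes.get(roi_id, "") if classes else "",
            "n_events": len(ev),
            "frequency_per_min": len(ev) / (duration_s / 60.0),
            "mean_peak_amplitude": ev["peak_amplitude"].mean()
                if len(ev) else np.nan,
            "mean_amplitude": ev["mean_amplitude"].mean()
                if len(ev) else np.nan,
            "mean_duration_s": ev["duration_s"].mean() if len(ev) else np.nan,
            "f0": result.f0,
            "sd": result.sd,
        })
    non_empty = [ev for ev in all_events if len(ev)]
    events = (pd.concat(non_empty, ignore_index=True)
              if non_empty else pd.DataFrame(columns=EVENT_COLUMNS))
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    return events, summary


def event_metrics(events: pd.DataFrame, trace_duration_s: float,
                  classes: Optional[dict[int, str]] = None) -> pd.DataFrame:
    """Per-ROI summary from an event table alone.

    frequency = events / (duration in minutes); amplitude and duration
    summaries are NaN for ROIs without events (callers list such ROIs in
    the table with zero rows to have them reported).
    """
    if trace_duration_s <= 0:
        raise ValueError("trace duration must be positive")
    minutes = trace_duration_s / 60.0
    rows = []
    for roi_id, group in events.groupby("roi_id"):
        rows.append({
            "roi_id": int(roi_id),
            "roi_class": classes.get(int(roi_id), "") if classes else "",
            "n_events": len(group),
            "frequency_per_min": len(group) / minutes,
            "mean_peak_amplitude": group["peak_amplitude"].mean(),
            "mean_amplitude": group["mean_amplitude"].mean(),
            "mean_duration_s": group["duration_s"].mean(),
            "f0": np.nan,
            "sd": np.nan,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
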