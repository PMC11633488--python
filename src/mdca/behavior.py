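"""Behavior-state labelling, alignment to imaging, scores, field selection.

Behavior video is sampled at 25 Hz; the centroid track yields a walking /
stationary classification (walking = smoothed speed above a threshold
sustained for a minimum epoch), while standing (rearing) cannot be derived
from a 2-D centroid and is accepted as an explicit annotation channel.
States are mapped onto 10-Hz imaging frames by nearest timestamp, events
are attributed to the state at their onset, and per-state frequencies are
normalized by the time spent in each state.

Behavioral scores follow the standard formulas: the grid-walking
foot-fault percentage, faults / (faults + non-faults) x 100, and the
cylinder forelimb-asymmetry score, (right - left) / (right + left + both).

Peri-infarct field selection applies the blood-flow rules: a candidate
field with over 35% flow reduction is ischemic core; fields adjacent to a
core field with a reduction in the closed interval [15%, 25%] are the
target peri-infarct fields; an animal with no target field is excluded.
An injection-site reduction within [40%, 60%] marks a usable stroke model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

WALKING = "walking"
STATIONARY = "stationary"
STANDING = "standing"

CORE = "core"
PERI_TARGET = "peri_target"
REJECT = "reject"

CORE_MIN_REDUCTION = 0.35          # strict: reduction > 35% -> core
PERI_REDUCTION_RANGE = (0.15, 0.25)  # closed interval
MODEL_REDUCTION_RANGE = (0.40, 0.60)  # closed interval


# --------------------------------------------------------------------------
# state labelling and alignment
# --------------------------------------------------------------------------

def label_state_epochs(track: pd.DataFrame,
                       speed_threshold_cm_s: float = 0.5,
                       min_epoch_s: float = 0.5,
                       smooth_s: float = 0.2,
                       standing: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Classify each 25-Hz sample as walking / stationary / standing.

    Walking requires the smoothed centroid speed to exceed
    ``speed_threshold_cm_s`` continuously for at least ``min_epoch_s``;
    all other samples are stationary unless the ``standing`` annotation
    (boolean per sample) marks them as standing. Returns a copy of the
    track with a ``state`` column.
    """
    track = track.reset_index(drop=True).copy()
    t = track["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("track needs at least two samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = float(np.median(np.diff(t)))
    dx = np.gradient(track["x_cm"].to_numpy(dtype=float), t)
    dy = np.gradient(track["y_cm"].to_numpy(dtype=float), t)
    speed = np.hypot(dx, dy)
    size = max(1, int(round(smooth_s / dt)))
    if size > 1:
        speed = ndimage.uniform_filter1d(speed, size=size, mode="nearest")

    fast = speed > speed_threshold_cm_s
    min_samples = max(1, int(round(min_epoch_s / dt)))
    walking = np.zeros_like(fast)
    labels, n_runs = ndimage.label(fast)
    for run in range(1, n_runs + 1):
        run_mask = labels == run
        if run_mask.sum() >= min_samples:
            walking[run_mask] = True

    state = np.where(walking, WALKING, STATIONARY).astype(object)
    if standing is not None:
        standing = np.asarray(standing, dtype=bool)
        if standing.shape != state.shape:
            raise ValueError("standing annotation must match track length")
        state[standing & ~walking] = STANDING
    track["state"] = state
    track["speed_cm_s"] = speed
    return track


def states_at_frames(behavior: pd.DataFrame, n_frames: int,
                     frame_rate_hz: float) -> np.ndarray:
    """State of each imaging frame, by nearest behavior timestamp."""
    t_beh = behavior["time_s"].to_numpy(dtype=float)
    t_img = np.arange(n_frames) / frame_rate_hz
    idx = np.searchsorted(t_beh, t_img)
    idx = np.clip(idx, 1, len(t_beh) - 1)
    left_closer = (t_img - t_beh[idx - 1]) <= (t_beh[idx] - t_img)
    nearest = np.where(left_closer, idx - 1, idx)
    return behavior["state"].to_numpy(dtype=object)[nearest]


def travel_distance(track: pd.DataFrame, window_s: float = 300.0) -> float:
    """Path length (cm): sum of Euclidean steps within the first
    ``window_s`` seconds of the track."""
    if len(track) < 2:
        raise ValueError("track needs at least two samples")
    sel = track[track["time_s"] <= track["time_s"].iloc[0] + window_s]
    dx = np.diff(sel["x_cm"].to_numpy(dtype=float))
    dy = np.diff(sel["y_cm"].to_numpy(dtype=float))
    return float(np.sum(np.hypot(dx, dy)))


def state_conditioned_stats(events: pd.DataFrame, frame_states: np.ndarray,
                            frame_rate_hz: float,
                            states: Iterable[str] = (WALKING, STATIONARY,
                                                     STANDING),
                            ) -> pd.DataFrame:
    """Event statistics conditioned on the behavior state at event onset.

    For each state: total time spent (s), event count, events per minute
    of that state, and amplitude summaries. States never visited report
    NaN frequency.
    """
    frame_states = np.asarray(frame_states, dtype=object)
    onset_frames = np.round(events["onset_s"].to_numpy(dtype=float)
                            * frame_rate_hz).astype(int)
    onset_frames = np.clip(onset_frames, 0, len(frame_states) - 1)
    event_states = frame_states[onset_frames]
    rows = []
    for state in states:
        time_s = float(np.sum(frame_states == state) / frame_rate_hz)
        sel = events[event_states == state]
        rows.append({
            "state": state,
            "time_s": time_s,
            "n_events": len(sel),
            "frequency_per_min": (len(sel) / (time_s / 60.0)
                                  if time_s > 0 else np.nan),
            "mean_peak_amplitude": sel["peak_amplitude"].mean()
                if len(sel) else np.nan,
            "mean_duration_s": sel["duration_s"].mean()
                if len(sel) else np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# behavioral test scores
# --------------------------------------------------------------------------

def foot_fault_ratio(n_faults: int, n_non_faults: int) -> float:
    """Grid-walking score per limb: faults / (faults + non-faults) x 100%."""
    if n_faults < 0 or n_non_faults < 0:
        raise ValueError("step counts must be non-negative")
    total = n_faults + n_non_faults
    if total == 0:
        raise ValueError("no steps recorded; foot-fault ratio undefined")
    return 100.0 * n_faults / total


def cylinder_score(n_right: int, n_left: int, n_both: int) -> float:
    """Cylinder-test asymmetry: (right - left) / (right + left + both)."""
    if min(n_right, n_left, n_both) < 0:
        raise ValueError("touch counts must be non-negative")
    total = n_right + n_left + n_both
    if total == 0:
        raise ValueError("no wall touches recorded; score undefined")
    return (n_right - n_left) / total


# --------------------------------------------------------------------------
# peri-infarct field selection
# --------------------------------------------------------------------------

@dataclass
class FieldSelection:
    """Outcome of the blood-flow screen over candidate imaging fields."""

    table: pd.DataFrame          # field_id, pre, post, reduction, verdict
    animal_included: bool        # at least one peri-infarct target field
    model_included: Optional[bool] = None  # injection-site drop in [40, 60]%


def flow_reduction(pre: float, post: float) -> float:
    """Fractional blood-flow reduction 1 - post/pre."""
    if pre <= 0:
        raise ValueError("pre-stroke flow must be positive")
    return 1.0 - post / pre


def select_peri_infarct_fields(fields: pd.DataFrame,
                               adjacency: Mapping[int, Iterable[int]],
                               injection_site_reduction: Optional[float] = None,
                               ) -> FieldSelection:
    """Apply the flow-reduction rules to candidate fields.

    ``fields`` needs columns field_id, pre, post. ``adjacency`` maps field
    id to the ids of neighbouring fields. Verdicts: reduction > 35% ->
    core; reduction within [15%, 25%] and adjacent to a core field ->
    peri_target; otherwise reject. The animal is included only if at
    least one peri_target exists. If given, the injection-site reduction
    is checked against the [40%, 60%] stroke-model inclusion window.
    """
    fields = fields.reset_index(drop=True).copy()
    fields["reduction"] = [
        flow_reduction(p, q) for p, q in zip(fields["pre"], fields["post"])
    ]
    core_ids = set(fields.loc[fields["reduction"] > CORE_MIN_REDUCTION,
                              "field_id"].astype(int))
    lo, hi = PERI_REDUCTION_RANGE
    verdicts = []
    for _, row in fields.iterrows():
        fid = int(row["field_id"])
        if fid in core_ids:
            verdicts.append(CORE)
        elif (lo <= row["reduction"] <= hi
              and any(int(n) in core_ids for n in adjacency.get(fid, ()))):
            verdicts.append(PERI_TARGET)
        else:
            verdicts.append(REJECT)
    fields["verdict"] = verdicts
    included = PERI_TARGET in verdicts
    model = None
    if injection_site_reduction is not None:
        mlo, mhi = MODEL_REDUCTION_RANGE
        model = mlo <= injection_site_reduction <= mhi
    return FieldSelection(table=fields, animal_included=included,
                          model_included=model)


def fields_from_flow_maps(pre_map: np.ndarray, post_map: np.ndarray,
                          boxes: list[tuple[slice, slice]],
                          ) -> pd.DataFrame:
    """Summarize candidate fields as mean pre/post flow over pixel boxes."""
    rows = []
    for i, (ys, xs) in enumerate(boxes):
        rows.append({"field_id": i,
                     "pre": float(np.mean(pre_map[ys, xs])),
                     "post": float(np.mean(post_map[ys, xs]))})
    return pd.DataFrame(rows)
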