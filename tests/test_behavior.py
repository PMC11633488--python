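"""Behavior states, alignment, scores, and peri-infarct field selection."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mdca.behavior import (cylinder_score, fields_from_flow_maps,
                           flow_reduction, foot_fault_ratio,
                           label_state_epochs, select_peri_infarct_fields,
                           state_conditioned_stats, states_at_frames,
                           travel_distance, WALKING, STATIONARY, STANDING,
                           CORE, PERI_TARGET, REJECT)
from mdca.synth import generate_behavior, generate_flow_maps


def _track(speeds_cm_s, rate=25.0):
    n = len(speeds_cm_s)
    dt = 1.0 / rate
    x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds_cm_s) * dt)[:-1]])
    return pd.DataFrame({"time_s": np.arange(n) * dt, "x_cm": x,
                         "y_cm": np.zeros(n)})


class TestStates:
    def test_zero_speed_all_stationary(self):
        track = label_state_epochs(_track([0.0] * 100))
        assert (track["state"] == STATIONARY).all()

    def test_constant_speed_all_walking(self):
        track = label_state_epochs(_track([5.0] * 100),
                                   speed_threshold_cm_s=0.5)
        assert (track["state"] == WALKING).all()

    def test_brief_spurt_below_min_epoch_stays_stationary(self):
        speeds = [0.0] * 50 + [5.0] * 5 + [0.0] * 50   # 0.2 s of motion
        track = label_state_epochs(_track(speeds), min_epoch_s=0.5)
        assert (track["state"] == STATIONARY).all()

    def test_standing_annotation_channel(self):
        standing = np.zeros(100, dtype=bool)
        standing[40:60] = True
        track = label_state_epochs(_track([0.0] * 100), standing=standing)
        assert (track["state"][40:60] == STANDING).all()
        assert (track["state"][:40] == STATIONARY).all()

    def test_nearest_timestamp_mapping(self):
        behavior = label_state_epochs(_track([0.0] * 250))
        behavior.loc[125:, "state"] = WALKING         # walking from t = 5 s
        states = states_at_frames(behavior, n_frames=100, frame_rate_hz=10.0)
        assert states[49] == STATIONARY               # t = 4.9 s
        assert states[51] == WALKING                  # t = 5.1 s

    def test_state_times_sum_to_recording(self):
        rng = np.random.default_rng(0)
        behavior = generate_behavior(60.0, rng)
        behavior = label_state_epochs(behavior,
                                      standing=(behavior["state"]
                                                == STANDING).to_numpy())
        states = states_at_frames(behavior, 600, 10.0)
        stats = state_conditioned_stats(
            pd.DataFrame(columns=["onset_s", "peak_amplitude",
                                  "duration_s"]), states, 10.0)
        assert stats["time_s"].sum() == pytest.approx(60.0)


class TestTravelDistance:
    def test_straight_path(self):
        track = pd.DataFrame({"time_s": [0.0, 1.0], "x_cm": [0.0, 3.0],
                              "y_cm": [0.0, 4.0]})
        assert travel_distance(track) == pytest.approx(5.0)

    def test_stationary_zero(self):
        track = _track([0.0] * 50)
        assert travel_distance(track) == 0.0

    def test_closed_square_loop(self):
        track = pd.DataFrame({
            "time_s": [0, 1, 2, 3, 4],
            "x_cm": [0.0, 1.0, 1.0, 0.0, 0.0],
            "y_cm": [0.0, 0.0, 1.0, 1.0, 0.0]})
        assert travel_distance(track) == pytest.approx(4.0)

    def test_window_limits_distance(self):
        track = pd.DataFrame({"time_s": [0, 100, 400],
                              "x_cm": [0.0, 3.0, 103.0],
                              "y_cm": [0.0, 4.0, 4.0]})
        assert travel_distance(track, window_s=300.0) == pytest.approx(5.0)


class TestStateConditionedStats:
    def test_all_events_during_walking(self):
        frame_states = np.array([WALKING] * 600, dtype=object)
        events = pd.DataFrame({"onset_s": [5.0, 25.0],
                               "peak_amplitude": [0.5, 0.4],
                               "duration_s": [1.0, 2.0]})
        stats = state_conditioned_stats(events, frame_states, 10.0)
        walking = stats[stats.state == WALKING].iloc[0]
        assert walking["frequency_per_min"] == pytest.approx(2.0)
        stationary = stats[stats.state == STATIONARY].iloc[0]
        assert np.isnan(stationary["frequency_per_min"])

    def test_planted_state_dependent_rates_recovered(self):
        # walking 2.0 and stationary 1.0 events/min, trace-level simulation
        rng = np.random.default_rng(3)
        n_frames = 10 * 7200 * 2                      # 2 h per state
        frame_states = np.array([WALKING, STATIONARY] * (n_frames // 2),
                                dtype=object)
        rate = {WALKING: 2.0, STATIONARY: 1.0}
        p = np.array([rate[s] / 60.0 / 10.0 for s in frame_states])
        onset_frames = np.flatnonzero(rng.uniform(size=n_frames) < p)
        events = pd.DataFrame({"onset_s": onset_frames / 10.0,
                               "peak_amplitude": 0.4, "duration_s": 1.0})
        stats = state_conditioned_stats(events, frame_states, 10.0)
        walking = stats[stats.state == WALKING].iloc[0]["frequency_per_min"]
        stationary = stats[stats.state == STATIONARY].iloc[0][
            "frequency_per_min"]
        assert walking == pytest.approx(2.0, rel=0.15)
        assert stationary == pytest.approx(1.0, rel=0.15)


class TestScores:
    def test_foot_fault_example(self):
        assert foot_fault_ratio(5, 15) == pytest.approx(25.0)

    def test_no_faults(self):
        assert foot_fault_ratio(0, 20) == 0.0

    def test_no_steps_rejected(self):
        with pytest.raises(ValueError):
            foot_fault_ratio(0, 0)

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=200, derandomize=True)
    def test_foot_fault_matches_exact_fraction(self, faults, non_faults):
        if faults + non_faults == 0:
            return
        expected = Fraction(100 * faults, faults + non_faults)
        assert foot_fault_ratio(faults, non_faults) == pytest.approx(
            float(expected))

    def test_cylinder_example(self):
        assert cylinder_score(10, 5, 5) == pytest.approx(0.25)

    def test_cylinder_symmetry(self):
        for both in (0, 3, 9):
            assert cylinder_score(7, 7, both) == 0.0

    def test_cylinder_no_touches_rejected(self):
        with pytest.raises(ValueError):
            cylinder_score(0, 0, 0)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=200, derandomize=True)
    def test_cylinder_matches_exact_fraction(self, r, l, b):
        if r + l + b == 0:
            return
        expected = Fraction(r - l, r + l + b)
        got = cylinder_score(r, l, b)
        assert got == pytest.approx(float(expected))
        assert -1.0 <= got <= 1.0


class TestFieldSelection:
    def _fields(self, reductions, pre=100.0):
        return pd.DataFrame({
            "field_id": range(len(reductions)),
            "pre": pre,
            "post": [pre * (1 - r) for r in reductions]})

    def test_paper_rule_outcome(self):
        fields = self._fields([0.40, 0.20, 0.22, 0.10, 0.05, 0.30])
        adjacency = {0: [1, 2], 1: [0], 2: [0], 3: [4], 4: [3], 5: []}
        sel = select_peri_infarct_fields(fields, adjacency)
        verdicts = dict(zip(sel.table.field_id, sel.table.verdict))
        assert verdicts == {0: CORE, 1: PERI_TARGET, 2: PERI_TARGET,
                            3: REJECT, 4: REJECT, 5: REJECT}
        assert sel.animal_included

    def test_no_core_excludes_animal(self):
        fields = self._fields([0.30, 0.20, 0.10])
        sel = select_peri_infarct_fields(fields, {0: [1], 1: [0, 2], 2: [1]})
        assert not sel.animal_included
        assert (sel.table.verdict == REJECT).all()

    def test_boundary_25_percent_is_target(self):
        fields = self._fields([0.40, 0.25])
        sel = select_peri_infarct_fields(fields, {0: [1], 1: [0]})
        assert sel.table.verdict.tolist() == [CORE, PERI_TARGET]

    def test_nonadjacent_in_range_rejected(self):
        fields = self._fields([0.40, 0.20])
        sel = select_peri_infarct_fields(fields, {0: [], 1: []})
        assert sel.table.verdict.tolist() == [CORE, REJECT]

    def test_rescaling_invariance(self):
        reductions = [0.40, 0.20, 0.10]
        adjacency = {0: [1], 1: [0, 2], 2: [1]}
        a = select_peri_infarct_fields(self._fields(reductions, 100.0),
                                       adjacency)
        b = select_peri_infarct_fields(self._fields(reductions, 350.0),
                                       adjacency)
        assert a.table.verdict.tolist() == b.table.verdict.tolist()

    def test_model_inclusion_window(self):
        fields = self._fields([0.40, 0.20])
        sel = select_peri_infarct_fields(fields, {0: [1], 1: [0]},
                                         injection_site_reduction=0.50)
        assert sel.model_included
        sel = select_peri_infarct_fields(fields, {0: [1], 1: [0]},
                                         injection_site_reduction=0.70)
        assert not sel.model_included

    def test_nonpositive_pre_flow_rejected(self):
        with pytest.raises(ValueError):
            flow_reduction(0.0, 10.0)

    def test_planted_flow_maps_selected_exactly(self):
        pre, post, _ = generate_flow_maps(0.40, 0.20, shape=(96, 96),
                                          core_radius_px=20,
                                          peri_width_px=16)
        boxes = [(slice(40, 56), slice(40, 56)),      # core centre
                 (slice(40, 56), slice(4, 20)),       # far left: untouched
                 (slice(40, 56), slice(64, 80)),      # annulus right
                 (slice(4, 20), slice(4, 20))]        # corner: untouched
        fields = fields_from_flow_maps(pre, post, boxes)
        adjacency = {0: [2], 2: [0], 1: [3], 3: [1]}
        sel = select_peri_infarct_fields(fields, adjacency)
        assert sel.table.verdict.tolist() == [CORE, REJECT, PERI_TARGET,
                                              REJECT]
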