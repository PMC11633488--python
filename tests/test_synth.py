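"""Simulator: layouts, event trains, rendering, traces, flow maps."""

import dataclasses

import numpy as np
import pytest

from mdca.synth import (SimulationSpec, generate_cell_layout,
                        generate_correlated_traces, generate_event_train,
                        generate_flow_maps, render_movie, simulate_recording,
                        transient_kernel, dff_trace_from_train)
from conftest import PX, small_sim_spec


class TestLayout:
    def test_single_soma_disc_area(self):
        spec = SimulationSpec(n_cells=1, microdomains_per_cell=0,
                              frame_size_px=64, field_of_view_um=64 * PX,
                              soma_radius_px=4, seed=0)
        layout = generate_cell_layout(spec)
        assert len(layout.labels) == 1
        (label,) = layout.labels
        assert layout.roi_class[label] == "soma"
        assert layout.area_px(label) == 49          # discretized disc r=4
        assert layout.area_um2(label) == pytest.approx(33.0, abs=0.1)

    def test_no_microdomains_requested(self):
        layout = generate_cell_layout(small_sim_spec(microdomains_per_cell=0))
        assert all(c == "soma" for c in layout.roi_class.values())

    def test_infeasible_soma_packing_raises(self):
        spec = SimulationSpec(n_cells=200, frame_size_px=64,
                              field_of_view_um=64 * PX)
        with pytest.raises(ValueError, match="packing"):
            generate_cell_layout(spec)

    def test_blob_classes_respect_size_rules(self):
        spec = small_sim_spec()
        layout = generate_cell_layout(spec)
        px2 = spec.pixel_size_um ** 2
        for label, cls in layout.roi_class.items():
            area = layout.area_px(label) * px2
            if cls == "soma":
                assert area >= 30.0
            else:
                assert 0.5 <= area <= 10.0

    def test_blobs_do_not_overlap(self):
        layout = generate_cell_layout(small_sim_spec())
        total = sum(layout.area_px(lbl) for lbl in layout.labels)
        assert np.count_nonzero(layout.label_image) == total


class TestEventTrain:
    def test_zero_rate_empty(self, rng):
        assert generate_event_train(0.0, 300.0, 0.4, 1.5, rng) == []

    def test_same_seed_identical(self):
        a = generate_event_train(2.0, 300.0, 0.4, 1.5,
                                 np.random.default_rng(3))
        b = generate_event_train(2.0, 300.0, 0.4, 1.5,
                                 np.random.default_rng(3))
        assert [e.onset_s for e in a] == [e.onset_s for e in b]

    def test_poisson_mean_count(self):
        # homogeneous Poisson: mean count over many seeds equals rate * T
        counts = [len(generate_event_train(2.0, 300.0, 0.4, 1.5,
                                           np.random.default_rng(s)))
                  for s in range(1000)]
        lam = 2.0 * 300.0 / 60.0                     # = 10
        se = np.sqrt(lam / 1000)
        assert np.mean(counts) == pytest.approx(lam, abs=4 * se)

    def test_onsets_within_duration(self, rng):
        train = generate_event_train(5.0, 120.0, 0.4, 1.5, rng)
        assert all(0.0 <= e.onset_s < 120.0 for e in train)


class TestKernel:
    def test_unit_peak(self):
        t = np.linspace(0, 10, 20001)
        k = transient_kernel(t, 0.2, 1.0)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert transient_kernel(np.array([-0.5]), 0.2, 1.0)[0] == 0.0

    def test_equal_taus_alpha_function(self):
        t = np.linspace(0, 10, 20001)
        k = transient_kernel(t, 0.5, 0.5)
        assert k.max() == pytest.approx(1.0, abs=1e-6)


class TestRender:
    def test_peak_pixel_value(self):
        spec = small_sim_spec(n_cells=1, microdomains_per_cell=0,
                              baseline_counts=100.0, noise_sd_counts=0.0,
                              duration_s=30.0)
        layout = generate_cell_layout(spec)
        label = layout.labels[0]
        trains = {label: generate_event_train(0, 1, 1, 1,
                                              np.random.default_rng(0))}
        from mdca.synth import Event
        trains[label] = [Event(onset_s=5.0, duration_s=1.5,
                               amplitude_dff=0.5)]
        movie, _ = render_movie(layout, trains, spec)
        mask = layout.mask(label)
        assert movie.data[:, mask].max() == pytest.approx(150.0, rel=1e-3)

    def test_no_events_constant_baseline(self):
        spec = small_sim_spec(noise_sd_counts=0.0, event_rate_per_min=0.0,
                              duration_s=30.0)
        layout = generate_cell_layout(spec)
        movie, _ = render_movie(layout, {}, spec)
        inside = layout.label_image > 0
        assert np.all(movie.data[:, inside] == spec.baseline_counts)
        assert np.all(movie.data[:, ~inside] == spec.background_counts)

    def test_jitter_shifts_recorded_and_recoverable(self):
        spec = small_sim_spec(jitter_max_px=3, noise_sd_counts=0.5,
                              duration_s=10.0, event_rate_per_min=0.0)
        layout = generate_cell_layout(spec)
        movie, shifts = render_movie(layout, {}, spec)
        assert np.abs(shifts).max() <= 3
        # exhaustive-search oracle recovers each planted shift exactly
        ref = movie.data[np.flatnonzero((shifts == 0).all(axis=1))[0]]
        for t in range(movie.n_frames):
            best, best_val = None, -np.inf
            for dy in range(-3, 4):
                for dx in range(-3, 4):
                    val = float((np.roll(ref, (dy, dx), axis=(0, 1))
                                 * movie.data[t]).sum())
                    if val > best_val:
                        best_val, best = val, (dy, dx)
            assert best == tuple(shifts[t])

    def test_noise_sd_matches_request(self):
        spec = small_sim_spec(noise_sd_counts=2.4, event_rate_per_min=0.0,
                              duration_s=30.0)
        layout = generate_cell_layout(spec)
        movie, _ = render_movie(layout, {}, spec)
        background = ~(layout.label_image > 0)
        sample = movie.data[:, background]            # >= 1e4 samples
        assert sample.size > 10_000
        assert np.std(sample) == pytest.approx(2.4, rel=0.05)

    def test_fixed_seed_bit_identical(self):
        spec = small_sim_spec(jitter_max_px=2)
        a = simulate_recording(spec)
        b = simulate_recording(dataclasses.replace(spec))
        assert np.array_equal(a.movie.data, b.movie.data)
        assert np.array_equal(a.ground_truth.shifts, b.ground_truth.shifts)

    def test_noiseless_roi_trace_recovers_planted_events(self):
        """Round trip: rendered noiseless ROI trace -> event detector with
        exact F0 returns the planted train (count, onsets, amplitudes)."""
        from mdca.events import compute_dff, detect_events

        spec = small_sim_spec(noise_sd_counts=0.0, duration_s=120.0,
                              event_rate_per_min=2.0, seed=11)
        rec = simulate_recording(spec)
        layout = rec.ground_truth.layout
        checked = 0
        for label in layout.labels:
            train = rec.ground_truth.event_trains[label]
            if not train:
                continue
            trace = rec.movie.data[:, layout.mask(label)].mean(axis=1)
            dff = compute_dff(trace, spec.baseline_counts, spec.frame_rate_hz)
            # noiseless trace: threshold at 25% of the planted amplitude
            events = detect_events(dff, sd=0.05, frame_rate_hz=10.0)
            # overlapping transients can fuse into a single detection
            separated = sum(1 for i, e in enumerate(train)
                            if i == 0 or e.onset_s - train[i - 1].onset_s > 4)
            assert separated <= len(events) <= len(train)
            dff_true = dff_trace_from_train(train, spec.n_frames,
                                            spec.frame_rate_hz,
                                            spec.rise_tau_s, spec.decay_tau_s)
            for _, ev in events.iterrows():
                nearest = min(abs(ev.onset_s - e.onset_s) for e in train)
                assert nearest < 1.0
                window = dff_true[int(ev.onset_s * 10):int(ev.offset_s * 10)]
                assert ev.peak_amplitude == pytest.approx(window.max(),
                                                          rel=0.05)
            checked += 1
        assert checked >= 5


class TestCorrelatedTraces:
    def test_rho_zero_uncorrelated(self, rng):
        traces, labels = generate_correlated_traces(20, 4, 0.0, 300.0, rng)
        r = np.corrcoef(traces)
        same = (labels[:, None] == labels[None, :]) & ~np.eye(20, dtype=bool)
        assert abs(r[same].mean()) < 0.05

    def test_rho_one_identical_within_ensemble(self, rng):
        traces, labels = generate_correlated_traces(6, 2, 1.0, 50.0, rng)
        for k in range(2):
            members = traces[labels == k]
            assert np.allclose(members, members[0])

    def test_rho_recovered_monte_carlo(self):
        # shared-latent model: expected within-ensemble correlation = rho
        rs = []
        for seed in range(20):
            traces, labels = generate_correlated_traces(
                40, 4, 0.6, 300.0, np.random.default_rng(seed))
            r = np.corrcoef(traces)
            same = ((labels[:, None] == labels[None, :])
                    & ~np.eye(40, dtype=bool))
            rs.append(r[same].mean())
        assert np.mean(rs) == pytest.approx(0.6, abs=0.05)

    def test_invalid_rho_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_correlated_traces(10, 2, 1.5, 10.0, rng)


class TestFlowMaps:
    def test_core_drop_applied(self):
        pre, post, drop = generate_flow_maps(0.40, 0.20)
        core = drop == 0.40
        assert core.any()
        assert np.allclose(post[core], 0.60 * pre[core])

    def test_peri_drop_applied(self):
        pre, post, drop = generate_flow_maps(0.40, 0.20)
        peri = drop == 0.20
        assert peri.any()
        assert np.allclose(post[peri], 0.80 * pre[peri])

    def test_zero_drop_identity(self):
        pre, post, drop = generate_flow_maps(0.0, 0.0)
        assert np.all(drop == 0)
        assert np.array_equal(pre, post)
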