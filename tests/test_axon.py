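"""Axonal conduction tests: synchrony selection, soma ID, STA, tracking."""

import numpy as np
import pytest
from dataclasses import replace

from hdmea.axon import (
    BackpropStats,
    PathError,
    backpropagation_stats,
    count_synchronous_firings,
    endpoint_velocity,
    fit_conduction_velocity,
    identify_soma,
    spike_triggered_average,
    track_propagation_front,
    velocity_change_report,
)
from hdmea.grid import Recording, make_grid
from hdmea.synthetic import preset, simulate_recording


class TestEndpointVelocity:
    def test_printed_pairs(self):
        # distance (mm) / time (ms) gives velocity in m/s
        assert endpoint_velocity(2.44, 2.1) == pytest.approx(1.16, abs=0.005)
        assert endpoint_velocity(2.05, 1.5) == pytest.approx(1.37, abs=0.005)
        assert endpoint_velocity(1.70, 2.0) == pytest.approx(0.85, abs=0.005)

    def test_backprop_probability_pct(self):
        assert BackpropStats(486, 1167).probability_pct == pytest.approx(41.6, abs=0.05)
        with pytest.raises(PathError):
            BackpropStats(0, 0).probability_pct


class TestSynchronousFirings:
    def test_coincident_block_scores_center(self):
        g = make_grid(5, 5)
        rate = 1000.0
        data = np.zeros((25, 200), dtype=np.float32)
        # 3x3 block spikes at the same sample in each of 2 frames
        block = [g.index(r, c) for r in (1, 2, 3) for c in (1, 2, 3)]
        for s in (20, 120):
            data[block, s] = -100.0
        rec = Recording(grid=g, sampling_rate=rate, data=data)
        counts = count_synchronous_firings(rec, window=0.1, dt=0.001)
        assert counts[g.index(2, 2)] == 2
        assert counts[g.index(0, 0)] == 0

    def test_spread_out_maxima_do_not_score(self, rng):
        g = make_grid(5, 5)
        data = rng.normal(0, 1, (25, 500)).astype(np.float32)
        rec = Recording(grid=g, sampling_rate=1000.0, data=data)
        counts = count_synchronous_firings(rec, window=0.1, dt=0.001)
        # random noise maxima are uniform over 100 frames: coincidences rare
        assert counts.sum() <= 3


class TestIdentifySoma:
    def test_largest_component_and_centroid(self):
        g = make_grid(6, 6)
        amp = np.zeros(36)
        blob = [g.index(r, c) for r in (2, 3) for c in (2, 3)]
        amp[blob] = 300.0
        amp[g.index(0, 5)] = 250.0   # single secondary electrode
        locus = identify_soma(amp, g, amp_threshold=200.0)
        assert locus.electrodes == frozenset(blob)
        assert locus.peak_amplitude_uv == 300.0
        expected = np.mean([g.position(e) for e in blob], axis=0)
        assert locus.centroid == pytest.approx(tuple(expected))
        assert frozenset({g.index(0, 5)}) in locus.secondary

    def test_spike_train_extracted_from_recording(self):
        g = make_grid(6, 6)
        rate = 5000.0
        data = np.zeros((36, 5000), dtype=np.float32)
        e = g.index(3, 3)
        for s in (1000, 2500, 4000):
            data[e, s] = -400.0
        rec = Recording(grid=g, sampling_rate=rate, data=data)
        amp = np.max(np.abs(data), axis=1)
        locus = identify_soma(amp, g, amp_threshold=300.0, rec=rec)
        assert locus.train is not None
        np.testing.assert_allclose(locus.train.times, np.array([1000, 2500, 4000]) / rate)


class TestSta:
    def test_recovers_deterministic_template(self):
        g = make_grid(3, 3)
        rate = 10000.0
        n = 20000
        data = np.zeros((9, n), dtype=np.float32)
        template = np.array([-10, -40, -80, -40, -10], dtype=np.float32)
        triggers = np.array([2000, 5000, 9000, 15000])
        for c in triggers:
            data[4, c - 2: c + 3] += template
        rec = Recording(grid=g, sampling_rate=rate, data=data)
        avg, offsets, used = spike_triggered_average(rec, triggers / rate, half_window=0.001)
        assert used == 4
        assert offsets.size == avg.shape[1]
        mid = np.flatnonzero(offsets == 0)[0]
        np.testing.assert_allclose(avg[4, mid - 2: mid + 3], template, atol=1e-5)

    def test_triggers_near_edges_skipped(self):
        g = make_grid(3, 3)
        rec = Recording(grid=g, sampling_rate=1000.0, data=np.zeros((9, 100), dtype=np.float32))
        _, _, used = spike_triggered_average(rec, np.array([0.0005, 0.05, 0.0999]), half_window=0.003)
        assert used == 1


class TestTracking:
    def test_velocity_recovery_on_axon_preset(self):
        # forward front on the axon preset: slope within 5%, good linear fit
        cfg = preset("axon", rng_seed=5)
        cfg = replace(cfg, duration_s=3.0)
        rec, gt = simulate_recording(cfg)
        amp_map = np.max(np.abs(rec.data), axis=1)
        locus = identify_soma(amp_map, rec.grid, 200.0, rec=rec)
        avg, offs, used = spike_triggered_average(rec, locus.train.times)
        assert used >= 20
        fwd, bwd = track_propagation_front(avg, offs, rec.grid, locus.centroid,
                                           exclude=locus.electrodes)
        fit_conduction_velocity(fwd)
        assert fwd.velocity_m_s == pytest.approx(cfg.axons[0].velocity_m_s, rel=0.05)
        assert fwd.r_squared >= 0.98
        # distances increase monotonically along the deduplicated front
        assert np.all(np.diff(fwd.cumdist_mm) > 0)

    def test_fit_requires_three_points(self):
        from hdmea.axon import ConductionPath

        p = ConductionPath(direction="forward", times_ms=np.array([0.0, 0.1]),
                           electrodes=np.array([0, 1]), cumdist_mm=np.array([0.0, 0.01]))
        with pytest.raises(PathError):
            fit_conduction_velocity(p)


class TestBackpropStats:
    def test_planted_ordered_precursors_detected(self):
        g = make_grid(4, 30)
        rate = 10000.0
        n = 40000
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1.0, (120, n)).astype(np.float32)
        path_e = np.array([g.index(2, c) for c in range(5, 25)])
        path_d = np.array([g.distance(g.index(2, 2), e) for e in path_e])
        triggers = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        # first 4 triggers get distal-to-proximal precursors, last 2 do not
        for t in triggers[:4]:
            c = int(t * rate)
            for k, e in enumerate(path_e):
                s = c - 6 - k   # farthest electrode earliest
                data[e, s - 1: s + 2] -= 30.0
        rec = Recording(grid=g, sampling_rate=rate, data=data)
        stats = backpropagation_stats(rec, triggers, path_e, path_d, noise_sigma=1.0)
        assert stats.n_triggers == 6
        assert stats.n_backprop == 4
        assert stats.probability_pct == pytest.approx(100 * 4 / 6)


class TestVelocityReport:
    def test_percent_of_baseline(self):
        rep = velocity_change_report(
            {"w0": [1.0, 2.0], "w1": [1.1, 1.8]}, baseline="w0"
        )
        row = rep.set_index("timepoint")
        assert row.loc["w0", "mean_pct"] == pytest.approx(100.0)
        assert row.loc["w1", "mean_pct"] == pytest.approx((110.0 + 90.0) / 2)

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(PathError):
            velocity_change_report({"w0": [0.0], "w1": [1.0]}, baseline="w0")
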