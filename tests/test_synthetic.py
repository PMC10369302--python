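"""Synthetic-generator tests: determinism, templates, ground-truth consistency."""

import dataclasses

import numpy as np
import pytest

from hdmea.grid import make_grid
from hdmea.synthetic import (
    EVOKED_BASELINE_HZ,
    EVOKED_CLUSTERS,
    AxonSpec,
    ConfigError,
    CouplingSpec,
    FiringModel,
    SynthConfig,
    UnitSpec,
    axon_path_electrodes,
    evoked_rate_profile,
    footprint_electrodes,
    preset,
    simulate_axon,
    simulate_evoked,
    simulate_recording,
    simulate_spike_trains,
    slice_region_masks,
    spike_template,
)


def _tiny_config(**over):
    base = dict(
        n_rows=8,
        n_cols=8,
        duration_s=2.0,
        sampling_rate_hz=5000.0,
        units=(UnitSpec(row=3, col=3, footprint_radius=1, amplitude_uv=300.0,
                        firing=FiringModel(rate=5.0)),),
        rng_seed=11,
    )
    base.update(over)
    return SynthConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        r1, g1 = simulate_recording(_tiny_config())
        r2, g2 = simulate_recording(_tiny_config())
        np.testing.assert_array_equal(r1.data, r2.data)
        for a, b in zip(g1.unit_trains, g2.unit_trains):
            np.testing.assert_array_equal(a, b)

    def test_different_seed_differs(self):
        r1, _ = simulate_recording(_tiny_config())
        r2, _ = simulate_recording(_tiny_config(rng_seed=12))
        assert not np.array_equal(r1.data, r2.data)

    def test_float32_output(self):
        rec, _ = simulate_recording(_tiny_config())
        assert rec.data.dtype == np.float32


class TestSpikeTemplate:
    def test_negative_first_peak_aligned(self):
        # at 10 kHz the 1 ms half-sine lobe has a sample exactly on its peak
        offsets, v = spike_template(10000.0, 200.0)
        assert v.min() == pytest.approx(-200.0)
        assert offsets[np.argmin(v)] == 0          # timestamp at negative peak
        assert v.max() == pytest.approx(100.0, rel=0.01)
        assert np.argmax(v) > np.argmin(v)         # positive lobe second

    def test_footprint_radius(self):
        g = make_grid(8, 8)
        assert len(footprint_electrodes(g, 3, 3, 1)) == 9
        assert len(footprint_electrodes(g, 0, 0, 1)) == 4
        assert footprint_electrodes(g, 3, 3, 0) == [g.index(3, 3)]

    def test_spike_visible_at_soma_electrode(self):
        cfg = _tiny_config(noise_rms_uv=0.0)
        rec, gt = simulate_recording(cfg)
        e = rec.grid.index(3, 3)
        times = gt.unit_trains[0]
        assert times.size > 0
        samples = np.round(times * cfg.sampling_rate_hz).astype(int)
        samples = samples[samples < rec.n_samples]
        vals = rec.data[e, samples]
        assert np.median(vals) == pytest.approx(-300.0, rel=0.05)


class TestSpikeTrains:
    def test_rates_approximate_spec(self):
        rng = np.random.default_rng(0)
        units = [UnitSpec(0, 0, firing=FiringModel(rate=5.0))]
        trains = simulate_spike_trains(units, (), duration=200.0, rng=rng)
        assert trains[0].size == pytest.approx(1000, rel=0.15)

    def test_excitatory_coupling_adds_followers(self):
        from conftest import brute_force_sync_count

        rng = np.random.default_rng(1)
        units = [UnitSpec(0, 0, firing=FiringModel(rate=1.0)),
                 UnitSpec(0, 4, firing=FiringModel(rate=1.0))]
        coup = (CouplingSpec(source=0, target=1, p=1.0),)
        trains = simulate_spike_trains(units, coup, duration=100.0, rng=rng)
        sync = brute_force_sync_count(trains[0], trains[1], 0.1)
        # every source spike gets a follower within 100 ms
        assert sync >= trains[0].size

    def test_bursting_model_clusters_spikes(self):
        rng = np.random.default_rng(2)
        units = [UnitSpec(0, 0, firing=FiringModel(kind="burst", burst_rate=0.3,
                                                   intra_rate=80.0, burst_duration=0.2))]
        trains = simulate_spike_trains(units, (), duration=60.0, rng=rng)
        isis = np.diff(trains[0])
        # bimodal ISI structure: many short intra-burst intervals
        assert np.mean(isis < 0.05) > 0.5


class TestAxon:
    def test_latency_proportional_to_arclength(self):
        g = make_grid(9, 60)
        p = g.pitch
        spec = AxonSpec(soma_unit=0, path_um=((3 * p, 4 * p), (56 * p, 4 * p)),
                        velocity_m_s=1.0)
        electrodes, latencies, amps = simulate_axon(g, spec)
        # centerline electrodes: latency = distance / velocity
        row4 = [e for e in electrodes if g.rowcol(e)[0] == 4]
        xs = np.array([g.position(e)[0] for e in row4])
        lats = np.array([latencies[e] for e in row4])
        order = np.argsort(xs)
        fit = np.polyfit(xs[order] * 1e-6, lats[order], 1)
        assert fit[0] == pytest.approx(1.0, rel=0.02)   # 1 s per meter at 1 m/s

    def test_lateral_corridor_amplitudes_decay(self):
        g = make_grid(9, 60)
        p = g.pitch
        spec = AxonSpec(soma_unit=0, path_um=((3 * p, 4 * p), (56 * p, 4 * p)))
        electrodes, _, amps = simulate_axon(g, spec)
        rows = {g.rowcol(e)[0] for e in electrodes}
        assert rows == {3, 4, 5}
        center = np.mean([amps[e] for e in electrodes if g.rowcol(e)[0] == 4])
        side = np.mean([amps[e] for e in electrodes if g.rowcol(e)[0] == 3])
        assert side < center

    def test_path_electrodes_cover_segment(self):
        g = make_grid(9, 60)
        p = g.pitch
        els, arclen, perp = axon_path_electrodes(g, ((3 * p, 4 * p), (56 * p, 4 * p)))
        assert len(els) == len(arclen) == len(perp)
        assert arclen.max() == pytest.approx((56 - 3) * p, rel=0.02)


class TestEvoked:
    @pytest.mark.parametrize("cid", [2, 3, 4, 5])
    def test_profile_hits_printed_statistics(self, cid):
        peak, t_peak, mean10 = EVOKED_CLUSTERS[cid]
        t, r = evoked_rate_profile(cid, dt=1e-4)
        assert r.max() == pytest.approx(peak, abs=1e-6)
        assert t[np.argmax(r)] == pytest.approx(t_peak, abs=1e-3)
        assert np.trapezoid(r, t) / 10.0 == pytest.approx(mean10, abs=0.01)

    def test_cluster1_flat_baseline(self):
        t, r = evoked_rate_profile(1)
        assert np.all(r == EVOKED_BASELINE_HZ)

    def test_simulate_evoked_count_tracks_mean_rate(self):
        rng = np.random.default_rng(3)
        counts = [simulate_evoked(4, onset=0.0, rng=rng).size for _ in range(50)]
        # expected count = 10 s x printed mean rate 13.2 Hz
        assert np.mean(counts) == pytest.approx(132.0, rel=0.1)

    def test_unknown_cluster_raises(self):
        with pytest.raises(ConfigError):
            evoked_rate_profile(9)


class TestPresets:
    @pytest.mark.parametrize("name", ["cortical_net", "drg", "axon", "organoid", "slice_lfp"])
    def test_presets_construct(self, name):
        cfg = preset(name)
        assert isinstance(cfg, SynthConfig)

    def test_unknown_preset_raises(self):
        with pytest.raises(ConfigError):
            preset("nope")

    def test_override_applies(self):
        cfg = preset("axon", rng_seed=99)
        assert cfg.rng_seed == 99

    def test_slice_region_masks_partition(self):
        g = make_grid(40, 40)
        masks = slice_region_masks(g)
        assert len(masks) == 4
        all_e = set()
        for m in masks.values():
            m.validate(g)
            assert not (all_e & m.electrodes)
            all_e |= m.electrodes
        assert len(all_e) == g.n_electrodes
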