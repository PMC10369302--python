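"""Unit-detection tests: spike detection, soma merging, DRG maps, summaries."""

import numpy as np
import pytest

from hdmea.grid import make_grid
from hdmea.units import (
    activity_summary,
    call_drg_somata,
    cosine_similarity,
    dedupe_times,
    detect_spikes,
    drg_soma_similarity_map,
    electrodes_per_soma_histogram,
    firing_histogram,
    merge_somata,
    rate_band_label,
    unit_firing_stats,
)


class TestDetectSpikes:
    def test_timestamps_at_negative_extremum(self):
        rate = 5000.0
        x = np.zeros(5000)
        x[1000:1005] = [-50, -90, -120, -80, -40]   # extremum at sample 1002
        x[3000] = -85.0
        st = detect_spikes(x, rate, threshold=80.0)
        np.testing.assert_allclose(st.times, [1002 / rate, 3000 / rate])

    def test_subthreshold_ignored(self):
        x = np.zeros(1000)
        x[500] = -79.0
        assert detect_spikes(x, 5000.0, threshold=80.0).times.size == 0

    def test_dead_time_suppresses_refires(self):
        rate = 5000.0
        x = np.zeros(1000)
        x[100] = -100.0
        x[102] = -100.0   # 0.4 ms later: inside the 1 ms dead time
        x[110] = -100.0   # 2 ms later: separate spike
        st = detect_spikes(x, rate, threshold=80.0)
        assert st.times.size == 2

    def test_positive_threshold_detects_positive_peaks(self):
        x = np.zeros(1000)
        x[300] = 90.0
        st = detect_spikes(x, 5000.0, threshold=80.0)
        np.testing.assert_allclose(st.times, [300 / 5000.0])


class TestSimilarity:
    def test_cosine_hand_values(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert cosine_similarity(np.array([1.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_gives_zero(self):
        assert cosine_similarity(np.zeros(4), np.ones(4)) == 0.0

    def test_firing_histogram_counts(self):
        h = firing_histogram(np.array([0.0005, 0.0012, 0.0013, 0.0999]), duration=0.1, bin_s=0.001)
        assert h.size == 100
        assert h[0] == 1 and h[1] == 2 and h[99] == 1
        assert h.sum() == 4

    def test_dedupe_times(self):
        out = dedupe_times(np.array([0.0, 0.0005, 0.002, 0.0025, 0.004]))
        np.testing.assert_allclose(out, [0.0, 0.002, 0.004])


class TestMergeSomata:
    def test_adjacent_identical_trains_merge(self):
        g = make_grid(5, 5)
        t = np.array([0.1, 0.5, 1.2, 3.3])
        trains = {11: t, 12: t + 0.0002, 3: np.array([2.0, 4.0])}
        units = merge_somata(trains, g, duration=5.0)
        assert len(units) == 2
        merged = next(u for u in units if 11 in u.electrodes)
        assert merged.electrodes == frozenset({11, 12})
        # near-duplicate spikes deduplicated in the pooled train
        assert merged.train.times.size == 4
        lone = next(u for u in units if 3 in u.electrodes)
        assert lone.electrodes == frozenset({3})

    def test_distant_identical_trains_not_merged(self):
        g = make_grid(5, 5)
        t = np.array([0.1, 0.5, 1.2])
        units = merge_somata({0: t, 24: t}, g, duration=2.0)
        assert len(units) == 2

    def test_dissimilar_neighbors_not_merged(self):
        g = make_grid(5, 5)
        units = merge_somata(
            {11: np.array([0.1, 0.5, 1.2]), 12: np.array([0.3, 0.9, 1.7])}, g, duration=2.0
        )
        assert len(units) == 2

    def test_silent_electrodes_dropped(self):
        g = make_grid(5, 5)
        units = merge_somata({7: np.array([]), 11: np.array([0.1])}, g, duration=1.0)
        assert len(units) == 1
        assert units[0].electrodes == frozenset({11})

    def test_centroid_is_electrode_mean(self):
        g = make_grid(5, 5)
        t = np.array([0.1, 0.5, 1.2, 2.0])
        units = merge_somata({11: t, 12: t}, g, duration=3.0)
        cx, cy = units[0].centroid
        px = (g.position(11) + g.position(12)) / 2
        assert (cx, cy) == pytest.approx(tuple(px))


class TestRateBands:
    @pytest.mark.parametrize(
        "rate,label",
        [
            (0.0, "0"),
            (0.05, "(0,0.1)"),
            (0.1, "[0.1,0.5)"),
            (0.49, "[0.1,0.5)"),
            (0.5, "[0.5,1.0)"),
            (1.0, "[1.0,2.0)"),
            (2.0, "[2.0,5.0)"),
            (5.0, "[5.0,10.0)"),
            (9.99, "[5.0,10.0)"),
            (10.0, ">=10.0"),
            (50.0, ">=10.0"),
        ],
    )
    def test_band_boundaries(self, rate, label):
        assert rate_band_label(rate) == label

    def test_unit_firing_stats_pct(self):
        from hdmea.units import NeuronUnit, SpikeTrain

        units = []
        counts = [0, 0, 1, 30]   # over 10 s: rates 0, 0, 0.1, 3.0 Hz
        for i, n in enumerate(counts):
            times = np.linspace(0.1, 9.9, n) if n else np.array([])
            units.append(NeuronUnit(i, frozenset({i}), (0.0, 0.0), SpikeTrain(i, times)))
        per, bands = unit_firing_stats(units, duration=10.0)
        assert len(per) == 4
        assert bands["n_units"].sum() == 4
        assert bands["pct"].sum() == pytest.approx(100.0)
        assert bands.loc[bands["band"] == "0", "pct"].item() == pytest.approx(50.0)
        assert bands.loc[bands["band"] == "[0.1,0.5)", "n_units"].item() == 1
        assert bands.loc[bands["band"] == "[2.0,5.0)", "n_units"].item() == 1

    def test_electrodes_per_soma_histogram(self):
        from hdmea.units import NeuronUnit, SpikeTrain

        units = [
            NeuronUnit(0, frozenset({0, 1}), (0, 0), SpikeTrain(0, np.array([0.1]))),
            NeuronUnit(1, frozenset({5}), (0, 0), SpikeTrain(1, np.array([0.1]))),
            NeuronUnit(2, frozenset({7, 8}), (0, 0), SpikeTrain(2, np.array([0.1]))),
        ]
        h = electrodes_per_soma_histogram(units)
        assert h[1] == 1 and h[2] == 2


class TestDrgMap:
    def test_borders_nan_interior_high_for_coherent_blob(self):
        g = make_grid(7, 7)
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1.0, (49, 4000))
        sig = np.zeros(4000)
        sig[::100] = -300.0
        blob = [g.index(r, c) for r in (2, 3, 4) for c in (2, 3, 4)]
        for e in blob:
            data[e] += sig
        m = drg_soma_similarity_map(data, g)
        assert np.isnan(m[0]) and np.isnan(m[6]) and np.isnan(m[42])
        center = g.index(3, 3)
        far = g.index(1, 5)
        assert m[center] > m[far]

    def test_call_drg_somata_finds_blob(self):
        g = make_grid(7, 7)
        m = np.full(49, 0.05)
        m[[g.index(r, c) for r in (0, 6) for c in range(7)]] = np.nan
        m[[g.index(r, 0) for r in range(7)]] = np.nan
        m[[g.index(r, 6) for r in range(7)]] = np.nan
        blob = [g.index(r, c) for r in (2, 3) for c in (2, 3)]
        m[blob] = 0.9
        calls = call_drg_somata(m, g)
        assert len(calls) == 1
        assert calls[0] == frozenset(blob)


class TestActivitySummary:
    def test_hand_arithmetic(self):
        trains = {0: np.array([0.1, 0.2, 0.3]), 1: np.array([5.0]), 2: np.array([])}
        s = activity_summary(trains, contact_mask={0, 1, 2, 3}, duration=10.0)
        assert s.total_spikes == 4
        assert s.n_active == 2
        assert s.n_mask == 4
        assert s.active_pct == pytest.approx(50.0)
        assert s.mean_rate_active_hz == pytest.approx(4 / 2 / 10.0)
        assert s.firing_electrodes_per_bin.size == 2000
        assert s.firing_electrodes_per_bin.max() == 1
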