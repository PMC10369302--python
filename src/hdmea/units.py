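"""Spike detection and neuron-unit identification.

A soma spans several adjacent electrodes on a high-density array, so raw
per-electrode spike trains over-count neurons. Electrodes whose 1-ms firing
histograms have cosine similarity >= 0.3 with an adjacent electrode are
merged into a single unit; the unit spike train is the deduplicated union of
its member-electrode trains and the centroid is the mean member position.

Also provides the waveform-similarity soma map used for large DRG somata,
per-unit firing-frequency banding, and array-level activity summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ElectrodeGrid

#: firing-histogram bin used for merging, s
MERGE_BIN_S = 1e-3
#: cosine-similarity threshold for merging adjacent electrodes
MERGE_SIM_THRESHOLD = 0.3
#: spike thresholds used in the source experiments, µV
THRESHOLD_CORTICAL_UV = 80.0
THRESHOLD_DRG_UV = 100.0
THRESHOLD_ORGANOID_UV = 200.0

#: firing-frequency band edges (Hz); a unit with rate r falls in the band
#: whose interval contains it; rate 0 is its own "nonspontaneous" band
RATE_BAND_EDGES = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)


class ParameterError(ValueError):
    pass


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (s) from one electrode or unit."""

    source_id: int
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def rate(self, duration: float) -> float:
        return self.n_spikes / duration


@dataclass
class NeuronUnit:
    """A merged electrode set with its pooled spike train.

    ``centroid`` is the center of gravity of the member electrode positions
    (µm); ``rate_hz`` is spike count over recording duration.
    """

    unit_id: int
    electrodes: frozenset[int]
    centroid: tuple[float, float]
    train: SpikeTrain
    rate_hz: float = field(default=0.0)


def detect_spikes(
    x: np.ndarray,
    rate: float,
    threshold: float,
    dead_time: float = 1e-3,
    source_id: int = 0,
) -> SpikeTrain:
    """Threshold crossing detection (|v| >= threshold, both polarities).

    Each excursion of |v| above threshold yields one spike, timestamped at
    the absolute extremum within the excursion; further excursions starting
    within ``dead_time`` (s) of an accepted spike are suppressed.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    x = np.asarray(x, dtype=float)
    above = np.abs(x) >= threshold
    if not above.any():
        return SpikeTrain(source_id, np.empty(0))
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [x.size]])
    peaks = []
    last = -np.inf
    dead = dead_time * rate
    for s, e in zip(starts, ends):
        if s - last < dead:
            continue
        p = s + int(np.argmax(np.abs(x[s:e])))
        peaks.append(p)
        last = p
    return SpikeTrain(source_id, np.asarray(peaks, dtype=float) / rate)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); 0 by convention when either vector is all-zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def firing_histogram(times: np.ndarray, duration: float, bin_s: float = MERGE_BIN_S) -> np.ndarray:
    """Spike-count histogram on a fixed bin grid over [0, duration]."""
    n_bins = int(np.ceil(duration / bin_s))
    h, _ = np.histogram(times, bins=n_bins, range=(0, n_bins * bin_s))
    return h


def dedupe_times(times: np.ndarray, window: float = MERGE_BIN_S) -> np.ndarray:
    """Greedy deduplication: keep a spike only if >= window after the last kept."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= window:
            kept.append(t)
    return np.asarray(kept)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_somata(
    trains: dict[int, np.ndarray],
    grid: ElectrodeGrid,
    duration: float,
    bin_s: float = MERGE_BIN_S,
    sim_threshold: float = MERGE_SIM_THRESHOLD,
) -> list[NeuronUnit]:
    """Merge electrodes with matching firing patterns into neuron units.

    Builds an undirected graph over electrodes with an edge wherever two
    8-adjacent electrodes have cosine similarity >= ``sim_threshold``
    between their ``bin_s`` firing histograms; connected components become
    units. Silent electrodes (all-zero histogram, similarity 0 by
    convention) never merge and are dropped.

    Parameters
    ----------
    trains : {electrode_index: spike times (s)}
    """
    active = {e: np.asarray(t, dtype=float) for e, t in trains.items() if len(t) > 0}
    if not active:
        return []
    idx = sorted(active)
    pos_in_idx = {e: i for i, e in enumerate(idx)}
    hists = {e: firing_histogram(active[e], duration, bin_s) for e in idx}
    uf = _UnionFind(len(idx))
    for e in idx:
        for nb in grid.neighbors(e):
            if nb in pos_in_idx and nb > e:
                if cosine_similarity(hists[e], hists[nb]) >= sim_threshold:
                    uf.union(pos_in_idx[e], pos_in_idx[nb])
    comps: dict[int, list[int]] = {}
    for i, e in enumerate(idx):
        comps.setdefault(uf.find(i), []).append(e)
    units = []
    pos = grid.positions
    for uid, members in enumerate(sorted(comps.values(), key=min)):
        pooled = dedupe_times(np.concatenate([active[e] for e in members]), window=bin_s)
        cx, cy = pos[members].mean(axis=0)
        units.append(
            NeuronUnit(
                unit_id=uid,
                electrodes=frozenset(members),
                centroid=(float(cx), float(cy)),
                train=SpikeTrain(uid, pooled),
                rate_hz=pooled.size / duration,
            )
        )
    return units


def drg_soma_similarity_map(data: np.ndarray, grid: ElectrodeGrid) -> np.ndarray:
    """Mean waveform cosine similarity to the 8 surrounding electrodes.

    For every interior electrode the full-trace waveform is compared with
    each of its 8 neighbors; the map holds the mean of those similarities.
    Border electrodes are NaN (undefined). Large somata covering many
    electrodes appear as local maxima.
    """
    out = np.full(grid.n_electrodes, np.nan)
    interior = grid.interior_electrodes()
    if interior.size == 0:
        warnings.warn("grid smaller than 3x3: similarity map undefined", stacklevel=2)
        return out
    norms = np.linalg.norm(data, axis=1)
    for e in interior:
        sims = []
        for nb in sorted(grid.neighbors(e)):
            if norms[e] == 0 or norms[nb] == 0:
                sims.append(0.0)
            else:
                sims.append(float(data[e] @ data[nb] / (norms[e] * norms[nb])))
        out[e] = np.mean(sims)
    return out


def call_drg_somata(sim_map: np.ndarray, grid: ElectrodeGrid, n_sd: float = 2.0) -> list[frozenset[int]]:
    """Group electrodes above mean + n_sd*SD of the similarity map into
    connected candidate-soma components."""
    valid = np.isfinite(sim_map)
    if not valid.any():
        return []
    thr = np.nanmean(sim_map) + n_sd * np.nanstd(sim_map)
    hot = set(np.flatnonzero(valid & (sim_map >= thr)))
    comps = []
    while hot:
        seed = hot.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            e = frontier.pop()
            for nb in grid.neighbors(e) & hot:
                hot.discard(nb)
                comp.add(nb)
                frontier.append(nb)
        comps.append(frozenset(comp))
    return sorted(comps, key=lambda c: -len(c))


def rate_band_label(rate: float) -> str:
    """Firing-frequency band label for one unit."""
    if rate == 0:
        return "0"
    if rate < RATE_BAND_EDGES[0]:
        return f"(0,{RATE_BAND_EDGES[0]})"
    for lo, hi in zip(RATE_BAND_EDGES, RATE_BAND_EDGES[1:]):
        if lo <= rate < hi:
            return f"[{lo},{hi})"
    return f">={RATE_BAND_EDGES[-1]}"


def unit_firing_stats(units: list[NeuronUnit], duration: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit firing table and aggregate band percentages.

    Returns
    -------
    per_unit : DataFrame (unit_id, rate_hz, band, n_electrodes)
    bands : DataFrame (band, n_units, pct) covering all bands in order,
        with percentages of the total unit count.
    """
    rows = [
        {
            "unit_id": u.unit_id,
            "rate_hz": u.train.n_spikes / duration,
            "band": rate_band_label(u.train.n_spikes / duration),
            "n_electrodes": len(u.electrodes),
        }
        for u in units
    ]
    per_unit = pd.DataFrame(rows, columns=["unit_id", "rate_hz", "band", "n_electrodes"])
    order = ["0", "(0,0.1)"] + [
        f"[{lo},{hi})" for lo, hi in zip((0.1, 0.5, 1.0, 2.0, 5.0), (0.5, 1.0, 2.0, 5.0, 10.0))
    ] + [">=10.0"]
    n = len(per_unit)
    counts = per_unit["band"].value_counts() if n else pd.Series(dtype=int)
    bands = pd.DataFrame(
        {
            "band": order,
            "n_units": [int(counts.get(b, 0)) for b in order],
        }
    )
    bands["pct"] = 100.0 * bands["n_units"] / n if n else 0.0
    return per_unit, bands


def electrodes_per_soma_histogram(units: list[NeuronUnit]) -> pd.Series:
    """Histogram of member-electrode counts per unit (bin = 1 electrode)."""
    sizes = pd.Series([len(u.electrodes) for u in units], dtype=int)
    return sizes.value_counts().sort_index()


@dataclass
class ActivitySummary:
    total_spikes: int
    n_active: int
    n_mask: int
    active_pct: float
    mean_rate_active_hz: float
    firing_electrodes_per_bin: np.ndarray


def activity_summary(
    trains: dict[int, np.ndarray],
    contact_mask: set[int] | frozenset[int],
    duration: float,
    bin_s: float = 5e-3,
) -> ActivitySummary:
    """Array-level totals over the electrodes a tissue contacts.

    ``firing_electrodes_per_bin[k]`` counts the distinct electrodes with at
    least one spike in time bin k (default 5 ms bins).
    """
    mask = set(contact_mask)
    total = sum(len(trains.get(e, ())) for e in mask)
    active = [e for e in mask if len(trains.get(e, ())) > 0]
    n_bins = int(np.ceil(duration / bin_s)) if duration > 0 else 0
    per_bin = np.zeros(n_bins, dtype=int)
    for e in active:
        bins = np.unique(np.minimum((np.asarray(trains[e]) / bin_s).astype(int), n_bins - 1))
        per_bin[bins] += 1
    return ActivitySummary(
        total_spikes=int(total),
        n_active=len(active),
        n_mask=len(mask),
        active_pct=100.0 * len(active) / len(mask) if mask else 0.0,
        mean_rate_active_hz=(total / len(active) / duration) if active else 0.0,
        firing_electrodes_per_bin=per_bin,
    )
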