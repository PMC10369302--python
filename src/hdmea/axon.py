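"""Axonal conduction analysis: conduction-path electrode selection,
soma identification, spike-triggered averaging, propagation-front tracking,
velocity fitting, and backpropagation statistics.

The workflow: (1) select electrodes repeatedly participating in
sub-millisecond synchronous firings with their lattice neighbors;
(2) locate the soma as the largest connected high-amplitude component and
detect its spike train; (3) average voltage in a +/-3 ms window around each
soma spike; (4) on the averaged map, track the firing front outward from
the soma centroid in 0.1 ms frames; (5) fit cumulative conduction distance
against time by least squares — the slope is the conduction velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ElectrodeGrid, Recording
from .units import SpikeTrain, dedupe_times, detect_spikes

SYNC_WINDOW_S = 0.05
SYNC_DT_S = 1e-3
SYNC_MIN_NEIGHBORS = 4
STA_HALF_WINDOW_S = 3e-3
TRACK_STEP_S = 1e-4
#: -k*sigma firing criterion on the averaged map
TRACK_K_SIGMA = 5.0
SOMA_THRESHOLD_UV = 200.0
#: path electrodes that must fire pre-soma, in distal-to-proximal order,
#: for a trigger to count as backpropagating
BACKPROP_MIN_ELECTRODES = 5


class PathError(ValueError):
    pass


def count_synchronous_firings(
    rec: Recording,
    window: float = SYNC_WINDOW_S,
    dt: float = SYNC_DT_S,
    min_neighbors: int = SYNC_MIN_NEIGHBORS,
) -> np.ndarray:
    """Per-electrode synchronous-firing counts.

    The recording is cut into ``window``-long frames; in each frame every
    electrode is summarized by the time of its maximum |v|. An electrode
    scores one synchronous firing in a frame when at least ``min_neighbors``
    of its 8 lattice neighbors reach their maximum within < ``dt`` of its
    own. Counts accumulate over all frames.
    """
    grid = rec.grid
    fs = rec.sampling_rate
    win = int(round(window * fs))
    n_win = rec.n_samples // win
    if n_win == 0:
        return np.zeros(grid.n_electrodes, dtype=int)
    x = np.abs(rec.data[:, : n_win * win]).reshape(grid.n_electrodes, n_win, win)
    tmax = x.argmax(axis=2) / fs  # (electrodes, windows), s within frame
    counts = np.zeros(grid.n_electrodes, dtype=int)
    neighbor_lists = [sorted(grid.neighbors(e)) for e in range(grid.n_electrodes)]
    for e in range(grid.n_electrodes):
        nbs = neighbor_lists[e]
        close = np.abs(tmax[nbs] - tmax[e][None, :]) < dt  # (n_nb, n_win)
        counts[e] = int(np.sum(close.sum(axis=0) >= min_neighbors))
    return counts


@dataclass
class SomaLocus:
    """Soma electrode set with centroid, peak amplitude and spike train."""

    electrodes: frozenset[int]
    centroid: tuple[float, float]
    peak_amplitude_uv: float
    train: SpikeTrain | None = None
    secondary: list[frozenset[int]] = field(default_factory=list)


def _connected_components(electrodes: set[int], grid: ElectrodeGrid) -> list[frozenset[int]]:
    pool = set(electrodes)
    comps = []
    while pool:
        seed = pool.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            e = frontier.pop()
            for nb in grid.neighbors(e) & pool:
                pool.discard(nb)
                comp.add(nb)
                frontier.append(nb)
        comps.append(frozenset(comp))
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def identify_soma(
    amp_map: np.ndarray,
    grid: ElectrodeGrid,
    amp_threshold: float,
    selected: np.ndarray | None = None,
    rec: Recording | None = None,
    spike_threshold: float = SOMA_THRESHOLD_UV,
) -> SomaLocus:
    """Locate the soma on a maximum-amplitude map.

    Soma electrodes are the largest 8-connected component with
    ``amp_map >= amp_threshold`` (restricted to ``selected`` electrodes when
    given); the centroid is their center of gravity. When a recording is
    passed, the soma spike train is detected on the peak electrode at
    ``spike_threshold`` (µV) with 1-ms deduplication across the soma
    electrodes. Other high-amplitude components are reported as secondary
    candidates.
    """
    amp_map = np.asarray(amp_map, dtype=float)
    hot = set(np.flatnonzero(amp_map >= amp_threshold).tolist())
    if selected is not None:
        hot &= set(int(e) for e in np.asarray(selected).ravel())
    if not hot:
        raise PathError(f"no electrode reaches the {amp_threshold} µV amplitude threshold")
    comps = _connected_components(hot, grid)
    soma = comps[0]
    members = sorted(soma)
    centroid = grid.positions[members].mean(axis=0)
    train = None
    if rec is not None:
        parts = []
        for e in members:
            st = detect_spikes(rec.data[e], rec.sampling_rate, spike_threshold)
            parts.append(st.times)
        pooled = dedupe_times(np.concatenate(parts) if parts else np.empty(0), window=1e-3)
        train = SpikeTrain(source_id=members[int(np.argmax(amp_map[members]))], times=pooled)
    return SomaLocus(
        electrodes=frozenset(members),
        centroid=(float(centroid[0]), float(centroid[1])),
        peak_amplitude_uv=float(amp_map[members].max()),
        train=train,
        secondary=comps[1:],
    )


def spike_triggered_average(
    rec: Recording,
    trigger_times: np.ndarray,
    half_window: float = STA_HALF_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean voltage in [-half_window, +half_window] around each trigger.

    Triggers whose window is clipped by a recording edge are skipped (and
    excluded from the trigger count). Returns (electrodes x time average,
    time offsets in s, number of triggers used).
    """
    fs = rec.sampling_rate
    h = int(round(half_window * fs))
    centers = np.round(np.asarray(trigger_times, dtype=float) * fs).astype(int)
    usable = centers[(centers - h >= 0) & (centers + h < rec.n_samples)]
    if usable.size == 0:
        raise PathError("no trigger fits inside the recording")
    acc = np.zeros((rec.data.shape[0], 2 * h + 1))
    for c in usable:
        acc += rec.data[:, c - h: c + h + 1]
    acc /= usable.size
    offsets = np.arange(-h, h + 1) / fs
    return acc, offsets, int(usable.size)


@dataclass
class ConductionPath:
    """Time-ordered propagation front with cumulative conduction distance.

    ``times_ms`` are offsets from the soma spike (absolute value for the
    backward path, so distance grows with time in both directions).
    """

    direction: str
    times_ms: np.ndarray
    electrodes: np.ndarray
    cumdist_mm: np.ndarray
    velocity_m_s: float = np.nan
    r_squared: float = np.nan

    @property
    def total_distance_mm(self) -> float:
        return float(self.cumdist_mm[-1]) if self.cumdist_mm.size else 0.0

    @property
    def total_time_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0]) if self.times_ms.size else 0.0

    def endpoint_velocity_m_s(self) -> float:
        """Endpoint arithmetic distance/time (mm/ms = m/s)."""
        if self.times_ms.size < 2 or self.total_time_ms == 0:
            raise PathError("endpoint velocity needs >= 2 time points")
        return self.total_distance_mm / self.total_time_ms

    def to_frame(self, grid: ElectrodeGrid) -> pd.DataFrame:
        pos = grid.positions[self.electrodes]
        return pd.DataFrame(
            {
                "frame_time_ms": self.times_ms,
                "electrode": self.electrodes,
                "x_um": pos[:, 0],
                "y_um": pos[:, 1],
                "cumdist_mm": self.cumdist_mm,
            }
        )


def track_propagation_front(
    avg_map: np.ndarray,
    offsets: np.ndarray,
    grid: ElectrodeGrid,
    soma_centroid: tuple[float, float],
    step: float = TRACK_STEP_S,
    k_sigma: float = TRACK_K_SIGMA,
    exclude: frozenset[int] | set[int] = frozenset(),
) -> tuple[ConductionPath, ConductionPath]:
    """Track the forward (t > 0) and backward (t < 0) propagation fronts.

    Per ``step``-long frame, among electrodes whose averaged trace is below
    the -k*sigma firing criterion within that frame, the one farthest from
    the soma centroid is appended to the path; frames with no firing
    electrode are skipped. The point's time is the selected electrode's
    first threshold crossing (sample resolution), which removes the frame
    quantization from the velocity fit. Cumulative distance sums the
    straight-line distances between consecutive selected electrodes.
    ``exclude`` drops electrodes (e.g. the soma locus itself) from
    selection.
    """
    n_pre = max(2, avg_map.shape[1] // 6)
    sigma = np.median(np.std(avg_map[:, :n_pre], axis=1))
    thr = -k_sigma * sigma
    soma = np.asarray(soma_centroid, dtype=float)
    dist_to_soma = np.linalg.norm(grid.positions - soma, axis=1)
    keep = np.ones(grid.n_electrodes, dtype=bool)
    for e in exclude:
        keep[e] = False

    below = avg_map < thr
    # per-electrode firing time on each side of the trigger: the time of the
    # negative extremum (max-amplitude convention), which is independent of
    # the electrode's signal amplitude
    def _peak_time(e: int, sign: int) -> float:
        side = (offsets > 0) if sign > 0 else (offsets < 0)
        idx = np.flatnonzero(side & below[e])
        if idx.size == 0:
            return np.nan
        return abs(offsets[idx[np.argmin(avg_map[e, idx])]])

    def _track(sign: int) -> ConductionPath:
        if sign > 0:
            frame_edges = np.arange(0.0, offsets[-1] + step / 2, step)
        else:
            frame_edges = np.arange(0.0, -offsets[0] + step / 2, step)
        sel_t, sel_e = [], []
        for f0 in frame_edges:
            if sign > 0:
                m = (offsets > f0) & (offsets <= f0 + step)
            else:
                m = (offsets < -f0) & (offsets >= -(f0 + step))
            if not m.any():
                continue
            firing = np.flatnonzero(keep & below[:, m].any(axis=1))
            if firing.size == 0:
                continue
            far = int(firing[np.argmax(dist_to_soma[firing])])
            t_cross = _peak_time(far, sign)
            sel_t.append(t_cross if np.isfinite(t_cross) else f0 + step / 2)
            sel_e.append(far)
        sel_t = np.asarray(sel_t)
        sel_e = np.asarray(sel_e, dtype=int)
        if sel_e.size > 1:
            # a frame that re-selects the previous electrode adds no front
            # advance (e.g. after the front reaches the path end); keep the
            # first occurrence only
            fresh = np.concatenate([[True], sel_e[1:] != sel_e[:-1]])
            sel_t, sel_e = sel_t[fresh], sel_e[fresh]
        if sel_e.size == 0:
            return ConductionPath(
                direction="forward" if sign > 0 else "backward",
                times_ms=np.empty(0), electrodes=sel_e, cumdist_mm=np.empty(0),
            )
        pos = grid.positions[sel_e]
        steps_mm = np.concatenate([[0.0], np.linalg.norm(np.diff(pos, axis=0), axis=1) * 1e-3])
        return ConductionPath(
            direction="forward" if sign > 0 else "backward",
            times_ms=sel_t * 1e3,
            electrodes=sel_e,
            cumdist_mm=np.cumsum(steps_mm),
        )

    return _track(+1), _track(-1)


def fit_conduction_velocity(path: ConductionPath) -> ConductionPath:
    """Least-squares fit of cumulative distance (mm) against time (ms).

    The slope is the conduction velocity in m/s (mm/ms); R^2 measures fit
    quality. Returns the path with ``velocity_m_s`` and ``r_squared`` set.
    """
    if path.times_ms.size < 3:
        raise PathError("velocity fit needs >= 3 path points")
    t, d = path.times_ms, path.cumdist_mm
    if np.ptp(t) == 0:
        raise PathError("degenerate time spread")
    slope, intercept = np.polyfit(t, d, 1)
    pred = slope * t + intercept
    ss_res = np.sum((d - pred) ** 2)
    ss_tot = np.sum((d - d.mean()) ** 2)
    path.velocity_m_s = float(slope)
    path.r_squared = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    return path


def endpoint_velocity(distance_mm: float, time_ms: float) -> float:
    """Endpoint arithmetic: conduction distance over conduction time (m/s)."""
    if time_ms <= 0:
        raise PathError("conduction time must be positive")
    return distance_mm / time_ms


@dataclass
class BackpropStats:
    n_backprop: int
    n_triggers: int

    @property
    def probability_pct(self) -> float:
        """100 * backpropagating triggers / all triggers."""
        if self.n_triggers == 0:
            raise PathError("no triggers")
        return 100.0 * self.n_backprop / self.n_triggers


def backpropagation_stats(
    rec: Recording,
    trigger_times: np.ndarray,
    path_electrodes: np.ndarray,
    path_dist_um: np.ndarray,
    half_window: float = STA_HALF_WINDOW_S,
    k_sigma: float = 3.0,
    noise_sigma: float | None = None,
    min_electrodes: int = BACKPROP_MIN_ELECTRODES,
    min_dist_um: float = 35.0,
) -> BackpropStats:
    """Per-trigger backpropagation detection along a known conduction path.

    A trigger counts as backpropagating when, in its pre-soma window
    [-half_window, 0), at least ``min_electrodes`` path electrodes (farther
    than ``min_dist_um`` from the soma, so the soma's own footprint does not
    vote) cross below -k*sigma, and their crossing times are ordered
    distal-to-proximal (Pearson r(distance, time) <= -0.5).
    """
    fs = rec.sampling_rate
    h = int(round(half_window * fs))
    path_electrodes = np.asarray(path_electrodes, dtype=int)
    path_dist_um = np.asarray(path_dist_um, dtype=float)
    far = path_dist_um > min_dist_um
    electrodes = path_electrodes[far]
    dists = path_dist_um[far]
    if noise_sigma is None:
        noise_sigma = float(np.median(np.std(rec.data[electrodes, : min(rec.n_samples, int(fs))], axis=1)))
    thr = -k_sigma * noise_sigma
    n_back = 0
    centers = np.round(np.asarray(trigger_times, dtype=float) * fs).astype(int)
    usable = centers[(centers - h >= 0) & (centers < rec.n_samples)]
    for c in usable:
        snip = rec.data[electrodes, c - h: c]  # pre-soma window
        below = snip < thr
        fired = below.any(axis=1)
        if fired.sum() < min_electrodes:
            continue
        t_first = np.argmax(below[fired], axis=1).astype(float)
        d = dists[fired]
        if np.std(t_first) == 0 or np.std(d) == 0:
            continue
        r = float(np.corrcoef(d, t_first)[0, 1])
        if r <= -0.5:
            n_back += 1
    return BackpropStats(n_backprop=n_back, n_triggers=int(usable.size))


def velocity_change_report(
    velocities_by_timepoint: dict[str, list[float]],
    baseline: str,
) -> pd.DataFrame:
    """Velocities as percentages of the baseline timepoint (baseline = 100%).

    ``velocities_by_timepoint`` maps timepoint labels to per-well velocity
    lists (parallel across timepoints). Reports mean percent change and SEM
    across wells.
    """
    base = np.asarray(velocities_by_timepoint[baseline], dtype=float)
    if np.any(base <= 0):
        raise PathError("baseline velocities must be positive")
    rows = []
    for label, vals in velocities_by_timepoint.items():
        pct = 100.0 * np.asarray(vals, dtype=float) / base
        sem = pct.std(ddof=1) / np.sqrt(pct.size) if pct.size > 1 else 0.0
        rows.append({"timepoint": label, "mean_pct": pct.mean(), "sem_pct": sem, "n": pct.size})
    return pd.DataFrame(rows)
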