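"""LFP propagation analysis on slice-style recordings.

An LFP event in a region is a run of contiguous sample frames in which at
least ``min_electrodes`` of the region's electrodes exceed an amplitude
threshold. The propagated area is the distinct-electrode footprint of the
event times the electrode cell area (pitch^2); the areal velocity is that
area over the event duration (mm^2/s). Inter-region synchrony counts event
pairs whose onsets fall within a time window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ElectrodeGrid, Recording, RegionMask


@dataclass
class PropagationEvent:
    region: str
    start: float
    end: float
    electrodes: frozenset[int]
    area_mm2: float = np.nan
    velocity_mm2_s: float = np.nan

    @property
    def duration(self) -> float:
        return self.end - self.start


def amplitude_threshold(rec: Recording, region: RegionMask, quiet: tuple[float, float], n_sd: float = 5.0) -> float:
    """Default event threshold: n_sd times the median per-electrode SD of a
    quiet period within the region."""
    i0 = int(round(quiet[0] * rec.sampling_rate))
    i1 = int(round(quiet[1] * rec.sampling_rate))
    idx = sorted(region.electrodes)
    return n_sd * float(np.median(np.std(rec.data[idx, i0:i1], axis=1)))


def detect_lfp_events(
    rec: Recording,
    region: RegionMask,
    amp_threshold: float,
    min_electrodes: int = 3,
) -> list[PropagationEvent]:
    """Detect propagation events in one region.

    An event spans contiguous frames (samples) where >= ``min_electrodes``
    region electrodes exceed |amp_threshold| (inclusive); events are
    separated by at least one quiet frame. Area and velocity are filled via
    :func:`propagation_area_velocity`.
    """
    idx = sorted(region.electrodes)
    active = np.abs(rec.data[idx]) >= amp_threshold  # (n_region, n_samples)
    hot = active.sum(axis=0) >= min_electrodes
    if not hot.any():
        return []
    d = np.diff(hot.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if hot[0]:
        starts = np.concatenate([[0], starts])
    if hot[-1]:
        ends = np.concatenate([ends, [hot.size]])
    fs = rec.sampling_rate
    events = []
    for s, e in zip(starts, ends):
        involved = frozenset(np.asarray(idx)[active[:, s:e].any(axis=1)].tolist())
        ev = PropagationEvent(region=region.label, start=s / fs, end=e / fs, electrodes=involved)
        propagation_area_velocity(ev, rec.grid)
        events.append(ev)
    return events


def propagation_area_velocity(event: PropagationEvent, grid: ElectrodeGrid) -> tuple[float, float]:
    """Propagated area (mm^2) and areal velocity (mm^2/s) of one event.

    Area = distinct active electrodes x pitch^2 (electrode cell area);
    velocity = area / event duration, NaN (flagged) for zero duration.
    """
    cell_mm2 = (grid.pitch * 1e-3) ** 2
    event.area_mm2 = len(event.electrodes) * cell_mm2
    event.velocity_mm2_s = event.area_mm2 / event.duration if event.duration > 0 else np.nan
    return event.area_mm2, event.velocity_mm2_s


def region_synchrony(
    events_by_region: dict[str, list[PropagationEvent]],
    window: float = 0.05,
) -> pd.DataFrame:
    """Pairwise event co-occurrence between regions.

    Counts event pairs across two regions with onset difference <= window.
    """
    rows = []
    regions = sorted(events_by_region)
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            onsets_a = np.array([e.start for e in events_by_region[a]])
            onsets_b = np.array([e.start for e in events_by_region[b]])
            n = 0
            for t in onsets_a:
                n += int(np.sum(np.abs(onsets_b - t) <= window))
            rows.append({"region_a": a, "region_b": b, "n_cooccurring": n})
    return pd.DataFrame(rows)
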