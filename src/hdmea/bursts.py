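"""Burst analytics: network bursts from pooled spike trains, single-neuron
bursts by the Poisson-Surprise statistic, the 12-parameter burst tables, and
vehicle normalization.

Network bursts use a four-step interval method: pool and sort spikes across
units, group runs whose inter-spike interval stays at or below an ISI
threshold, merge groups closer than an inter-burst-interval threshold, then
keep groups with enough spikes and enough participating units.

Single-neuron bursts score candidate groups with the Poisson-Surprise
S = -ln P(N >= n) for a Poisson count N at the unit's mean rate over the
group span; groups are runs of intervals below the unit's mean ISI, and the
contiguous sub-window with maximal S is retained when S clears a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

# Defaults follow conventional MEA burst-detection practice; the source
# method names the thresholds without printing values, so all are exposed.
NB_ISI_THRESHOLD_S = 0.100
NB_IBI_THRESHOLD_S = 0.300
NB_MIN_SPIKES = 5
NB_MIN_UNITS = 2
PS_THRESHOLD = 10.0
PS_MIN_SPIKES = 3
MF_BIN_S = 0.010


class ParameterError(ValueError):
    pass


@dataclass
class NetworkBurst:
    start: float
    end: float
    n_spikes: int
    units: frozenset[int]
    spike_times: np.ndarray

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SingleNeuronBurst:
    unit_id: int
    start: float
    end: float
    n_spikes: int
    surprise: float
    spike_times: np.ndarray

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_network_bursts(
    times: np.ndarray,
    unit_ids: np.ndarray,
    isi_th: float = NB_ISI_THRESHOLD_S,
    ibi_th: float = NB_IBI_THRESHOLD_S,
    min_spikes: int = NB_MIN_SPIKES,
    min_units: int = NB_MIN_UNITS,
) -> list[NetworkBurst]:
    """Four-step network-burst detection on unit-pooled spikes.

    Parameters
    ----------
    times, unit_ids : parallel arrays of spike times (s) and source units.
    """
    times = np.asarray(times, dtype=float)
    unit_ids = np.asarray(unit_ids)
    if times.size == 0:
        return []
    order = np.argsort(times, kind="stable")
    times, unit_ids = times[order], unit_ids[order]
    # step 2: split where ISI exceeds the threshold
    gaps = np.diff(times)
    breaks = np.flatnonzero(gaps > isi_th) + 1
    groups = np.split(np.arange(times.size), breaks)
    # step 3: merge groups whose separation is strictly below ibi_th
    merged: list[np.ndarray] = []
    for g in groups:
        if merged and times[g[0]] - times[merged[-1][-1]] < ibi_th:
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    # step 4: size and participation filters
    out = []
    for g in merged:
        uids = frozenset(np.unique(unit_ids[g]).tolist())
        if g.size >= min_spikes and len(uids) >= min_units:
            out.append(
                NetworkBurst(
                    start=float(times[g[0]]),
                    end=float(times[g[-1]]),
                    n_spikes=int(g.size),
                    units=uids,
                    spike_times=times[g].copy(),
                )
            )
    return out


def poisson_surprise(n: int, span: float, rate: float) -> float:
    """Poisson-Surprise S = -ln P(N >= n) for N ~ Poisson(rate * span).

    Uses the regularized incomplete gamma identity
    P(N >= n) = P(Gamma(n) <= mu) = gammainc(n, mu), with a log-sum-exp
    fallback for tails below double-precision range.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if span <= 0 or rate <= 0:
        raise ParameterError("span and rate must be positive")
    mu = rate * span
    tail = special.gammainc(n, mu)
    if tail > 0:
        return float(-np.log(tail))
    # extreme tail: sum Poisson log-pmf terms from n upward
    ks = np.arange(n, n + 200)
    logp = ks * np.log(mu) - mu - special.gammaln(ks + 1)
    return float(-special.logsumexp(logp))


def detect_ps_bursts(
    times: np.ndarray,
    duration: float,
    unit_id: int = 0,
    s_threshold: float = PS_THRESHOLD,
    min_spikes: int = PS_MIN_SPIKES,
) -> list[SingleNeuronBurst]:
    """Poisson-Surprise burst detection for one unit.

    Candidate groups are maximal runs of consecutive spikes joined by ISIs
    strictly below the unit's mean ISI; within each group the contiguous
    sub-window maximizing S is retained when S >= ``s_threshold`` and the
    sub-window holds >= ``min_spikes`` spikes. The Poisson rate is the
    unit's overall mean rate (count / duration).
    """
    times = np.sort(np.asarray(times, dtype=float))
    if times.size < 3:
        return []
    isis = np.diff(times)
    mean_isi = isis.mean()
    rate = times.size / duration
    breaks = np.flatnonzero(isis >= mean_isi) + 1
    bursts = []
    for g in np.split(np.arange(times.size), breaks):
        if g.size < min_spikes:
            continue
        t = times[g]
        best = None
        for i in range(t.size):
            for j in range(i + min_spikes - 1, t.size):
                span = t[j] - t[i]
                if span <= 0:
                    continue
                s = poisson_surprise(j - i + 1, span, rate)
                if best is None or s > best[0]:
                    best = (s, i, j)
        if best and best[0] >= s_threshold:
            s, i, j = best
            bursts.append(
                SingleNeuronBurst(
                    unit_id=unit_id,
                    start=float(t[i]),
                    end=float(t[j]),
                    n_spikes=int(j - i + 1),
                    surprise=float(s),
                    spike_times=t[i:j + 1].copy(),
                )
            )
    return bursts


def _max_frequency(burst_times: np.ndarray, mf_bin: float) -> tuple[float, float]:
    """(max bin rate in Hz, time of the max bin center) for one burst."""
    t0 = burst_times[0]
    n_bins = max(1, int(np.ceil((burst_times[-1] - t0) / mf_bin)))
    h, edges = np.histogram(burst_times, bins=n_bins, range=(t0, t0 + n_bins * mf_bin))
    k = int(np.argmax(h))
    return h[k] / mf_bin, 0.5 * (edges[k] + edges[k + 1])


_PARAMS = [
    "TS", "n_bursts", "IBI", "duration", "spikes_per_burst", "MF", "IMFI",
    "CV_IBI", "CV_duration", "CV_spikes", "CV_MF", "CV_IMFI",
]


def burst_parameter_table(
    bursts: list,
    total_spikes: int,
    duration: float,
    mf_bin: float = MF_BIN_S,
) -> pd.Series:
    """The 12 burst parameters for one condition.

    TS: total spikes in the recording; n_bursts; IBI: mean onset-to-onset
    inter-burst interval; duration and spikes_per_burst: burst means;
    MF: mean over bursts of the maximum intra-burst bin rate (``mf_bin``
    histogram, expressed in Hz); IMFI: mean interval between successive
    bursts' MF bin centers; plus the CVs (SD/mean) of the five burst
    quantities. Entries that need >= 1 burst (or >= 2 for intervals/CVs)
    are NaN, mirroring the N/A convention for lost bursts.

    Works for network bursts and single-neuron bursts alike (the
    single-neuron table is the same 12 parameters per unit).
    """
    out = pd.Series(np.nan, index=_PARAMS, dtype=float)
    out["TS"] = total_spikes
    out["n_bursts"] = len(bursts)
    if not bursts:
        return out
    starts = np.array([b.start for b in bursts])
    durs = np.array([b.duration for b in bursts])
    counts = np.array([b.n_spikes for b in bursts], dtype=float)
    mf = np.empty(len(bursts))
    mf_t = np.empty(len(bursts))
    for i, b in enumerate(bursts):
        mf[i], mf_t[i] = _max_frequency(b.spike_times, mf_bin)
    out["duration"] = durs.mean()
    out["spikes_per_burst"] = counts.mean()
    out["MF"] = mf.mean()
    if len(bursts) >= 2:
        ibis = np.diff(starts)
        imfis = np.diff(mf_t)
        out["IBI"] = ibis.mean()
        out["IMFI"] = imfis.mean()
        out["CV_IBI"] = _cv(ibis)
        out["CV_IMFI"] = _cv(imfis)
        out["CV_duration"] = _cv(durs)
        out["CV_spikes"] = _cv(counts)
        out["CV_MF"] = _cv(mf)
    return out


def _cv(x: np.ndarray) -> float:
    m = x.mean()
    if m == 0:
        return np.nan
    return float(x.std(ddof=0) / m)


def normalize_to_vehicle(condition: pd.Series, vehicle: pd.Series) -> pd.Series:
    """Each parameter as a percentage of its vehicle value (vehicle = 100%).

    NaN where the vehicle value is 0 or either entry is N/A.
    """
    out = pd.Series(np.nan, index=condition.index, dtype=float)
    for k in condition.index:
        v = vehicle.get(k, np.nan)
        c = condition[k]
        if np.isfinite(v) and np.isfinite(c) and v != 0:
            out[k] = 100.0 * c / v
    return out
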