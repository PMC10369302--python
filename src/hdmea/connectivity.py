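"""Directed functional connectivity by surrogate-calibrated synchronized-spike
counting.

For an ordered unit pair (reference -> target), the synchronized-spike count
is the number of target spikes falling within 100 ms after each reference
spike. The null distribution comes from 100 surrogates of the target train
built by randomly permuting its inter-spike intervals (first spike anchored,
so span, count and rate are conserved). The connection Z score is
(real - surrogate mean) / surrogate SD; Z >= 3 is called excitatory,
Z <= -3 inhibitory. The per-unit excitability connection rate (ECR) is the
percentage of a unit's n-1 possible partners with Z >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYNC_WINDOW_S = 0.100
N_SURROGATES = 100
Z_EXCITATORY = 3.0
Z_INHIBITORY = -3.0


class ParameterError(ValueError):
    pass


def count_synchronized_spikes(ref: np.ndarray, target: np.ndarray, window: float = SYNC_WINDOW_S) -> int:
    """Number of target spikes in (t, t + window] summed over reference spikes t.

    Directional (ref -> target); the window is half-open so a simultaneous
    spike is not counted.
    """
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    if ref.size == 0 or target.size == 0:
        return 0
    hi = np.searchsorted(target, ref + window, side="right")
    lo = np.searchsorted(target, ref, side="right")
    return int(np.sum(hi - lo))


def make_isi_surrogates(times: np.ndarray, n: int = N_SURROGATES, rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """ISI-shuffled surrogate spike trains.

    Each surrogate anchors the first spike time and applies a random
    permutation of the inter-spike intervals, conserving the spike count,
    the last spike time, and the ISI multiset exactly.
    """
    times = np.sort(np.asarray(times, dtype=float))
    rng = np.random.default_rng() if rng is None else rng
    if times.size < 2:
        import warnings

        warnings.warn("train has < 2 spikes; surrogates identical to input", stacklevel=2)
        return [times.copy() for _ in range(n)]
    isis = np.diff(times)
    out = []
    for _ in range(n):
        shuffled = rng.permutation(isis)
        out.append(times[0] + np.concatenate([[0.0], np.cumsum(shuffled)]))
    return out


def connection_z_score(
    ref: np.ndarray,
    target: np.ndarray,
    n_surrogates: int = N_SURROGATES,
    window: float = SYNC_WINDOW_S,
    rng: np.random.Generator | None = None,
    shuffle_both: bool = False,
) -> float:
    """Z score of the real synchronized-spike count against ISI surrogates.

    Returns NaN (undefined) when the surrogate SD is zero and the real count
    differs from the degenerate surrogate value; 0 when they coincide.
    """
    rng = np.random.default_rng() if rng is None else rng
    real = count_synchronized_spikes(ref, target, window)
    targ_surr = make_isi_surrogates(target, n_surrogates, rng)
    if shuffle_both:
        ref_surr = make_isi_surrogates(ref, n_surrogates, rng)
    else:
        ref_surr = [np.asarray(ref, dtype=float)] * n_surrogates
    counts = np.array(
        [count_synchronized_spikes(r, t, window) for r, t in zip(ref_surr, targ_surr)],
        dtype=float,
    )
    sd = counts.std(ddof=1)
    mean = counts.mean()
    if sd == 0:
        return 0.0 if real == mean else float("nan")
    return float((real - mean) / sd)


@dataclass
class ConnectivityResult:
    """Directed connectivity for a unit population.

    ``z[i, j]`` scores the i -> j connection; ``real``/``surr_mean``/
    ``surr_sd`` hold the underlying synchronized-spike statistics; the
    classification is 1 (excitatory, Z >= 3), -1 (inhibitory, Z <= -3) or 0.
    """

    unit_ids: list[int]
    real: np.ndarray
    surr_mean: np.ndarray
    surr_sd: np.ndarray
    z: np.ndarray
    n_surrogates: int
    window: float
    seed: int | None = None
    classification: np.ndarray = field(init=False)

    def __post_init__(self):
        c = np.zeros_like(self.z, dtype=int)
        with np.errstate(invalid="ignore"):
            c[self.z >= Z_EXCITATORY] = 1
            c[self.z <= Z_INHIBITORY] = -1
        np.fill_diagonal(c, 0)
        self.classification = c


def connectivity_matrix(
    trains: dict[int, np.ndarray],
    n_surrogates: int = N_SURROGATES,
    window: float = SYNC_WINDOW_S,
    seed: int | None = None,
) -> ConnectivityResult:
    """Full directed Z-score matrix over all ordered unit pairs."""
    rng = np.random.default_rng(seed)
    ids = sorted(trains)
    n = len(ids)
    real = np.zeros((n, n))
    mean = np.zeros((n, n))
    sd = np.zeros((n, n))
    z = np.full((n, n), np.nan)
    # surrogate counts depend only on the target train and each reference
    # train; precompute surrogates once per target
    surrogates = {j: make_isi_surrogates(trains[ids[j]], n_surrogates, rng) for j in range(n)}
    for i in range(n):
        ref = np.asarray(trains[ids[i]], dtype=float)
        for j in range(n):
            if i == j:
                z[i, j] = 0.0
                continue
            real[i, j] = count_synchronized_spikes(ref, trains[ids[j]], window)
            counts = np.array(
                [count_synchronized_spikes(ref, s, window) for s in surrogates[j]],
                dtype=float,
            )
            mean[i, j] = counts.mean()
            sd[i, j] = counts.std(ddof=1)
            if sd[i, j] > 0:
                z[i, j] = (real[i, j] - mean[i, j]) / sd[i, j]
            elif real[i, j] == mean[i, j]:
                z[i, j] = 0.0
    return ConnectivityResult(
        unit_ids=ids, real=real, surr_mean=mean, surr_sd=sd, z=z,
        n_surrogates=n_surrogates, window=window, seed=seed,
    )


def classify_and_summarize(z: np.ndarray) -> pd.Series:
    """Network-level connection percentages over ordered off-diagonal pairs."""
    n = z.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = z[off]
    finite = np.isfinite(vals)
    total = off.sum()
    exc = np.sum(vals[finite] >= Z_EXCITATORY)
    inh = np.sum(vals[finite] <= Z_INHIBITORY)
    return pd.Series(
        {
            "n_pairs": float(total),
            "pct_excitatory": 100.0 * exc / total if total else 0.0,
            "pct_inhibitory": 100.0 * inh / total if total else 0.0,
        }
    )


def ecr(z_row: np.ndarray, n_units: int, self_index: int | None = None) -> float:
    """Excitability connection rate for one unit, percent.

    100 * |{j != i : Z_ij >= 3}| / (n_units - 1). ``z_row`` may include the
    self entry (pass ``self_index``) or hold partners only.
    """
    if n_units < 2:
        raise ParameterError("ECR requires at least 2 units")
    z_row = np.asarray(z_row, dtype=float)
    mask = np.ones(z_row.size, dtype=bool)
    if self_index is not None:
        mask[self_index] = False
    vals = z_row[mask]
    with np.errstate(invalid="ignore"):
        k = int(np.sum(vals >= Z_EXCITATORY))
    return 100.0 * k / (n_units - 1)
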