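"""Evoked-response histograms and hierarchical Ward clustering.

Each unit's response to an administration is a 100-bin histogram of spike
counts over the 10 s post-administration window (100 ms bins). Responses
are clustered by agglomerative Ward linkage on Euclidean distances and cut
at k clusters (k = 5 by default); per-cluster summaries report the peak of
the mean rate profile, its time, and the 10-s mean rate, plus per-condition
cluster proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

EVOKED_WINDOW_S = 10.0
EVOKED_BIN_S = 0.100
DEFAULT_K = 5


class ParameterError(ValueError):
    pass


@dataclass
class ResponseVector:
    """One unit's post-administration response histogram (raw counts)."""

    unit_id: int
    condition: str
    counts: np.ndarray
    bin_s: float = EVOKED_BIN_S

    @property
    def rate_hz(self) -> np.ndarray:
        return self.counts / self.bin_s


def response_histograms(
    trains: dict[int, np.ndarray],
    t0: float,
    condition: str = "",
    window: float = EVOKED_WINDOW_S,
    bin_s: float = EVOKED_BIN_S,
) -> list[ResponseVector]:
    """Per-unit spike-count histograms over [t0, t0 + window)."""
    n_bins = int(round(window / bin_s))
    out = []
    for uid in sorted(trains):
        h, _ = np.histogram(
            np.asarray(trains[uid], dtype=float), bins=n_bins, range=(t0, t0 + n_bins * bin_s)
        )
        out.append(ResponseVector(unit_id=uid, condition=condition, counts=h, bin_s=bin_s))
    return out


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1..k per response
    linkage: np.ndarray
    k: int


def ward_cluster(vectors: list[ResponseVector], k: int = DEFAULT_K) -> ClusterResult:
    """Agglomerative clustering with Euclidean metric and Ward linkage,
    cut at ``k`` clusters. Vectors are clustered as raw counts."""
    if len(vectors) < k:
        raise ParameterError(f"need >= {k} vectors, got {len(vectors)}")
    X = np.vstack([v.counts for v in vectors]).astype(float)
    if len(vectors) == 1:
        return ClusterResult(labels=np.array([1]), linkage=np.empty((0, 4)), k=1)
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(labels=labels, linkage=Z, k=int(labels.max()))


def cluster_summaries(
    result: ClusterResult, vectors: list[ResponseVector]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster response statistics and per-condition cluster proportions.

    Returns
    -------
    stats : DataFrame (cluster, n, peak_rate_hz, peak_time_s, mean_rate_hz)
        Peak of the cluster-mean rate profile, its bin-center time, and the
        mean rate over the whole window.
    proportions : DataFrame (condition, cluster, pct); percentages sum to
        100 within each condition.
    """
    labels = result.labels
    rows = []
    for c in range(1, result.k + 1):
        members = [v for v, lab in zip(vectors, labels) if lab == c]
        if not members:
            continue
        bin_s = members[0].bin_s
        mean_counts = np.mean([v.counts for v in members], axis=0)
        rate = mean_counts / bin_s
        j = int(np.argmax(rate))
        rows.append(
            {
                "cluster": c,
                "n": len(members),
                "peak_rate_hz": float(rate[j]),
                "peak_time_s": (j + 0.5) * bin_s,
                "mean_rate_hz": float(rate.mean()),
            }
        )
    stats = pd.DataFrame(rows)
    prop_rows = []
    conditions = sorted({v.condition for v in vectors})
    for cond in conditions:
        idx = [i for i, v in enumerate(vectors) if v.condition == cond]
        n = len(idx)
        for c in range(1, result.k + 1):
            count = sum(1 for i in idx if labels[i] == c)
            prop_rows.append({"condition": cond, "cluster": c, "pct": 100.0 * count / n})
    return stats, pd.DataFrame(prop_rows)
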