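"""k-means clustering of TE trajectories under Pearson-correlation distance.

Profiles are per-transcript TE values over the ordered stages.  Distance is
d = 1 - r (r the Pearson correlation), so shape, not scale, drives the
grouping: a profile and any positive affine transform of it are at distance
zero.  Centroids are means of per-row z-standardized profiles, re-standardized
so the mean stays a valid representative under 1 - r.  Zero-variance rows
have undefined correlation and must be removed before clustering.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_MAX_ITER = 5_000_000


class ZeroVarianceError(ValueError):
    pass


def _zscore(arr: np.ndarray) -> np.ndarray:
    sd = arr.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ZeroVarianceError("zero-variance profile: correlation undefined")
    return (arr - arr.mean(axis=-1, keepdims=True)) / sd


def pearson_distance(x, y) -> float:
    """1 - Pearson r; in [0, 2]. Requires >= 2 entries and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("profiles must be 1-D, equal length >= 2")
    zx, zy = _zscore(x), _zscore(y)
    r = float(np.dot(zx, zy) / len(x))
    return 1.0 - r


def drop_zero_variance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Split off rows whose profile is constant (undefined correlation)."""
    sd = matrix.std(axis=1, ddof=0)
    flagged = list(matrix.index[sd == 0])
    return matrix.loc[sd > 0], flagged


@dataclass
class ClusterAssignment:
    k: int
    labels: pd.Series           # row id -> cluster id
    centroids: np.ndarray       # k x n_stages, z-standardized
    seed: int
    iterations_run: int
    max_iterations: int
    objective: float            # total within-cluster 1 - r distance

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def kmeans_cluster(matrix: pd.DataFrame, k: int, seed: int = 0,
                   max_iter: int = DEFAULT_MAX_ITER) -> ClusterAssignment:
    """Lloyd alternation under Pearson distance; deterministic given seed.

    Empty clusters are re-seeded from the point farthest from its centroid;
    nearest-centroid ties break toward the lowest cluster id.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of rows {len(matrix)}")
    z = _zscore(matrix.to_numpy(float))
    n, m = z.shape
    rng = np.random.default_rng(seed)
    centroids = z[rng.choice(n, size=k, replace=False)]

    labels = np.full(n, -1)
    it = 0
    while it < max_iter:
        it += 1
        # distances: 1 - (z . c)/m; argmin takes lowest cluster id on ties
        d = 1.0 - (z @ centroids.T) / m
        new_labels = d.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):  # re-seed from farthest point
                far = d[np.arange(n), new_labels].argmax()
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            mean = z[labels == c].mean(axis=0)
            sd = mean.std()
            centroids[c] = (mean - mean.mean()) / sd if sd > 0 else mean - mean.mean()
    d = 1.0 - (z @ centroids.T) / m
    objective = float(d[np.arange(n), labels].sum())
    return ClusterAssignment(k, pd.Series(labels, index=matrix.index),
                             centroids, seed, it, max_iter, objective)


def total_distance(matrix: pd.DataFrame, labels: pd.Series) -> float:
    """Objective of an arbitrary labeling (for baselines): within-cluster sum
    of 1 - r to the z-standardized mean profile."""
    z = _zscore(matrix.to_numpy(float))
    m = z.shape[1]
    lab = labels.reindex(matrix.index).to_numpy()
    total = 0.0
    for c in np.unique(lab):
        zc = z[lab == c]
        mean = zc.mean(axis=0)
        sd = mean.std()
        cent = (mean - mean.mean()) / sd if sd > 0 else mean - mean.mean()
        total += float((1.0 - (zc @ cent) / m).sum())
    return total


def summarize_clusters(assignment: ClusterAssignment,
                       annotations: Mapping[str, str] | None = None,
                       ) -> pd.DataFrame:
    """Per cluster: member count, family-label frequencies, centroid profile."""
    annotations = annotations or {}
    rows = []
    for c in range(assignment.k):
        members = assignment.members(c)
        freq: dict[str, float] = {}
        for tid in members:
            label = annotations.get(tid, "unknown")
            freq[label] = freq.get(label, 0) + 1
        n = max(len(members), 1)
        freq = {lab: cnt / n for lab, cnt in
                sorted(freq.items(), key=lambda kv: -kv[1])}
        rows.append({"cluster": c, "n_members": len(members),
                     "label_frequencies": freq,
                     "centroid": assignment.centroids[c].round(4).tolist()})
    return pd.DataFrame(rows).set_index("cluster")


def silhouette_scan(matrix: pd.DataFrame, k_range=range(2, 11),
                    seed: int = 0) -> pd.Series:
    """Mean silhouette (Pearson distance) per k; guidance only, not applied."""
    z = _zscore(matrix.to_numpy(float))
    m = z.shape[1]
    d_full = 1.0 - (z @ z.T) / m
    out = {}
    for k in k_range:
        if k >= len(matrix):
            break
        labels = kmeans_cluster(matrix, k, seed=seed).labels.to_numpy()
        sil = []
        for i in range(len(matrix)):
            same = labels == labels[i]
            same[i] = False
            a = d_full[i, same].mean() if same.any() else 0.0
            b = min(d_full[i, labels == c].mean()
                    for c in np.unique(labels) if c != labels[i])
            sil.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
        out[k] = float(np.mean(sil))
    return pd.Series(out, name="silhouette")


def replicate_correlations(rpkm: pd.DataFrame) -> pd.DataFrame:
    """QC: Pearson r between replicate RPKM vectors per (stage, type) pair."""
    from .models import LibraryKey

    keys = [LibraryKey.from_label(c) for c in rpkm.columns]
    groups: dict[tuple[str, str], list[str]] = {}
    for key in keys:
        groups.setdefault((key.stage, key.lib_type), []).append(key.label)
    rows = []
    for (stage, lib_type), labels in groups.items():
        labels = sorted(labels)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                x = rpkm[labels[i]].to_numpy(float)
                y = rpkm[labels[j]].to_numpy(float)
                r = float(np.corrcoef(x, y)[0, 1])
                rows.append({"stage": stage, "type": lib_type,
                             "rep_a": labels[i], "rep_b": labels[j], "r": r})
    return pd.DataFrame(rows)
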