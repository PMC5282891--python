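"""Co-expression clustering: expressed filter, z-scaling, WPGMA tree cut.

Profiles are z-scaled per transcript across libraries (population sd), the
pairwise distance is 1 - Pearson correlation (Euclidean optional), trees are
built with the WPGMA merge rule d(k, i u j) = (d(k,i) + d(k,j)) / 2, and
clusters are the connected components after cutting merges above the cut
height (default 0.69 on the correlation-distance scale).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io_formats import ExpressionTable


def expressed_filter(expr: ExpressionTable, threshold: float = 1.0) -> set[str]:
    """Transcripts with FPKM strictly above ``threshold`` in >= 1 library."""
    mask = (expr.values > threshold).any(axis=1)
    return set(expr.values.index[mask])


def zscale(expr: ExpressionTable, ids=None, ddof: int = 0) -> pd.DataFrame:
    """Per-transcript z-scores across libraries (population sd by default).

    Zero-variance profiles are mapped to all-zero rows with a warning.
    """
    df = expr.values if ids is None else expr.subset(ids).values
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant profiles z-scaled to all zeros")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd_safe
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def _cluster_labels(n: int) -> list[str]:
    """Deterministic labels A, B, ..., Z, AA, AB, ... in first-appearance order."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


@dataclass
class ClusterAssignment:
    """Flat clusters plus the merge tree they were cut from."""

    labels: dict[str, str]          # transcript_id -> cluster label
    linkage_matrix: np.ndarray      # scipy linkage encoding of the WPGMA tree
    cut: float
    ids: list[str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tid, lab in self.labels.items():
            out.setdefault(lab, []).append(tid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": self.ids, "cluster": [self.labels[t] for t in self.ids]}
        ).set_index("transcript_id")


def correlation_distance(scaled: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance on z-scaled rows.

    For rows with population-z scaling, Pearson r is (x . y) / n, which keeps
    all-zero (formerly constant) rows well-defined: r = 0, distance 1.
    """
    z = scaled.to_numpy(dtype=float)
    # rows are mean 0 after z-scaling; unit-normalise so r = x . y
    norms = np.linalg.norm(z, axis=1)
    unit = z / np.where(norms == 0, 1.0, norms)[:, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def wpgma_cluster(
    scaled: pd.DataFrame, cut: float = 0.69, metric: str = "correlation"
) -> ClusterAssignment:
    """WPGMA agglomeration of scaled profiles, cut into flat clusters.

    ``metric`` is "correlation" (1 - Pearson, the default and the scale on
    which the 0.69 cut is interpreted) or "euclidean".  Merges at height
    exactly equal to ``cut`` stay together; only merges strictly above the
    cut are severed.  Cluster labels are letters in order of first
    appearance along the input ordering.
    """
    ids = list(scaled.index)
    if len(ids) == 0:
        return ClusterAssignment({}, np.empty((0, 4)), cut, [])
    if len(ids) == 1:
        return ClusterAssignment({ids[0]: "A"}, np.empty((0, 4)), cut, ids)
    if metric == "correlation":
        condensed = correlation_distance(scaled)
    elif metric == "euclidean":
        condensed = pdist(scaled.to_numpy(dtype=float), metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(condensed, method="weighted")
    flat = fcluster(Z, t=cut, criterion="distance")
    labels_in_order: dict[int, str] = {}
    names = _cluster_labels(len(set(flat)))
    for c in flat:
        if c not in labels_in_order:
            labels_in_order[c] = names[len(labels_in_order)]
    labels = {tid: labels_in_order[c] for tid, c in zip(ids, flat)}
    return ClusterAssignment(labels, Z, cut, ids)


def cluster_expressed(
    expr: ExpressionTable,
    threshold: float = 1.0,
    cut: float = 0.69,
    metric: str = "correlation",
) -> ClusterAssignment:
    """Convenience: expressed filter -> z-scale -> WPGMA cut."""
    ids = [t for t in expr.transcripts if t in expressed_filter(expr, threshold)]
    scaled = zscale(expr, ids)
    return wpgma_cluster(scaled, cut=cut, metric=metric)
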