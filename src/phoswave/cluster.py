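"""Ward hierarchical clustering of temporal profiles with elbow selection.

Linkage follows the ward.D2 convention: agglomeration by the Lance-Williams
update on Euclidean distances with un-squared merge heights (scipy's
``ward`` method).  The cluster count is chosen, when not given, by a
deterministic elbow rule on the within-group sum-of-squares curve; cluster
ids are renumbered by order of first appearance in the input, matching R's
``cutree`` labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class ClusterResult:
    labels: pd.Series       # feature id -> cluster id in 1..k
    linkage: np.ndarray     # scipy linkage matrix (child, child, height, size)
    k: int
    wss_curve: pd.Series    # within-group sum of squares per candidate k

    def members(self, cluster_id: int) -> pd.Index:
        return self.labels.index[self.labels == cluster_id]


def _relabel_by_appearance(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by first appearance in data order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def within_group_ss(values: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of squared Euclidean distance to the centroid."""
    total = 0.0
    for lab in np.unique(labels):
        block = values[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def elbow_k(wss: Mapping[int, float]) -> int:
    """Deterministic elbow: k with the largest second difference of WSS.

    The curvature wss(k-1) - 2 wss(k) + wss(k+1) is evaluated for every
    interior candidate k; the argmax (smallest k on ties) is returned.
    """
    ks = sorted(wss)
    if len(ks) < 3:
        return ks[-1]
    best_k, best_curv = ks[1], -np.inf
    for k in ks[1:-1]:
        curv = wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
        if curv > best_curv:
            best_curv, best_k = curv, k
    return best_k


def ward_cluster(
    profiles: pd.DataFrame,
    k: int | None = None,
    kmax: int = 15,
) -> ClusterResult:
    """Cluster scaled temporal profiles by Ward linkage.

    When ``k`` is None it is selected by :func:`elbow_k` over 1..kmax.
    ``k`` is always overridable to reproduce a previously chosen cut.
    """
    values = profiles.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("profiles must be finite")
    n = len(profiles)
    if n < 2:
        raise ValueError("need at least two profiles")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of profiles {n}")
    Z = linkage(values, method="ward")
    kmax_eff = min(kmax, n)
    wss = {}
    for kk in range(1, kmax_eff + 1):
        labels = fcluster(Z, t=kk, criterion="maxclust")
        wss[kk] = within_group_ss(values, labels)
    wss_curve = pd.Series(wss, name="wss")
    wss_curve.index.name = "k"
    if k is None:
        k = elbow_k(wss)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(_relabel_by_appearance(raw), index=profiles.index,
                       name="cluster")
    return ClusterResult(labels=labels, linkage=Z, k=int(k),
                         wss_curve=wss_curve)


def cluster_summary(
    profiles: pd.DataFrame, result: ClusterResult,
) -> pd.DataFrame:
    """Per-cluster median and quartile profiles across timepoints.

    Columns: cluster, timepoint, n, median, q25, q75.
    """
    missing = result.labels.index.difference(profiles.index)
    if len(missing):
        raise ValueError(f"assignments cover unknown features: "
                         f"{list(missing[:5])}")
    rows = []
    for cid in range(1, result.k + 1):
        members = result.members(cid)
        if len(members) == 0:
            raise ValueError(f"cluster {cid} is empty")
        block = profiles.loc[members]
        med = block.median()
        q25 = block.quantile(0.25)
        q75 = block.quantile(0.75)
        for col in profiles.columns:
            rows.append({
                "cluster": cid,
                "timepoint": col,
                "n": len(members),
                "median": med[col],
                "q25": q25[col],
                "q75": q75[col],
            })
    return pd.DataFrame(rows)


def linkage_frame(result: ClusterResult) -> pd.DataFrame:
    """Flat-text form of the merge tree (child ids, height, size)."""
    Z = result.linkage
    return pd.DataFrame({
        "child_a": Z[:, 0].astype(int),
        "child_b": Z[:, 1].astype(int),
        "height": Z[:, 2],
        "size": Z[:, 3].astype(int),
    })
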