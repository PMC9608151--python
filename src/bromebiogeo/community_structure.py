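"""Core-community inference, group-exclusivity (Venn) partition, and
silhouette-guided hierarchical clustering of ASV abundance profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .tables_io import CountTable, to_relative


@dataclass
class VennPartition:
    """Counts of ASVs by the exact subset of groups they occupy.

    ``regions`` maps a sorted tuple of group labels to the number of
    non-zero ASVs whose occupied samples fall in exactly those groups;
    regions are disjoint and sum to the number of occupied ASVs.
    """

    regions: dict[tuple[str, ...], int]
    total_asvs: int

    def percentage(self, region: tuple[str, ...]) -> float:
        return 100.0 * self.regions.get(tuple(sorted(region)), 0) / self.total_asvs

    def single_group_fraction(self) -> float:
        """Fraction of occupied ASVs confined to exactly one group."""
        solo = sum(n for reg, n in self.regions.items() if len(reg) == 1)
        return solo / self.total_asvs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(reg), "n_asvs": n, "pct": 100.0 * n / self.total_asvs}
            for reg, n in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class ProfileClustering:
    asv_order: list[str]          # leaf order of the dendrogram
    labels: pd.Series             # asv_id -> cluster id
    k: int
    silhouette_by_k: dict[int, float]


def core_asvs(t: CountTable) -> pd.DataFrame:
    """ASVs present (count > 0) in every sample, with their per-sample
    relative abundances."""
    pres = t.presence()
    ubiquitous = pres.all(axis=1)
    rel = to_relative(t).proportions
    return rel.loc[ubiquitous]


def partition_by_group(t: CountTable) -> VennPartition:
    """Assign every occupied ASV to the exact subset of groups where it
    occurs (the Venn-diagram partition of the regional pool)."""
    if t.groups is None:
        raise ValueError("partition_by_group requires group labels")
    pres = t.presence()
    group_order = t.group_labels()
    cols_by_group = {g: [t.sample_ids.index(s) for s in t.group_samples(g)] for g in group_order}
    occ_by_group = np.column_stack(
        [pres[:, cols_by_group[g]].any(axis=1) for g in group_order]
    )
    regions: dict[tuple[str, ...], int] = {}
    total = 0
    for row in occ_by_group:
        if not row.any():
            continue
        total += 1
        reg = tuple(sorted(g for g, occ in zip(group_order, row) if occ))
        regions[reg] = regions.get(reg, 0) + 1
    return VennPartition(regions, total)


def within_group_core_fraction(t: CountTable, group: str) -> float:
    """Of the ASVs found anywhere in ``group``, the fraction found in
    every one of its samples."""
    samples = t.group_samples(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples")
    pres = t.subset_samples(samples).presence()
    anywhere = pres.any(axis=1)
    if not anywhere.any():
        return 0.0
    everywhere = pres.all(axis=1)
    return float(everywhere.sum() / anywhere.sum())


def cluster_profiles(
    t: CountTable,
    k_range: range | list[int] = range(2, 11),
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ProfileClustering:
    """Hierarchically cluster row-normalized ASV abundance profiles.

    ASVs present in only one sample are removed; each remaining ASV's
    abundance vector is divided by its own total, so clustering reflects
    *where* an ASV lives, not how abundant it is. The number of clusters
    is the k in ``k_range`` maximizing the mean silhouette (smallest k
    wins ties). Rows are sorted by ASV id before clustering so the result
    does not depend on input order.
    """
    pres = t.presence()
    keep = pres.sum(axis=1) >= 2
    if keep.sum() < 2:
        raise ValueError("fewer than two ASVs occur in more than one sample")
    sub = t.counts.loc[keep].sort_index()
    profiles = sub.to_numpy(dtype=float)
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    Z = hierarchy.linkage(profiles, method=linkage_method, metric=metric)
    ks = [k for k in k_range if 2 <= k <= len(sub) - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(profiles, lab, metric=metric))
    best_k = min(ks, key=lambda k: (-round(sil[k], 12), k))
    leaf_order = hierarchy.leaves_list(Z)
    return ProfileClustering(
        asv_order=[sub.index[i] for i in leaf_order],
        labels=pd.Series(labels_by_k[best_k], index=sub.index, name="cluster"),
        k=best_k,
        silhouette_by_k=sil,
    )
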