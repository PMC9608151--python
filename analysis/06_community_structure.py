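#!/usr/bin/env python
"""Core community, forest-exclusivity partition and ASV profile clusters.

The core community is the set of ASVs found in every sample; the Venn
partition assigns each ASV to the exact subset of forests where it
occurs; profile clustering groups ASVs by where in the dataset their
reads fall (row-normalized abundance profiles, average-linkage
hierarchical clustering, silhouette-optimal k).
"""

from pathlib import Path

import pandas as pd

from bromebiogeo import (
    cluster_profiles,
    core_asvs,
    partition_by_group,
    read_count_table,
    within_group_core_fraction,
)

STUDY = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    t = read_count_table(STUDY / "filtered.tsv", STUDY / "metadata.tsv")

    core = core_asvs(t)
    core.round(5).to_csv(RESULTS / "core_asvs.tsv", sep="\t")
    total = len(t.occupied_asvs())
    print(f"core community: {len(core)} ASVs "
          f"({100 * len(core) / total:.2f}% of {total} occupied ASVs)")

    venn = partition_by_group(t)
    venn.to_frame().to_csv(RESULTS / "venn_partition.tsv", sep="\t", index=False)
    print(f"{100 * venn.single_group_fraction():.1f}% of ASVs occur in a single forest")
    for g in t.group_labels():
        frac = within_group_core_fraction(t, g)
        print(f"  {g}: {100 * frac:.1f}% of its ASVs present in all its samples")

    clus = cluster_profiles(t, k_range=range(2, 11))
    summary = clus.labels.value_counts().sort_index().rename("n_asvs").to_frame()
    summary.index.name = "cluster"
    summary.to_csv(RESULTS / "profile_clusters.tsv", sep="\t")
    print(f"profile clustering chose k = {clus.k} "
          f"(silhouette {clus.silhouette_by_k[clus.k]:.3f}); "
          f"cluster sizes {clus.labels.value_counts().sort_index().tolist()}")


if __name__ == "__main__":
    main()
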