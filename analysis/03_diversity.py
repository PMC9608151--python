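#!/usr/bin/env python
"""Alpha diversity and taxonomic composition.

Effective number of species (inverse Simpson) per sample on the rarefied
table, a Kruskal-Wallis test of forest differences, and phylum-level
relative abundances with taxa under 1% of the dataset pooled as
'others'.
"""

from pathlib import Path

import pandas as pd

from bromebiogeo import (
    aggregate_at_rank,
    collapse_rare,
    effective_species_per_sample,
    kruskal_wallis,
    read_count_table,
    read_taxonomy,
    to_relative,
)

STUDY = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    rare = read_count_table(STUDY / "rarefied.tsv", STUDY / "metadata.tsv")
    ens = effective_species_per_sample(rare)
    kw = kruskal_wallis(ens.to_numpy(), [rare.groups[s] for s in ens.index])
    out = pd.DataFrame({
        "sample_id": ens.index,
        "forest": [rare.groups[s] for s in ens.index],
        "ENS": ens.to_numpy().round(2),
    })
    out.to_csv(RESULTS / "ens.tsv", sep="\t", index=False)
    print(f"ENS range {ens.min():.0f}-{ens.max():.0f} across samples")
    print(f"forest effect on ENS: H({kw.df}) = {kw.H:.2f}, p = {kw.p:.3f}")

    filtered = read_count_table(STUDY / "filtered.tsv", STUDY / "metadata.tsv")
    tax = read_taxonomy(STUDY / "taxonomy.tsv")
    phylum = collapse_rare(aggregate_at_rank(to_relative(filtered), tax, rank=1))
    phylum.proportions.round(4).to_csv(RESULTS / "composition_phylum.tsv", sep="\t")
    print(f"phylum table: {len(phylum.proportions)} rows "
          f"(rare phyla pooled into 'others') -> results/composition_phylum.tsv")


if __name__ == "__main__":
    main()
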