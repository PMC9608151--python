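#!/usr/bin/env python
"""Discard shallow libraries and rarefy the remainder to a common depth.

Samples under 1,000 reads are removed (the standard depth filter for
amplicon libraries); the rest are subsampled without replacement to the
minimum retained depth so diversity and overlap statistics are not
confounded by sequencing effort.
"""

from pathlib import Path

from bromebiogeo import (
    filter_low_depth,
    min_depth,
    rarefy,
    read_count_table,
    write_count_table,
)

SEED = 17
STUDY = Path("scratch/study")


def main() -> None:
    t = read_count_table(STUDY / "counts.tsv", STUDY / "metadata.tsv")
    filtered = filter_low_depth(t, min_reads=1000)
    dropped = sorted(set(t.sample_ids) - set(filtered.sample_ids))
    print(f"retained {len(filtered.sample_ids)}/{len(t.sample_ids)} samples; "
          f"discarded {dropped}")

    depth = min_depth(filtered)
    rare = rarefy(filtered, depth, seed=SEED)
    print(f"rarefied all samples to the minimum depth ({depth} reads)")

    write_count_table(filtered, STUDY / "filtered.tsv")
    write_count_table(rare, STUDY / "rarefied.tsv")


if __name__ == "__main__":
    main()
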