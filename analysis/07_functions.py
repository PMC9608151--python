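#!/usr/bin/env python
"""Putative metabolic functions from the taxon->function rule engine.

Every ASV whose lineage matches a rule contributes its reads to the
matched functional groups; groups under 1% of all assignments are
pooled as 'others'; core functional groups are those detected in every
sample.
"""

from pathlib import Path

from bromebiogeo import (
    assign_functions,
    core_functions,
    functional_abundance,
    parse_rules,
    read_count_table,
    read_taxonomy,
)

STUDY = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    t = read_count_table(STUDY / "filtered.tsv", STUDY / "metadata.tsv")
    tax = read_taxonomy(STUDY / "taxonomy.tsv")
    rules = parse_rules(STUDY / "rules.txt")

    assignments = assign_functions(tax, rules)
    fa = functional_abundance(t, assignments)
    fa.proportions.round(5).to_csv(RESULTS / "functional_abundance.tsv", sep="\t")

    n_unassigned = sum(1 for a in t.asv_ids if not assignments.get(a))
    print(f"assigned {fa.n_assigned_asvs} ASVs to functions; "
          f"{100 * n_unassigned / len(t.asv_ids):.1f}% of ASVs unassignable")
    top = fa.proportions.mean(axis=1).sort_values(ascending=False).head(4)
    for g, v in top.items():
        print(f"  {g}: {100 * v:.1f}% of assignments")

    core = core_functions(fa)
    n_seen = (fa.proportions.sum(axis=1) > 0).sum()
    print(f"core functional groups (present in all samples): {len(core)}/{n_seen} "
          f"({100 * len(core) / n_seen:.0f}%)")
    (RESULTS / "core_functions.txt").write_text("\n".join(core) + "\n")


if __name__ == "__main__":
    main()
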