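"""Rule-based assignment of putative metabolic functions to taxa.

A rules file maps functional groups (e.g. methanogenesis, nitrogen
fixation) to taxon patterns; an ASV whose lineage matches any pattern of
a group is assigned to that group, possibly to several groups at once.
This mirrors the literature-curated approach of databases like FAPROTAX:
a function demonstrated for the cultured members of a taxon is
extrapolated to all members of that taxon. The bundled miniature rules
file covers the functional groups most often reported from acidic,
organic-rich freshwater habitats; it is a small, scientifically sensible
stand-in, not a redistribution of any curated database.

Rules grammar (plain text)::

    > functional_group_name
        Domain;Phylum;...;Genus      # any contiguous rank path
        SingleTaxonName

Pattern semantics: a pattern's semicolon-separated rank path matches a
lineage if it occurs as a contiguous run of ranks anywhere in the
lineage (case-insensitive). A one-rank pattern therefore matches that
name at any rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import CountTable, TaxonomyTable, OTHERS_LABEL


class RulesFormatError(ValueError):
    pass


@dataclass
class FunctionalRules:
    """Ordered (group -> taxon patterns) mapping; each pattern is a tuple
    of lower-cased rank names."""

    groups: dict[str, list[tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, pats in self.groups.items():
            if not pats:
                raise RulesFormatError(f"group {name!r} has no patterns")

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)


@dataclass
class FunctionalAbundance:
    """Group x sample matrix of assignment-weighted relative abundances.

    Each (ASV, group) assignment contributes the ASV's read count to that
    group's stream; proportions are over the total assignment-weighted
    reads of the sample, so a multi-function ASV counts once per function.
    """

    proportions: pd.DataFrame        # groups x samples, sums to 1 per sample
    unassigned_fraction: pd.Series   # per sample, fraction of reads unassigned
    n_assigned_asvs: int


def parse_rules(path: str | Path) -> FunctionalRules:
    """Parse a rules file; see the module docstring for the grammar."""
    groups: dict[str, list[tuple[str, ...]]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].rstrip()
            if not line.strip():
                continue
            if line.lstrip().startswith(">"):
                name = line.lstrip()[1:].strip()
                if not name:
                    raise RulesFormatError(f"line {ln}: empty group name")
                if name in groups:
                    raise RulesFormatError(f"line {ln}: duplicate group {name!r}")
                groups[name] = []
                current = name
            else:
                if current is None:
                    raise RulesFormatError(
                        f"line {ln}: pattern before any '>' group header"
                    )
                pat = tuple(p.strip().lower() for p in line.strip().split(";") if p.strip())
                if not pat:
                    raise RulesFormatError(f"line {ln}: empty pattern")
                groups[current].append(pat)
    return FunctionalRules(groups)


def write_rules(rules: FunctionalRules, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, pats in rules.groups.items():
            fh.write(f"> {name}\n")
            for pat in pats:
                fh.write("    " + ";".join(pat) + "\n")


def bundled_rules_path() -> Path:
    """Path to the miniature rules file shipped with the package."""
    return Path(resources.files("bromebiogeo").joinpath("data/mini_rules.txt"))


def _matches(pattern: tuple[str, ...], lineage_lc: list[str]) -> bool:
    k = len(pattern)
    if k == 0 or k > len(lineage_lc):
        return False
    return any(
        tuple(lineage_lc[i : i + k]) == pattern for i in range(len(lineage_lc) - k + 1)
    )


def assign_functions(tax: TaxonomyTable, rules: FunctionalRules) -> dict[str, set[str]]:
    """Map every ASV id to the (possibly empty) set of functional groups
    whose patterns match its lineage."""
    out: dict[str, set[str]] = {}
    for asv, lineage in tax.lineages.items():
        lin_lc = [r.lower() for r in lineage]
        hits = {
            g for g, pats in rules.groups.items() if any(_matches(p, lin_lc) for p in pats)
        }
        out[asv] = hits
    return out


def functional_abundance(
    t: CountTable,
    assignments: dict[str, set[str]],
    others_threshold: float = 0.01,
    weighted: bool = True,
) -> FunctionalAbundance:
    """Per-sample functional composition from read counts and assignments.

    ``weighted=True`` (default) weights every assignment stream by the
    ASV's read counts; ``weighted=False`` counts each ASV once per group
    regardless of abundance. Groups contributing less than
    ``others_threshold`` of all assignments dataset-wide are merged into
    ``others``. Unassignable ASVs are discarded from the proportions and
    reported via ``unassigned_fraction``.
    """
    group_names = sorted({g for s in assignments.values() for g in s})
    if not group_names:
        raise ValueError("no ASV could be assigned to any functional group")
    mat = np.zeros((len(group_names), len(t.sample_ids)))
    gidx = {g: i for i, g in enumerate(group_names)}
    n_assigned = 0
    assigned_reads = np.zeros(len(t.sample_ids))
    for i, asv in enumerate(t.asv_ids):
        hits = assignments.get(asv, set())
        if not hits:
            continue
        n_assigned += 1
        row = t.matrix[i].astype(float) if weighted else (t.matrix[i] > 0).astype(float)
        assigned_reads += t.matrix[i]
        for g in hits:
            mat[gidx[g]] += row
    stream_totals = mat.sum(axis=0)
    if (stream_totals == 0).all():
        raise ValueError("assigned ASVs have zero reads in every sample")
    safe = np.where(stream_totals == 0, 1.0, stream_totals)
    props = mat / safe
    df = pd.DataFrame(props, index=group_names, columns=t.sample_ids)
    # dataset-wide "others" merge on share of total assignments
    share = mat.sum(axis=1) / mat.sum()
    rare = share < others_threshold
    if rare.any():
        kept = df.loc[~rare]
        others = df.loc[rare].sum(axis=0)
        df = pd.concat([kept, others.to_frame(OTHERS_LABEL).T])
    total_reads = t.sample_sums().to_numpy().astype(float)
    unassigned = 1.0 - assigned_reads / np.where(total_reads == 0, 1.0, total_reads)
    return FunctionalAbundance(
        proportions=df,
        unassigned_fraction=pd.Series(unassigned, index=t.sample_ids),
        n_assigned_asvs=n_assigned,
    )


def core_functions(fa: FunctionalAbundance) -> list[str]:
    """Functional groups with nonzero abundance in every sample."""
    present = (fa.proportions > 0).all(axis=1)
    return [g for g in fa.proportions.index[present] if g != OTHERS_LABEL]
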