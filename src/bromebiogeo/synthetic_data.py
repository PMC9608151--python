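"""Synthetic tank-bromeliad communities for end-to-end pipeline testing.

Two generating regimes:

* ``generate_niche`` — group-structured ("forest"-structured) communities:
  most pool ASVs are private to one group, a minority is shared, a small
  core is planted in every sample, and environmental variables covary
  with group along an elevation-like gradient (temperature decreasing).
* ``generate_neutral`` — every sample is a multinomial draw from one
  shared regional pool; group labels and environmental variables carry no
  information. This is the regime the biogeography null models describe,
  so it calibrates their type-I error.

The defaults mirror the sampling design the pipeline is built for: five
forests, 5+3+3+3+3 bromeliads, a regional pool of 5,000 ASVs with a
heavy-tailed (lognormal) abundance distribution, ~85% of pool ASVs
private to one forest, per-sample depths of roughly 10^4 reads, and a
planted core of 12 ubiquitous ASVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .function_annotation import FunctionalRules, bundled_rules_path, parse_rules, write_rules
from .tables_io import (
    CountTable,
    EnvTable,
    TaxonomyTable,
    write_count_table,
    write_env_table,
    write_metadata,
    write_taxonomy,
)

# lineage bank (domain..genus); weights give a plausible phylum mix with
# abundant Proteobacteria/Verrucomicrobia/Acidobacteria/Planctomycetes and
# a deliberately large unassignable fraction (uncultured lineages).
_LINEAGE_BANK: list[tuple[str, float]] = [
    ("Bacteria;Verrucomicrobia;Verrucomicrobiae;Pedosphaerales;Pedosphaeraceae;Pedosphaera", 8),
    ("Bacteria;Verrucomicrobia;Verrucomicrobiae;Chthoniobacterales;Chthoniobacteraceae;Chthoniobacter", 6),
    ("Bacteria;Planctomycetes;Planctomycetia;Pirellulales;Pirellulaceae;Pirellula", 8),
    ("Bacteria;Acidobacteria;Acidobacteriia;Acidobacteriales;Acidobacteriaceae;Occallatibacter", 8),
    ("Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Xanthobacteraceae;Xanthobacter", 6),
    ("Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Paracoccus", 3),
    ("Bacteria;Proteobacteria;Alphaproteobacteria;Rhodospirillales;Rhodospirillaceae;Rhodospirillum", 2),
    ("Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae;Hydrogenophaga", 3),
    ("Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Citrobacter", 3),
    ("Bacteria;Proteobacteria;Gammaproteobacteria;Legionellales;Legionellaceae;Legionella", 2),
    ("Bacteria;Proteobacteria;Gammaproteobacteria;Methylococcales;Methylococcaceae;Methylobacter", 2),
    ("Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales;Chromatiaceae;Chromatium", 1),
    ("Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae;Microbacter", 5),
    ("Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium", 3),
    ("Bacteria;Firmicutes;Bacilli;Bacillales;Planococcaceae;Sporosarcina", 1),
    ("Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospiraceae;Nitrospira", 1),
    ("Bacteria;Proteobacteria;Betaproteobacteria;Nitrosomonadales;Nitrosomonadaceae;Nitrosomonas", 1),
    ("Bacteria;Desulfobacterota;Desulfovibrionia;Desulfovibrionales;Desulfovibrionaceae;Desulfovibrio", 2),
    ("Bacteria;Cyanobacteria;Oxyphotobacteria;Nostocales;Nostocaceae;Nostoc", 1),
    ("Bacteria;Fibrobacteres;Fibrobacteria;Fibrobacterales;Fibrobacteraceae;Fibrobacter", 1),
    ("Bacteria;Bdellovibrionota;Bdellovibrionia;Bdellovibrionales;Bdellovibrionaceae;Bdellovibrio", 1),
    ("Bacteria;Chlamydiae;Chlamydiia;Chlamydiales;Simkaniaceae;Simkania", 1),
    ("Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium", 2),
    ("Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanomicrobiaceae;Methanoculleus", 2),
    # unassignable fraction: no rules pattern matches these lineages
    ("Bacteria;Verrucomicrobia;Verrucomicrobiae;uncultured;uncultured;uncultured", 14),
    ("Bacteria;Planctomycetes;Planctomycetia;Gemmatales;Gemmataceae;uncultured", 8),
    ("Bacteria;Acidobacteria;Acidobacteriia;Subgroup_2;uncultured;uncultured", 10),
    ("Bacteria;Proteobacteria;Deltaproteobacteria;Myxococcales;uncultured;uncultured", 6),
    ("Bacteria;Patescibacteria;Parcubacteria;uncultured;uncultured;uncultured", 6),
    ("Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;uncultured", 5),
    ("Bacteria;Dependentiae;Babeliae;Babeliales;uncultured;uncultured", 3),
]

_DEFAULT_ENV_GROUP_MEANS = {
    # elevation transect: temperature falls, tank chemistry shifts mildly
    "temperature": (25.9, 22.2, 20.1, 16.4, 13.1),
    "pH": (6.2, 5.6, 5.0, 4.8, 5.1),
    "salinity": (0.15, 0.06, 0.05, 0.04, 0.04),
    "DO": (32.0, 30.0, 28.0, 30.0, 29.0),
    "IC": (3.5, 3.1, 2.9, 2.6, 2.4),
    "OC": (27.8, 27.8, 27.8, 27.8, 27.8),
    "N": (10.9, 10.9, 10.9, 10.9, 10.9),
    "P": (0.05, 0.05, 0.05, 0.05, 0.05),
}

_ENV_NOISE_SD = {
    "temperature": 1.0,
    "pH": 0.4,
    "salinity": 0.03,
    "DO": 8.0,
    "IC": 0.3,
    "OC": 10.0,
    "N": 5.0,
    "P": 0.04,
}

# weight multipliers fixed at design time so that the occupied
# single-group fraction tracks cfg.exclusivity and shared taxa stay at a
# few percent of reads (see docs/methods.md)
_HOME_BOOST = 6.0
_SHARED_SCALE = 0.4


@dataclass
class SyntheticConfig:
    n_groups: int = 5
    samples_per_group: tuple[int, ...] = (5, 3, 3, 3, 3)
    pool_size: int = 5000
    exclusivity: float = 0.85
    sad_shape: float = 1.5
    depth_range: tuple[int, int] = (9843, 30000)
    core_size: int = 12
    env_effect: dict[str, tuple[float, ...]] | None = None
    seed: int = 0
    # flat sample indices forced to a sub-cutoff depth (study-shaped runs)
    shallow_sample_indices: tuple[int, ...] = ()
    shallow_depth_range: tuple[int, int] = (100, 999)

    def __post_init__(self) -> None:
        if not 0.0 <= self.exclusivity <= 1.0:
            raise ValueError("exclusivity must lie in [0, 1]")
        if self.pool_size < self.core_size + self.n_groups:
            raise ValueError("pool_size must be >= core_size + n_groups")
        if len(self.samples_per_group) != self.n_groups:
            raise ValueError("samples_per_group length must equal n_groups")
        if self.depth_range[0] <= 0 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("invalid depth_range")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_group))

    def group_names(self) -> list[str]:
        return [f"forest_{i + 1}" for i in range(self.n_groups)]


def study_shaped_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The sampling design the pipeline targets: 17 bromeliads in five
    forests of which three libraries come out below the 1,000-read
    cutoff (two in forest 1, one in forest 5)."""
    params = dict(
        samples_per_group=(5, 3, 3, 3, 3),
        shallow_sample_indices=(3, 4, 16),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class SyntheticDataset:
    counts: CountTable
    taxonomy: TaxonomyTable
    env: EnvTable
    rules: FunctionalRules
    ground_truth: pd.DataFrame          # per ASV: home_group, is_core
    env_group_means: pd.DataFrame       # variable x group true means
    mode: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_count_table(self.counts, out / "counts.tsv")
        write_metadata(self.counts.groups, out / "metadata.tsv")
        write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        write_env_table(self.env, out / "env.tsv")
        write_rules(self.rules, out / "rules.txt")
        gt = self.ground_truth.copy()
        gt.index.name = "asv_id"
        gt.to_csv(out / "ground_truth.tsv", sep="\t")


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _pool(cfg: SyntheticConfig, rng: np.random.Generator):
    asv_ids = [f"ASV_{i + 1:05d}" for i in range(cfg.pool_size)]
    abund = rng.lognormal(mean=0.0, sigma=cfg.sad_shape, size=cfg.pool_size)
    roles = np.full(cfg.pool_size, "shared", dtype=object)
    roles[: cfg.core_size] = "core"
    n_private = int(round(cfg.exclusivity * (cfg.pool_size - cfg.core_size)))
    home = np.full(cfg.pool_size, "", dtype=object)
    groups = cfg.group_names()
    private_idx = np.arange(cfg.core_size, cfg.core_size + n_private)
    roles[private_idx] = "private"
    home[private_idx] = rng.choice(groups, size=n_private)
    return asv_ids, abund, roles, home


def _taxonomy(cfg: SyntheticConfig, asv_ids: list[str], rng: np.random.Generator) -> TaxonomyTable:
    bank = [lin for lin, _ in _LINEAGE_BANK]
    weights = np.array([w for _, w in _LINEAGE_BANK], dtype=float)
    pick = rng.choice(len(bank), size=len(asv_ids), p=weights / weights.sum())
    lineages = {
        asv: bank[k].split(";") + [f"sp_{i + 1}"] for i, (asv, k) in enumerate(zip(asv_ids, pick))
    }
    return TaxonomyTable(lineages)


def _depths(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.depth_range
    depths = rng.integers(lo, hi + 1, size=cfg.n_samples)
    for idx in cfg.shallow_sample_indices:
        depths[idx] = rng.integers(cfg.shallow_depth_range[0], cfg.shallow_depth_range[1] + 1)
    return depths


def _env(cfg: SyntheticConfig, sample_groups: list[str], sample_ids: list[str],
         rng: np.random.Generator, group_structured: bool) -> tuple[EnvTable, pd.DataFrame]:
    groups = cfg.group_names()
    means = dict(_DEFAULT_ENV_GROUP_MEANS)
    if cfg.env_effect:
        means.update(cfg.env_effect)
    table = {}
    true_means = {}
    for var, mu in means.items():
        mu = np.asarray(mu, dtype=float)
        if len(mu) != cfg.n_groups:
            mu = np.interp(np.linspace(0, 1, cfg.n_groups), np.linspace(0, 1, len(mu)), mu)
        if not group_structured:
            mu = np.full(cfg.n_groups, mu.mean())
        true_means[var] = mu
        gi = np.array([groups.index(g) for g in sample_groups])
        vals = mu[gi] + rng.normal(0.0, _ENV_NOISE_SD[var], size=len(sample_groups))
        if var in ("salinity", "P", "IC", "OC", "N", "DO"):
            vals = np.clip(vals, 0.0, None)
        table[var] = vals
    env = EnvTable(pd.DataFrame(table, index=pd.Index(sample_ids, name="sample_id")))
    return env, pd.DataFrame(true_means, index=groups).T


def _plant_core(counts: np.ndarray, core_idx: np.ndarray) -> None:
    """Guarantee every planted core ASV at least one read per sample,
    repaying reads from the currently largest cells (depth unchanged)."""
    for j in range(counts.shape[1]):
        col = counts[:, j]
        for i in core_idx:
            if col[i] == 0:
                donor = int(np.argmax(col))
                col[donor] -= 1
                col[i] = 1


def _sample_labels(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    sample_ids, sample_groups = [], []
    for g, n in zip(cfg.group_names(), cfg.samples_per_group):
        for k in range(n):
            sample_ids.append(f"{g}_s{k + 1}")
            sample_groups.append(g)
    return sample_ids, sample_groups


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_niche(cfg: SyntheticConfig) -> SyntheticDataset:
    """Group-structured communities (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    asv_ids, abund, roles, home = _pool(cfg, rng)
    sample_ids, sample_groups = _sample_labels(cfg)
    depths = _depths(cfg, rng)
    counts = np.zeros((cfg.pool_size, cfg.n_samples), dtype=np.int64)
    core_idx = np.flatnonzero(roles == "core")
    weight_cache: dict[str, np.ndarray] = {}
    for g in cfg.group_names():
        w = np.zeros(cfg.pool_size)
        w[roles == "core"] = abund[roles == "core"]
        w[roles == "shared"] = _SHARED_SCALE * abund[roles == "shared"]
        mine = (roles == "private") & (home == g)
        w[mine] = _HOME_BOOST * abund[mine]
        weight_cache[g] = w / w.sum()
    for j, (g, depth) in enumerate(zip(sample_groups, depths)):
        counts[:, j] = rng.multinomial(int(depth), weight_cache[g])
    _plant_core(counts, core_idx)
    return _assemble(cfg, rng, asv_ids, abund, roles, home, counts, sample_ids,
                     sample_groups, group_structured=True, mode="niche")


def generate_neutral(cfg: SyntheticConfig) -> SyntheticDataset:
    """Neutral regime: all samples drawn from one shared pool; groups and
    environment carry no signal."""
    rng = np.random.default_rng(cfg.seed)
    asv_ids, abund, _, _ = _pool(cfg, rng)
    roles = np.full(cfg.pool_size, "shared", dtype=object)
    home = np.full(cfg.pool_size, "", dtype=object)
    sample_ids, sample_groups = _sample_labels(cfg)
    depths = _depths(cfg, rng)
    p = abund / abund.sum()
    counts = np.zeros((cfg.pool_size, cfg.n_samples), dtype=np.int64)
    for j, depth in enumerate(depths):
        counts[:, j] = rng.multinomial(int(depth), p)
    return _assemble(cfg, rng, asv_ids, abund, roles, home, counts, sample_ids,
                     sample_groups, group_structured=False, mode="neutral")


def _assemble(cfg, rng, asv_ids, abund, roles, home, counts, sample_ids, sample_groups,
              group_structured: bool, mode: str) -> SyntheticDataset:
    df = pd.DataFrame(counts, index=pd.Index(asv_ids, name="asv_id"), columns=sample_ids)
    groups = pd.Series(sample_groups, index=sample_ids, name="group")
    table = CountTable(df, groups)
    tax = _taxonomy(cfg, asv_ids, rng)
    env, true_means = _env(cfg, sample_groups, sample_ids, rng, group_structured)
    rules = parse_rules(bundled_rules_path())
    gt = pd.DataFrame(
        {
            "home_group": home,
            "is_core": roles == "core",
            "role": roles,
            # true (unnormalised) regional-pool abundance of each ASV; in
            # neutral mode this is exactly the shared sampling weight
            "pool_abundance": abund,
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    return SyntheticDataset(table, tax, env, rules, gt, true_means, mode)
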