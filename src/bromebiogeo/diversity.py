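"""Alpha/beta diversity: rarefaction, effective species number, Bray-Curtis,
Jaccard overlap and the Kruskal-Wallis group test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .tables_io import CountTable, RelAbundTable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class KWResult:
    H: float
    df: int
    p: float
    tie_corrected: bool = True


def rarefy(t: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to a common ``depth``.

    Each sample's reads are treated as a finite urn (multivariate
    hypergeometric draw), so rarefied column sums equal ``depth`` exactly
    and the draw is reproducible for a given ``seed``.
    """
    sums = t.sample_sums()
    low = sums[sums < depth]
    if len(low):
        raise ValueError(
            f"depth {depth} exceeds total of sample(s) {list(low.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(t.matrix)
    for j, s in enumerate(t.sample_ids):
        out[:, j] = rng.multivariate_hypergeometric(t.matrix[:, j], depth)
    df = pd.DataFrame(out, index=t.counts.index, columns=t.counts.columns)
    return CountTable(df, t.groups)


def min_depth(t: CountTable) -> int:
    """The smallest sample total — the conventional common rarefaction depth."""
    return int(t.sample_sums().min())


def effective_species(counts: np.ndarray | pd.Series) -> float:
    """Inverse Simpson index 1 / sum(p_i^2): the number of equally abundant
    taxa that would give the same dominance structure."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("effective_species needs at least one positive count")
    p = x / total
    return float(1.0 / np.sum(p**2))


def effective_species_per_sample(t: CountTable) -> pd.Series:
    return pd.Series(
        [effective_species(t.matrix[:, j]) for j in range(len(t.sample_ids))],
        index=t.sample_ids,
        name="ENS",
    )


def bray_curtis(t: CountTable | RelAbundTable, on_proportions: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y). Computed on
    per-sample proportions by default so unequal sequencing depth does not
    masquerade as community turnover.
    """
    if isinstance(t, RelAbundTable):
        mat = t.proportions.to_numpy().T
        ids = t.sample_ids
    else:
        mat = t.matrix.T.astype(float)
        ids = t.sample_ids
        if on_proportions:
            sums = mat.sum(axis=1, keepdims=True)
            if (sums == 0).any():
                raise ValueError("all-zero sample in Bray-Curtis input")
            mat = mat / sums
    if mat.shape[0] < 2:
        raise ValueError("bray_curtis needs at least two samples")
    if (mat.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    return DistanceMatrix(ids, squareform(pdist(mat, metric="braycurtis")))


def jaccard_overlap(a: set | frozenset, b: set | frozenset) -> float:
    """Jaccard similarity |a & b| / |a | b| of two presence sets."""
    if not a and not b:
        raise ValueError("Jaccard overlap undefined for two empty sets")
    return len(a & b) / len(a | b)


def kruskal_wallis(values, groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square tail probability."""
    values = np.asarray(values, dtype=float)
    labels = pd.Series(list(groups))
    samples = [values[(labels == g).to_numpy()] for g in labels.unique()]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis: empty group")
    if np.ptp(np.concatenate(samples)) == 0:
        # identical values everywhere: H == 0 by definition, scipy raises
        return KWResult(H=0.0, df=len(samples) - 1, p=1.0)
    H, p = stats.kruskal(*samples)
    return KWResult(H=float(H), df=len(samples) - 1, p=float(p))
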