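"""Null-model biogeography of ASV tables.

Community overlap and co-occurrence structure are quantified with three
statistics — mean Jaccard overlap (MJO) on presence sets, the per-ASV
coefficient of variation (CV) of relative abundances, and a generalized
(N-community) Morisita-Horn similarity (MA) — and each of MJO and MA is
calibrated against a dedicated null model by shuffling the count table
many times:

* the *multinomial* null redraws each sample's ASV identities from the
  regional pool weighted by mean relative abundance, preserving every
  sample's richness and total count exactly;
* the *row-column proportional* null scatters the grand total of reads
  over matrix cells with probability proportional to the product of row
  and column totals.

Observed values in the lower tail of the null distribution indicate
segregation (samples share fewer taxa than random assembly from the pool
predicts); the upper tail indicates aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import ma_null_distribution, mjo_null_distribution
from .tables_io import CountTable


@dataclass
class NullTestResult:
    """An observed statistic against its null distribution.

    ``p_low``/``p_high`` follow the literal shuffle fractions
    #{null <= obs}/reps and #{null >= obs}/reps; ``p_low_incl`` and
    ``p_high_incl`` are the observation-inclusive (k+1)/(reps+1) estimates,
    which never return an exact zero.
    """

    statistic_name: str
    observed: float
    null_values: np.ndarray
    reps: int
    seed: int
    scope: str = "global"

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.reps:
            raise ValueError("null_values length must equal reps")

    @property
    def p_low(self) -> float:
        return float(np.mean(self.null_values <= self.observed))

    @property
    def p_high(self) -> float:
        return float(np.mean(self.null_values >= self.observed))

    @property
    def p_low_incl(self) -> float:
        return (int(np.sum(self.null_values <= self.observed)) + 1) / (self.reps + 1)

    @property
    def p_high_incl(self) -> float:
        return (int(np.sum(self.null_values >= self.observed)) + 1) / (self.reps + 1)

    def format_p(self, which: str = "low") -> str:
        p = self.p_low if which == "low" else self.p_high
        return f"< {1.0 / self.reps:g}" if p == 0 else f"{p:g}"


# ---------------------------------------------------------------------------
# observed statistics
# ---------------------------------------------------------------------------

def _mjo_from_presence(pres: np.ndarray) -> float:
    """Mean pairwise Jaccard similarity from a boolean ASV x sample matrix."""
    n = pres.shape[1]
    if n < 2:
        raise ValueError("MJO needs at least two samples")
    inter = pres.T.astype(np.float64) @ pres.astype(np.float64)
    rich = np.diag(inter)
    union = rich[:, None] + rich[None, :] - inter
    iu = np.triu_indices(n, k=1)
    if (union[iu] == 0).any():
        raise ValueError("MJO undefined: a pair of empty samples")
    return float(np.mean(inter[iu] / union[iu]))


def mean_jaccard_overlap(t: CountTable, scope: str | None = None) -> float:
    """Unweighted mean Jaccard overlap over unordered sample pairs.

    ``scope`` is None for the global MJO (all pairs) or a group label for
    the within-group MJO.
    """
    if scope is None:
        sub = t
    else:
        sub = t.subset_samples(t.group_samples(scope))
    return _mjo_from_presence(sub.presence())


def per_group_mjo(t: CountTable) -> pd.Series:
    vals = {g: mean_jaccard_overlap(t, scope=g) for g in t.group_labels()}
    return pd.Series(vals, name="MJO")


def asv_cv(t: CountTable, scope: str | None = None, ddof: int = 1) -> float:
    """Mean coefficient of variation of ASV relative abundances.

    For every ASV occurring in at least one sample of the scope, the CV
    (standard deviation over mean) of its per-sample relative abundances
    (zeros included) is computed across the scope's samples; the returned
    value is the mean over those occurring ASVs. The sample (n-1) standard
    deviation is used by default.
    """
    sub = t if scope is None else t.subset_samples(t.group_samples(scope))
    mat = sub.matrix.astype(float)
    if mat.shape[1] < 2:
        raise ValueError("CV needs at least two samples in scope")
    sums = mat.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("CV undefined with an all-zero sample in scope")
    rel = mat / sums
    occurring = rel.sum(axis=1) > 0
    if not occurring.any():
        raise ValueError("no occurring ASV in scope")
    rel = rel[occurring]
    mean = rel.mean(axis=1)
    sd = rel.std(axis=1, ddof=ddof)
    return float(np.mean(sd / mean))


def per_group_cv(t: CountTable, ddof: int = 1) -> pd.Series:
    vals = {g: asv_cv(t, scope=g, ddof=ddof) for g in t.group_labels()}
    return pd.Series(vals, name="CV")


def morisita_ma(t: CountTable) -> float:
    """Generalized (N-community) Morisita-Horn similarity C2N.

    With p_ij the relative abundance of ASV i in sample j and N samples:

        C2N = sum_i [ (sum_j p_ij)^2 - sum_j p_ij^2 ]
              / [ (N - 1) * sum_i sum_j p_ij^2 ]

    which reduces to the classic two-community Morisita-Horn index at
    N = 2; 1 means identical relative compositions, 0 means complete
    segregation (no taxon shared by any pair).
    """
    mat = t.matrix.astype(float)
    return _morisita_from_counts(mat)


def _morisita_from_counts(mat: np.ndarray) -> float:
    n = mat.shape[1]
    if n < 2:
        raise ValueError("MA needs at least two samples")
    sums = mat.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("MA undefined with a zero-total sample")
    p = mat / sums
    sq = p**2
    total_sq = sq.sum()
    num = float((p.sum(axis=1) ** 2).sum() - sq.sum())
    return num / ((n - 1) * total_sq)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def mean_relative_abundance(t: CountTable) -> np.ndarray:
    """Pool weights: mean over samples of per-sample proportions."""
    mat = t.matrix.astype(float)
    sums = mat.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("zero-total sample; rarefy/filter first")
    return (mat / sums).mean(axis=1)


def _multinomial_null_matrix(
    mat: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One shuffled matrix preserving each sample's richness and total.

    For each sample, its observed number of occupied ASVs is redrawn from
    the pool without replacement with probability proportional to
    ``weights`` (exponential-race sampling), counts are allocated
    multinomially among the drawn ASVs with renormalized weights, and any
    zero cell is repaired by moving one read from the currently largest
    cell so that richness is preserved exactly.
    """
    n_asv, n_samp = mat.shape
    pool = np.flatnonzero(weights > 0)
    out = np.zeros_like(mat)
    richness = (mat > 0).sum(axis=0)
    totals = mat.sum(axis=0)
    w_pool = weights[pool]
    for j in range(n_samp):
        s, n = int(richness[j]), int(totals[j])
        if s > len(pool):
            raise ValueError(
                f"sample richness {s} exceeds regional pool size {len(pool)}"
            )
        if s < len(pool):
            keys = rng.exponential(size=len(pool)) / w_pool
            chosen = pool[np.argpartition(keys, s - 1)[:s]]
        else:
            chosen = pool
        pw = weights[chosen]
        cnt = rng.multinomial(n, pw / pw.sum())
        zeros = np.flatnonzero(cnt == 0)
        for z in zeros:
            donor = int(np.argmax(cnt))
            cnt[donor] -= 1
            cnt[z] = 1
        out[chosen, j] = cnt
    return out


def multinomial_null(t: CountTable, seed: int | np.random.Generator) -> CountTable:
    """One shuffled table under the multinomial regional-pool null model."""
    rng = np.random.default_rng(seed)
    weights = mean_relative_abundance(t)
    out = _multinomial_null_matrix(t.matrix, weights, rng)
    df = pd.DataFrame(out, index=t.counts.index, columns=t.counts.columns)
    return CountTable(df, t.groups)


def _rc_null_matrix(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw of the row/column proportional null.

    Placing the grand total T independently into cells with probability
    (row_i * col_j) / T^2 factorises exactly into "draw column totals
    multinomially, then rows within each column", which is
    distributionally identical and fast.
    """
    total = int(mat.sum())
    if total <= 0:
        raise ValueError("empty table")
    row_p = mat.sum(axis=1).astype(float) / total
    col_tot = mat.sum(axis=0).astype(float)
    col_counts = rng.multinomial(total, col_tot / total)
    null = np.empty_like(mat)
    for j in range(mat.shape[1]):
        null[:, j] = rng.multinomial(int(col_counts[j]), row_p)
    return null


def rc_proportional_null(t: CountTable, seed: int | np.random.Generator) -> CountTable:
    """One shuffled table placing all reads cell-wise proportional to the
    product of row and column totals (margins preserved in expectation,
    grand total exactly)."""
    rng = np.random.default_rng(seed)
    null = _rc_null_matrix(t.matrix, rng)
    df = pd.DataFrame(null, index=t.counts.index, columns=t.counts.columns)
    return CountTable(df, t.groups)


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------

def mjo_test(
    t: CountTable,
    reps: int = 1000,
    seed: int = 0,
    pool_weights: np.ndarray | None = None,
) -> NullTestResult:
    """Observed MJO against ``reps`` multinomial-null shuffles.

    ``p_low`` (fraction of null MJOs <= observed) is the segregation
    p-value. The input should be rarefied to equal depth first.

    By default the regional pool and its weights are the plug-in
    estimate from the table itself (occupied ASVs, mean relative
    abundance), which is how the method is applied to field data. The
    test is then *conditional* on those weights: because every null
    community shares the same estimated vector, its estimation noise is
    common to all null samples and the test leans anticonservative (see
    the methods notes). ``pool_weights`` (aligned to ``t``'s ASV rows;
    zero entries are excluded from the pool) lets a caller test against
    a known regional pool instead — this is the exact calibration
    setting, where data drawn from the null with those weights yield
    uniform p-values.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    observed = _mjo_from_presence(t.presence())
    if pool_weights is None:
        weights = mean_relative_abundance(t)  # all-zero ASV rows drop out
    else:
        weights = np.asarray(pool_weights, dtype=float)
        if len(weights) != len(t.asv_ids):
            raise ValueError("pool_weights length must match ASV count")
    pool = weights > 0
    richness = (t.matrix > 0).sum(axis=0).astype(np.int64)
    if (richness > pool.sum()).any():
        raise ValueError("sample richness exceeds regional pool size")
    null_vals = mjo_null_distribution(
        weights[pool], richness, reps, int(seed) % 2**31
    )
    return NullTestResult("MJO", observed, null_vals, reps, seed)


def ma_test(t: CountTable, reps: int = 1000, seed: int = 0) -> NullTestResult:
    """Observed generalized Morisita similarity against ``reps`` draws of
    the row/column proportional null; ``p_low`` flags segregation and
    ``p_high`` aggregation."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    mat = t.matrix
    observed = _morisita_from_counts(mat.astype(float))
    row_tot = mat.sum(axis=1).astype(float)
    occupied = row_tot > 0  # all-zero ASV rows are ignored
    null_vals = ma_null_distribution(
        row_tot[occupied],
        mat.sum(axis=0).astype(float),
        reps,
        int(seed) % 2**31,
    )
    return NullTestResult("MA", observed, null_vals, reps, seed)
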