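"""Compiled inner loops for the null-model significance tests.

The Python-level null-model operations in :mod:`bromebiogeo.biogeography`
are the reference implementations used for single shuffles; these numba
kernels run the 1,000-shuffle loops of ``mjo_test`` and ``ma_test`` at
full problem size.

Exactness note for the MJO kernel: under the multinomial null the set of
occupied ASVs of a sample *is* the without-replacement draw (the
zero-count repair guarantees every drawn ASV keeps at least one read),
so the null MJO distribution depends only on the draws and the count
allocation step can be skipped entirely.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _weighted_wor(weights: np.ndarray, s: int) -> np.ndarray:
    """Indices of s items drawn without replacement with probability
    proportional to ``weights`` (exponential race: the s smallest
    Exp(1)/w_i arrival times)."""
    n = len(weights)
    if s >= n:
        return np.arange(n)
    keys = np.empty(n)
    for i in range(n):
        # exponential race: arrival time Exp(1)/w_i
        keys[i] = -np.log(np.random.random()) / weights[i]
    thr = np.partition(keys, s - 1)[s - 1]
    out = np.empty(s, np.int64)
    k = 0
    for i in range(n):
        if keys[i] <= thr:
            out[k] = i
            k += 1
            if k == s:
                break
    return out


_POPCNT16 = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.uint8)


@njit(cache=True)
def _popcount64(x: np.uint64, lut: np.ndarray) -> int:
    return int(
        lut[x & np.uint64(0xFFFF)]
        + lut[(x >> np.uint64(16)) & np.uint64(0xFFFF)]
        + lut[(x >> np.uint64(32)) & np.uint64(0xFFFF)]
        + lut[(x >> np.uint64(48)) & np.uint64(0xFFFF)]
    )


@njit(cache=True)
def mjo_null_distribution(
    weights: np.ndarray, richness: np.ndarray, reps: int, seed: int
) -> np.ndarray:
    """Null MJO values under the multinomial regional-pool null.

    ``weights``: positive pool weights (mean relative abundances) of the
    occupied ASVs; ``richness``: per-sample occupied-ASV counts.
    Presence sets are stored as bitsets; pair intersections are popcounts.
    """
    np.random.seed(seed)
    n_pool = len(weights)
    n_samp = len(richness)
    n_words = (n_pool + 63) // 64
    lut = _POPCNT16
    out = np.empty(reps)
    bits = np.zeros((n_samp, n_words), np.uint64)
    for r in range(reps):
        bits[:, :] = np.uint64(0)
        for j in range(n_samp):
            idx = _weighted_wor(weights, richness[j])
            for i in idx:
                bits[j, i >> 6] |= np.uint64(1) << np.uint64(i & 63)
        total = 0.0
        npairs = 0
        for a in range(n_samp):
            for b in range(a + 1, n_samp):
                inter = 0
                for w in range(n_words):
                    inter += _popcount64(bits[a, w] & bits[b, w], lut)
                union = richness[a] + richness[b] - inter
                total += inter / union
                npairs += 1
        out[r] = total / npairs
    return out


@njit(cache=True)
def ma_null_distribution(
    row_tot: np.ndarray, col_tot: np.ndarray, reps: int, seed: int
) -> np.ndarray:
    """Null generalized-Morisita (C2N) values under the row/column
    proportional null: the grand total is scattered over cells with
    probability rowsum*colsum/T^2, drawn as column totals first and then
    rows within columns (an exact factorisation of the multinomial)."""
    np.random.seed(seed)
    n_rows = len(row_tot)
    n_cols = len(col_tot)
    total = row_tot.sum()
    row_p = row_tot / total
    col_p = col_tot / total
    col_cum = np.cumsum(col_p)
    out = np.empty(reps)
    cells = np.zeros((n_rows, n_cols), np.int64)
    col_sum = np.zeros(n_cols, np.int64)
    for r in range(reps):
        col_sum[:] = 0
        # rows first (one long multinomial), then each occupied row over
        # columns: a categorical draw per read for small rows, an
        # early-terminating binomial chain otherwise — most rows carry
        # few reads, so this touches far fewer cells than column-major
        # sampling
        row_counts = np.random.multinomial(int(total), row_p)
        for i in range(n_rows):
            ni = row_counts[i]
            if ni == 0:
                cells[i, 0] = -1  # mark empty row
                continue
            if ni <= 4:
                for j in range(n_cols):
                    cells[i, j] = 0
                for _k in range(ni):
                    u = np.random.random()
                    j = 0
                    while col_cum[j] < u and j < n_cols - 1:
                        j += 1
                    cells[i, j] += 1
                    col_sum[j] += 1
                continue
            rem = ni
            acc = 1.0
            for j in range(n_cols - 1):
                pj = col_p[j] / acc
                if pj > 1.0:
                    pj = 1.0
                x = np.random.binomial(rem, pj)
                cells[i, j] = x
                col_sum[j] += x
                rem -= x
                acc -= col_p[j]
                if rem == 0:
                    for jj in range(j + 1, n_cols - 1):
                        cells[i, jj] = 0
                    break
            cells[i, n_cols - 1] = rem
            col_sum[n_cols - 1] += rem
        rowsum = np.zeros(n_rows)
        sumsq = 0.0
        for i in range(n_rows):
            if cells[i, 0] == -1:
                cells[i, 0] = 0
                continue
            for j in range(n_cols):
                cij = cells[i, j]
                if cij > 0:
                    pij = cij / col_sum[j]
                    rowsum[i] += pij
                    sumsq += pij * pij
        num = 0.0
        for i in range(n_rows):
            num += rowsum[i] * rowsum[i]
        num -= sumsq
        out[r] = num / ((n_cols - 1) * sumsq)
    return out
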