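"""Distance-based PERMANOVA and PCA of environmental variables.

PERMANOVA follows the McArdle-Anderson formulation: the squared
dissimilarity matrix is Gower-centered into an inner-product matrix G and
the pseudo-F statistic is built from traces of G projected onto the
design's hat matrix, so it works for any dissimilarity (including
non-Euclidean Bray-Curtis) without eigenvalue corrections. Predictors are
tested one at a time: either a categorical grouping (indicator design) or
a single numeric covariate (intercept + covariate design).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .tables_io import EnvTable


@dataclass
class PermanovaResult:
    predictor: str
    pseudo_F: float
    R2: float
    p: float
    nperm: int
    seed: int
    n: int
    method: str = "obs-inclusive permutation p; marginal single-predictor design"


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat_matrix(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse is safe for rank-deficient indicator designs
    return x @ np.linalg.pinv(x)


def _design(values: np.ndarray, categorical: bool) -> tuple[np.ndarray, int]:
    """Model matrix and its effective number of columns m (df1 = m - 1)."""
    if categorical:
        levels = pd.unique(values)
        if len(levels) < 2:
            raise ValueError("predictor is constant")
        x = np.column_stack([(values == lv).astype(float) for lv in levels])
        return x, len(levels)
    v = values.astype(float)
    if np.ptp(v) == 0:
        raise ValueError("predictor is constant")
    return np.column_stack([np.ones_like(v), v]), 2


def permanova(
    d: DistanceMatrix,
    x,
    nperm: int = 10000,
    seed: int = 0,
    predictor_name: str = "predictor",
    exact: bool = False,
) -> PermanovaResult:
    """Permutation test of a pseudo-F statistic on a dissimilarity matrix.

    ``x`` is either a sequence of group labels (categorical) or numbers
    (one continuous covariate), aligned with ``d.sample_ids``. The p-value
    uses the observation-inclusive convention (1 + #{F* >= F}) / (1 + nperm)
    and therefore never returns 0. With ``exact=True`` all n! label
    permutations are enumerated instead (small n only) and p is the exact
    fraction of permutations with F* >= F.
    """
    values = np.asarray(list(x))
    n = len(d.sample_ids)
    if len(values) != n:
        raise ValueError("predictor length does not match distance matrix")
    categorical = not np.issubdtype(values.dtype, np.number)
    xmat, m = _design(values, categorical)
    if n < m:
        raise ValueError(f"need at least {m} samples for {m} model columns")
    g = _gower_center(d.d)
    h = _hat_matrix(xmat)
    tr_g = float(np.trace(g))
    if n == m:
        # saturated design: every permutation is a relabeling of a perfect fit
        r2 = float(np.sum(h * g.T) / tr_g)
        return PermanovaResult(predictor=predictor_name, pseudo_F=float("inf"),
                               R2=r2, p=1.0, nperm=0, seed=seed, n=n)

    def f_stat(perm: np.ndarray) -> float:
        gp = g[np.ix_(perm, perm)]
        tr_hg = float(np.sum(h * gp.T))  # tr(H G) with H symmetric
        resid = tr_g - tr_hg
        return (tr_hg / (m - 1)) / (resid / (n - m))

    ident = np.arange(n)
    f_obs = f_stat(ident)
    r2 = float(np.sum(h * g.T) / tr_g)

    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        fs = np.array([f_stat(np.asarray(p)) for p in itertools.permutations(range(n))])
        p_val = float(np.mean(fs >= f_obs - 1e-12))
        nperm_used = math.factorial(n)
    else:
        if nperm < 1:
            raise ValueError("nperm must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(nperm):
            perm = rng.permutation(n)
            if f_stat(perm) >= f_obs - 1e-12:
                count += 1
        p_val = (count + 1) / (nperm + 1)
        nperm_used = nperm
    return PermanovaResult(
        predictor=predictor_name,
        pseudo_F=float(f_obs),
        R2=r2,
        p=p_val,
        nperm=nperm_used,
        seed=seed,
        n=n,
    )


def permanova_env(
    d: DistanceMatrix,
    env: EnvTable,
    variables: list[str],
    nperm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal PERMANOVA of each environmental variable in turn.

    Samples missing a variable are dropped for that variable's test and
    the n actually used is reported.
    """
    rows = []
    for i, var in enumerate(variables):
        keep = [s for s in d.sample_ids if s in env.sample_ids and pd.notna(env.values.loc[s, var])]
        idx = [d.sample_ids.index(s) for s in keep]
        sub = DistanceMatrix(keep, d.d[np.ix_(idx, idx)])
        res = permanova(
            sub, env.values.loc[keep, var].to_numpy(), nperm=nperm,
            seed=seed + i, predictor_name=var,
        )
        rows.append(
            {"predictor": var, "pseudo_F": res.pseudo_F, "R2": res.R2,
             "p": res.p, "n": res.n, "nperm": res.nperm}
        )
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # variables x components
    variance_fraction: np.ndarray


def pca(env: EnvTable, scale: bool = True, dropna: bool = True) -> PCAResult:
    """PCA of the environmental table (centered, unit-scaled by default).

    Sign convention: within each component the loading of largest
    magnitude is made positive. Samples with any missing variable are
    dropped when ``dropna``.
    """
    x = env.values.dropna(axis=0) if dropna else env.values
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 complete samples and >= 2 variables")
    arr = x.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    if scale:
        sd = arr.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [v for v, s in zip(x.columns, sd) if s == 0]
            raise ValueError(f"constant variable(s) with scale=True: {bad}")
        arr = arr / sd
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    # fix signs so the largest-|loading| entry of each component is positive
    for c in range(vt.shape[0]):
        piv = np.argmax(np.abs(vt[c]))
        if vt[c, piv] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=x.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=x.columns, columns=comp_names),
        variance_fraction=frac,
    )
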