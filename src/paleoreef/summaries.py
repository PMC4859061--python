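"""Assemblage statistics and model selection.

Site-by-species matrices (binary, rows = grid cells, columns = species) are
summarised with alpha diversity, pairwise Jaccard dissimilarity and its
richness-independent turnover component beta_jtu, the among-sites NODF
nestedness index with a sequential-swap null model, packed site orders with
Spearman congruence, and Mantel tests for distance decay.  Simulated maps
are compared to observed maps by least-squares fit (RSS, R^2) and ranked by
summed BIC across comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "richness_map",
    "jaccard_dissimilarity",
    "turnover_jtu",
    "nodf_sites",
    "swap_null",
    "SwapNullResult",
    "packed_order",
    "congruence",
    "mantel",
    "ModelFit",
    "model_fit",
    "rank_models",
]


def _as_matrix(matrix) -> tuple[np.ndarray, list, list]:
    """Coerce to a binary ndarray plus row/column labels."""
    if isinstance(matrix, pd.DataFrame):
        x = matrix.to_numpy()
        rows, cols = list(matrix.index), list(matrix.columns)
    else:
        x = np.asarray(matrix)
        rows = list(range(x.shape[0]))
        cols = list(range(x.shape[1]))
    if x.ndim != 2:
        raise ValueError("expected a 2-D site-by-species matrix")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("matrix entries must be 0/1")
    return x.astype(np.int64), rows, cols


def richness_map(matrix) -> pd.Series:
    """Alpha diversity: species count per site (row sums)."""
    x, rows, _ = _as_matrix(matrix)
    return pd.Series(x.sum(axis=1), index=rows, name="richness")


def _abc(x: np.ndarray):
    """Shared (a) and unique (b, c) species counts for every site pair."""
    a = x @ x.T
    fill = x.sum(axis=1)
    b = fill[:, None] - a
    c = fill[None, :] - a
    return a, b, c


def jaccard_dissimilarity(matrix) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity 1 - a/(a+b+c); NaN for two empty sites."""
    x, rows, _ = _as_matrix(matrix)
    a, b, c = _abc(x)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - a / denom
    d[denom == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=rows, columns=rows)


def turnover_jtu(matrix) -> pd.DataFrame:
    """Turnover component of Jaccard: 2*min(b,c) / (a + 2*min(b,c)).

    Insensitive to richness differences: a perfectly nested pair has
    min(b, c) = 0 and hence zero turnover.
    """
    x, rows, _ = _as_matrix(matrix)
    a, b, c = _abc(x)
    m = np.minimum(b, c)
    denom = a + 2 * m
    with np.errstate(invalid="ignore", divide="ignore"):
        t = 2.0 * m / denom
    t[denom == 0] = np.nan
    np.fill_diagonal(t, 0.0)
    return pd.DataFrame(t, index=rows, columns=rows)


def _nodf_rows(x: np.ndarray) -> float:
    """Among-sites NODF on a matrix with no zero-fill rows."""
    n = x.shape[0]
    a = x @ x.T
    fill = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        po = 100.0 * a / fill[None, :]
    contrib = np.where(fill[:, None] > fill[None, :], po, 0.0)
    n_pairs = n * (n - 1) / 2
    return float(contrib.sum() / n_pairs)


def nodf_sites(matrix) -> float:
    """Among-sites NODF in [0, 100].

    For each ordered site pair with fill(i) > fill(j) the paired overlap is
    100 * |shared| / fill(j); equal-fill pairs contribute zero ("decreasing
    fill").  The index is the mean over all site pairs.  Zero-fill rows are
    dropped (with a warning) before computation.
    """
    x, _, _ = _as_matrix(matrix)
    fill = x.sum(axis=1)
    if (fill == 0).any():
        warnings.warn(
            f"dropping {(fill == 0).sum()} zero-fill row(s) before NODF", stacklevel=2
        )
        x = x[fill > 0]
    if x.shape[0] < 2:
        raise ValueError("NODF needs at least 2 non-empty sites")
    return _nodf_rows(x)


def _has_checkerboard(x: np.ndarray) -> bool:
    n = x.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if ((x[i] == 1) & (x[j] == 0)).any() and ((x[i] == 0) & (x[j] == 1)).any():
                return True
    return False


@dataclass
class SwapNullResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    null_matrices: np.ndarray | None = None  # (n_null, rows, cols) if requested


def swap_null(
    matrix,
    n_null: int = 9999,
    rng: np.random.Generator | None = None,
    burn_in: int | None = None,
    thin: int | None = None,
    return_matrices: bool = False,
) -> SwapNullResult:
    """Sequential-swap null distribution of among-sites NODF.

    Null matrices are generated by 2x2 checkerboard swaps, which preserve
    every row and column sum exactly.  The chain burns in for ``burn_in``
    attempted swaps (default 10x the matrix fill) and runs the same number
    of attempts between samples.  The p-value is one-tailed for nestedness:
    (1 + #{null >= observed}) / (n_null + 1).
    """
    rng = np.random.default_rng() if rng is None else rng
    x, _, _ = _as_matrix(matrix)
    # zero rows/columns are invariant under swaps; drop them once
    x = x[x.sum(axis=1) > 0][:, x.sum(axis=0) > 0]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 non-empty sites")
    observed = _nodf_rows(x)
    if not _has_checkerboard(x):
        warnings.warn("no swappable checkerboard: degenerate null, p = 1", stacklevel=2)
        return SwapNullResult(observed, np.empty(0), 1.0)
    fill = int(x.sum())
    burn_in = 10 * fill if burn_in is None else burn_in
    thin = 10 * fill if thin is None else thin
    n_rows, n_cols = x.shape

    vals = np.empty(n_null)
    mats = np.empty((n_null, n_rows, n_cols), dtype=np.int8) if return_matrices else None
    # batched random candidate quadruples; the swap itself stays sequential
    batch = 1 << 15
    ri = rng.integers(0, n_rows, size=(batch, 2))
    ci = rng.integers(0, n_cols, size=(batch, 2))
    ptr = 0
    done = 0
    sampled = 0
    target = burn_in
    while sampled < n_null:
        if ptr >= batch:
            ri = rng.integers(0, n_rows, size=(batch, 2))
            ci = rng.integers(0, n_cols, size=(batch, 2))
            ptr = 0
        i1, i2 = ri[ptr]
        j1, j2 = ci[ptr]
        ptr += 1
        done += 1
        if i1 != i2 and j1 != j2:
            a = x[i1, j1]
            d = x[i2, j2]
            if a == d and x[i1, j2] == x[i2, j1] and a != x[i1, j2]:
                x[i1, j1] = x[i2, j2] = 1 - a
                x[i1, j2] = x[i2, j1] = a
        if done >= target:
            vals[sampled] = _nodf_rows(x)
            if mats is not None:
                mats[sampled] = x
            sampled += 1
            target += thin
    p = (1.0 + np.sum(vals >= observed - 1e-12)) / (n_null + 1.0)
    return SwapNullResult(observed, vals, float(p), mats)


def packed_order(matrix) -> list:
    """Site order of the maximally packed matrix.

    Sites sort by decreasing fill; ties break by decreasing total overlap
    with strictly richer sites, then by label.
    """
    x, rows, _ = _as_matrix(matrix)
    fill = x.sum(axis=1)
    shared = x @ x.T
    richer = fill[None, :] > fill[:, None]
    overlap_with_richer = (shared * richer.T).sum(axis=0)

    def key(i):
        return (-fill[i], -overlap_with_richer[i], rows[i])

    return [rows[i] for i in sorted(range(len(rows)), key=key)]


def congruence(matrix_a, matrix_b) -> tuple[float, float]:
    """Spearman rank correlation between the packed site orders of two matrices.

    Sites are matched by label; both matrices must share their site set.
    """
    order_a = packed_order(matrix_a)
    order_b = packed_order(matrix_b)
    if set(order_a) != set(order_b):
        raise ValueError("matrices must share the same site labels")
    rank_a = {s: i for i, s in enumerate(order_a)}
    rank_b = {s: i for i, s in enumerate(order_b)}
    sites = sorted(order_a, key=str)
    res = stats.spearmanr([rank_a[s] for s in sites], [rank_b[s] for s in sites])
    return float(res.statistic), float(res.pvalue)


def mantel(
    dist_a,
    dist_b,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    r_m is the Pearson correlation of the lower-triangle entries; the
    p-value permutes the site labels of the second matrix, one-tailed in the
    positive direction (distance decay), with the +1 convention including
    the observed statistic.
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and the same shape")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("distance matrices must be symmetric")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va, vb = a[iu], b[iu]
    if np.nanstd(va) == 0 or np.nanstd(vb) == 0:
        raise ValueError("zero-variance distance matrix: Mantel r undefined")
    r_obs = _pearson(va, vb)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        vp = b[np.ix_(p, p)][iu]
        if _pearson(va, vp) >= r_obs - 1e-12:
            count += 1
    p_val = (1.0 + count) / (n_perm + 1.0)
    return float(r_obs), float(p_val)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


@dataclass(frozen=True)
class ModelFit:
    """Least-squares comparison of a predicted and an observed map."""

    n: int
    k: int
    rss: float
    r2: float
    bic: float


_RSS_FLOOR = 1e-12


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant map: min-max rescaling undefined")
    return (v - lo) / (hi - lo)


def model_fit(predicted, observed, k: int, rescale: bool = True) -> ModelFit:
    """Fit statistics of a predicted map against an observed map.

    Maps given as pandas Series are aligned on their common cells (NaNs
    dropped); with ``rescale`` both are min-max rescaled to [0, 1] first, so
    the fit is invariant to affine rescaling of the raw inputs.  RSS is the
    residual sum of squares (floored at 1e-12 so that BIC = n*ln(RSS/n) +
    k*ln(n) stays finite), R^2 comes from OLS of observed on predicted.
    """
    if isinstance(predicted, pd.Series) or isinstance(observed, pd.Series):
        pred = pd.Series(predicted).astype(float)
        obs = pd.Series(observed).astype(float)
        common = pred.index.intersection(obs.index)
        pred = pred.loc[common].to_numpy()
        obs = obs.loc[common].to_numpy()
    else:
        pred = np.asarray(predicted, dtype=float)
        obs = np.asarray(observed, dtype=float)
        if pred.shape != obs.shape:
            raise ValueError("maps must have the same cells")
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    n = pred.size
    if n <= k:
        raise ValueError(f"maps share only {n} cells; need more than k={k}")
    if np.ptp(pred) == 0:
        raise ValueError("constant predicted map: R^2 undefined")
    if rescale:
        pred = _minmax(pred)
        obs = _minmax(obs)
    rss = max(float(np.sum((obs - pred) ** 2)), _RSS_FLOOR)
    lr = stats.linregress(pred, obs)
    r2 = float(lr.rvalue**2)
    bic = n * np.log(rss / n) + k * np.log(n)
    return ModelFit(n=n, k=k, rss=rss, r2=r2, bic=float(bic))


def rank_models(fits: dict[str, dict[str, ModelFit]]) -> pd.DataFrame:
    """Rank simulations by BIC summed across comparisons (ascending).

    ``fits`` maps simulation label -> comparison label -> ModelFit; every
    simulation must cover every comparison.  Ties break by fewer model
    parameters, then by label.
    """
    if not fits:
        raise ValueError("no fits to rank")
    comparisons = None
    rows = []
    for label, by_cmp in fits.items():
        keys = frozenset(by_cmp)
        if comparisons is None:
            comparisons = keys
        elif keys != comparisons:
            missing = sorted(comparisons ^ keys)
            raise ValueError(f"simulation {label!r} comparison mismatch: {missing}")
        row = {"simulation": label, "k": max(f.k for f in by_cmp.values())}
        for cname, f in by_cmp.items():
            row[f"bic_{cname}"] = f.bic
            row[f"r2_{cname}"] = f.r2
        row["total_bic"] = sum(f.bic for f in by_cmp.values())
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["total_bic", "k", "simulation"], kind="mergesort", ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table
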