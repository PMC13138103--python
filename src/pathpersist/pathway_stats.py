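"""Per-pathway two-condition tests on Betti-number series.

For each pathway and homological dimension the two conditions yield one
Betti series each over the filtration grid (tau = 101 values by default).
Two complementary statistics compare them:

* the two-sample Kolmogorov–Smirnov statistic K = sup |F_C - F_D| between
  the empirical distributions of the two sets of Betti values, and
* Cohen's d = (mean_C - mean_D) / s with the pooled standard deviation
  s^2 = ((n1-1) s_C^2 + (n2-1) s_D^2) / (n1 + n2 - 2),

so a positive d means the control series runs higher (e.g. more
disconnected components in the control state).  p-values come from
permutations that pool the 2*tau Betti values and reassign them to two
groups of the original sizes; ties count as "at least as extreme".
Benjamini–Hochberg correction is applied across pathways within each of
the four test families (KS / d, dimension 0 / 1), and a pathway is called
significant only when all four q-values fall below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .global_stats import bh_adjust

_TIE_TOL = 1e-12


def ks_statistic(series_c, series_d) -> float:
    """Two-sample KS statistic between two sets of Betti values."""
    c = np.asarray(series_c, dtype=float)
    d = np.asarray(series_d, dtype=float)
    if c.size == 0 or d.size == 0:
        raise ValueError("Betti series must be non-empty")
    return float(stats.ks_2samp(c, d).statistic)


def cohens_d(series_c, series_d) -> float:
    """Pooled-SD standardised mean difference mean(C) - mean(D) over s.

    Two identical constant series give d = 0; two unequal constant series
    have an undefined (infinite) effect and return a signed inf sentinel.
    """
    c = np.asarray(series_c, dtype=float)
    d = np.asarray(series_d, dtype=float)
    if c.size < 2 or d.size < 2:
        raise ValueError("Betti series must have length >= 2")
    mu_delta = c.mean() - d.mean()
    s = _pooled_sd(c, d)
    if s == 0.0:
        if mu_delta == 0.0:
            return 0.0
        return float(np.sign(mu_delta)) * np.inf
    return float(mu_delta / s)


def _pooled_sd(c: np.ndarray, d: np.ndarray) -> float:
    n1, n2 = len(c), len(d)
    var = ((n1 - 1) * c.var(ddof=1) + (n2 - 1) * d.var(ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(var))


def _ks_many(pool: np.ndarray, masks_c: np.ndarray) -> np.ndarray:
    """KS statistics for many label assignments at once.

    ``pool`` is the pooled sample; ``masks_c`` is (R, n) boolean, True where
    the element goes to group C.  The CDF difference is scanned over the
    sorted pool, evaluated at the last index of every tie group.
    """
    order = np.argsort(pool, kind="stable")
    sorted_pool = pool[order]
    # last position of each tie group in the sorted pool
    boundaries = np.nonzero(np.diff(sorted_pool) > _TIE_TOL)[0]
    eval_at = np.concatenate([boundaries, [len(pool) - 1]])
    m = masks_c[:, order]
    n_c = m[0].sum()
    n_d = len(pool) - n_c
    z = np.where(m, 1.0 / n_c, -1.0 / n_d)
    cdf_diff = np.cumsum(z, axis=1)[:, eval_at]
    return np.abs(cdf_diff).max(axis=1)


def _abs_d_many(pool: np.ndarray, masks_c: np.ndarray) -> np.ndarray:
    """|Cohen's d| for many label assignments at once."""
    n = len(pool)
    n_c = int(masks_c[0].sum())
    n_d = n - n_c
    sum_all, sumsq_all = pool.sum(), (pool**2).sum()
    sum_c = masks_c @ pool
    sumsq_c = masks_c @ (pool**2)
    sum_d = sum_all - sum_c
    sumsq_d = sumsq_all - sumsq_c
    mean_c, mean_d = sum_c / n_c, sum_d / n_d
    ss_c = sumsq_c - n_c * mean_c**2
    ss_d = sumsq_d - n_d * mean_d**2
    s = np.sqrt(np.maximum(ss_c + ss_d, 0.0) / (n - 2))
    diff = np.abs(mean_c - mean_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = diff / s
    out[(s == 0.0) & (diff == 0.0)] = 0.0
    out[(s == 0.0) & (diff > 0.0)] = np.inf
    return out


def _random_masks(rng: np.random.Generator, n_perm: int, n: int, n_c: int) -> np.ndarray:
    """(n_perm, n) boolean masks assigning exactly n_c elements to group C."""
    keys = rng.random((n_perm, n))
    return np.argsort(keys, axis=1).argsort(axis=1) < n_c


def permutation_pvalue(
    stat: str,
    series_c,
    series_d,
    n_perm: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    estimator: str = "count",
) -> float:
    """Permutation p-value for the KS statistic or |Cohen's d|.

    Pools the Betti values of both series, reassigns them to two groups of
    the original sizes ``n_perm`` times, and reports the proportion of
    permuted statistics >= the observed one (ties inclusive).
    """
    if stat not in ("ks", "d"):
        raise ValueError(f"unknown statistic {stat!r}; expected 'ks' or 'd'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    c = np.asarray(series_c, dtype=float)
    d = np.asarray(series_d, dtype=float)
    pool = np.concatenate([c, d])
    n_c = len(c)
    observed_mask = np.zeros((1, len(pool)), dtype=bool)
    observed_mask[0, :n_c] = True
    many = _ks_many if stat == "ks" else _abs_d_many
    observed = float(many(pool, observed_mask)[0])
    if rng is None:
        rng = np.random.default_rng(seed)
    masks = _random_masks(rng, n_perm, len(pool), n_c)
    perm_stats = many(pool, masks)
    count = int(np.sum(perm_stats >= observed - _TIE_TOL))
    if estimator == "plus_one":
        return (count + 1) / (n_perm + 1)
    return count / n_perm


@dataclass
class DimensionStats:
    """One pathway's statistics for a single homological dimension."""

    ks: float
    d: float
    mu_delta: float
    s_pooled: float
    p_ks: float
    p_d: float
    q_ks: float | None = None
    q_d: float | None = None


@dataclass
class PathwayTestResult:
    pathway_id: str
    dims: dict[int, DimensionStats] = field(default_factory=dict)
    significant: bool | None = None


def score_pathway(
    pathway_id: str,
    series_by_dim_c: dict[int, np.ndarray],
    series_by_dim_d: dict[int, np.ndarray],
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    estimator: str = "count",
) -> PathwayTestResult:
    """KS and Cohen's d with permutation p-values for every dimension."""
    if rng is None:
        rng = np.random.default_rng(seed)
    result = PathwayTestResult(pathway_id=pathway_id)
    for dim in sorted(series_by_dim_c):
        c = np.asarray(series_by_dim_c[dim], dtype=float)
        d = np.asarray(series_by_dim_d[dim], dtype=float)
        result.dims[dim] = DimensionStats(
            ks=ks_statistic(c, d),
            d=cohens_d(c, d),
            mu_delta=float(c.mean() - d.mean()),
            s_pooled=_pooled_sd(c, d),
            p_ks=permutation_pvalue("ks", c, d, n_perm, rng=rng, estimator=estimator),
            p_d=permutation_pvalue("d", c, d, n_perm, rng=rng, estimator=estimator),
        )
    return result


def pathway_significance(
    results: list[PathwayTestResult], alpha: float = 0.05
) -> list[PathwayTestResult]:
    """BH across pathways within each of the four test families.

    Fills q_ks / q_d per dimension and sets ``significant`` to True only
    when all four q-values are below ``alpha``.
    """
    if not results:
        return results
    dims = sorted(results[0].dims)
    for r in results:
        missing = [d for d in dims if d not in r.dims]
        if missing:
            raise ValueError(
                f"pathway {r.pathway_id} lacks dimensions {missing}"
            )
    for dim in dims:
        for which in ("ks", "d"):
            p = [getattr(r.dims[dim], f"p_{which}") for r in results]
            q = bh_adjust(p)
            for r, qv in zip(results, q):
                setattr(r.dims[dim], f"q_{which}", float(qv))
    for r in results:
        qs = [
            getattr(r.dims[dim], f"q_{which}")
            for dim in dims
            for which in ("ks", "d")
        ]
        r.significant = all(q < alpha for q in qs)
    return results
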