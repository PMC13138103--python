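"""Global two-condition test on averaged persistence landscapes.

Pathway landscapes are averaged per condition; the observed statistic for
each norm is the size of the disease-minus-control average difference.
Significance comes from a permutation null: pathway landscapes from both
conditions are pooled and randomly reassigned into two groups of the
original sizes, and the three norms of the reshuffled difference are
recomputed; the p-value is the proportion of permuted statistics at least
as large as the observed one.  The test runs separately per homological
dimension, and by default the three norms' p-values within a dimension
form one Benjamini–Hochberg family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .landscapes import NORMS, Landscape, _stack


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _array_norms(diff: np.ndarray, grid: np.ndarray) -> dict[str, float]:
    """The three landscape norms of a (K, T) difference array."""
    a = np.abs(diff)
    return {
        "sup": float(a.max()) if a.size else 0.0,
        "one": float(np.trapezoid(a, grid, axis=1).sum()) if a.size else 0.0,
        "two": float(np.sqrt(np.trapezoid(diff**2, grid, axis=1).sum()))
        if diff.size
        else 0.0,
    }


@dataclass
class GlobalTestResult:
    """Observed difference norms with permutation p and BH q values."""

    dimension: int
    observed: dict[str, float]
    p_values: dict[str, float]
    q_values: dict[str, float]
    n_permutations: int
    seed: int | None

    def summary(self) -> list[dict]:
        rows = []
        for norm in self.observed:
            p = self.p_values[norm]
            rows.append(
                {
                    "dimension": self.dimension,
                    "norm": norm,
                    "observed": self.observed[norm],
                    "p": p,
                    "p_text": f"< {1 / self.n_permutations:g}" if p == 0.0 else f"{p:g}",
                    "q": self.q_values[norm],
                    "n_perm": self.n_permutations,
                    "seed": self.seed,
                }
            )
        return rows


def global_permutation_test(
    landscapes_c: list[Landscape],
    landscapes_d: list[Landscape],
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    estimator: str = "count",
    adjust: bool = True,
) -> GlobalTestResult:
    """Permutation test of the averaged-landscape difference, one dimension.

    ``estimator="count"`` reports p = count/N exactly (a zero count prints
    as "< 1/N"); ``estimator="plus_one"`` uses the conservative
    (count + 1)/(N + 1).
    """
    if not landscapes_c or not landscapes_d:
        raise ValueError("both condition groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if estimator not in ("count", "plus_one"):
        raise ValueError(f"unknown p-value estimator {estimator!r}")
    pool, grid, dim = _stack(list(landscapes_c) + list(landscapes_d))
    n_c = len(landscapes_c)
    n = pool.shape[0]

    diff = pool[n_c:].mean(axis=0) - pool[:n_c].mean(axis=0)
    observed = _array_norms(diff, grid)

    if rng is None:
        rng = np.random.default_rng(seed)
    counts = {norm: 0 for norm in NORMS}
    for _ in range(n_perm):
        idx = rng.permutation(n)
        perm_diff = pool[idx[n_c:]].mean(axis=0) - pool[idx[:n_c]].mean(axis=0)
        perm_norms = _array_norms(perm_diff, grid)
        for norm in NORMS:
            if perm_norms[norm] >= observed[norm]:
                counts[norm] += 1
    if estimator == "count":
        p_values = {norm: counts[norm] / n_perm for norm in NORMS}
    else:
        p_values = {norm: (counts[norm] + 1) / (n_perm + 1) for norm in NORMS}
    if adjust:
        q = bh_adjust([p_values[norm] for norm in NORMS])
        q_values = dict(zip(NORMS, (float(x) for x in q)))
    else:
        q_values = dict(p_values)
    return GlobalTestResult(
        dimension=dim,
        observed=observed,
        p_values=p_values,
        q_values=q_values,
        n_permutations=n_perm,
        seed=seed,
    )


def global_tests(
    landscapes_by_dim: dict[int, tuple[list[Landscape], list[Landscape]]],
    n_perm: int = 1000,
    seed: int | None = None,
    estimator: str = "count",
    bh_family: str = "per_dimension",
) -> dict[int, GlobalTestResult]:
    """Run the global test for several dimensions.

    ``bh_family="per_dimension"`` adjusts each dimension's three norms on
    their own; ``"joint"`` adjusts all norms of all dimensions as one
    family.
    """
    if bh_family not in ("per_dimension", "joint"):
        raise ValueError(f"unknown BH family {bh_family!r}")
    rng = np.random.default_rng(seed)
    results = {}
    for dim in sorted(landscapes_by_dim):
        ls_c, ls_d = landscapes_by_dim[dim]
        results[dim] = global_permutation_test(
            ls_c, ls_d, n_perm=n_perm, rng=rng, seed=seed,
            estimator=estimator, adjust=(bh_family == "per_dimension"),
        )
    if bh_family == "joint":
        keys = [(dim, norm) for dim in results for norm in NORMS]
        q = bh_adjust([results[d].p_values[n] for d, n in keys])
        for (d, norm), qv in zip(keys, q):
            results[d].q_values[norm] = float(qv)
    return results
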