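"""Per-pathway KS / Cohen's d statistics and permutation inference."""

import itertools

import numpy as np
import pytest

from pathpersist import cohens_d, ks_statistic, pathway_significance, permutation_pvalue
from pathpersist.pathway_stats import DimensionStats, PathwayTestResult, score_pathway


def brute_force_ks(a, b):
    """sup |F_a - F_b| evaluated over the pooled support, from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    support = np.unique(np.concatenate([a, b]))
    return max(
        abs(np.mean(a <= v) - np.mean(b <= v)) for v in support
    )


class TestKsStatistic:
    def test_identical_series(self):
        s = np.array([0, 1, 2, 3, 3])
        assert ks_statistic(s, s) == 0.0

    def test_disjoint_supports(self):
        assert ks_statistic(np.zeros(10), np.full(10, 5)) == 1.0

    def test_matches_brute_force_cdf_evaluation(self):
        c = np.array([0, 0, 1, 2])
        d = np.array([1, 2, 2, 3])
        assert ks_statistic(c, d) == pytest.approx(brute_force_ks(c, d))

    def test_symmetry_on_random_integer_series(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 6, size=30)
            b = rng.integers(0, 6, size=30)
            k = ks_statistic(a, b)
            assert k == pytest.approx(ks_statistic(b, a))
            assert k == pytest.approx(brute_force_ks(a, b))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1, 2])


class TestCohensD:
    def test_identical_series_zero(self):
        s = np.array([1.0, 2.0, 3.0])
        assert cohens_d(s, s) == 0.0

    def test_hand_pooled_variance_case(self):
        # means 2 and 3, both sample SDs 1 -> pooled s = 1, d = -1
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_positive_d_means_control_runs_higher(self):
        assert cohens_d([5, 6, 7], [1, 2, 3]) > 0

    def test_constant_unequal_series_give_inf_sentinel(self):
        assert cohens_d([2, 2, 2], [5, 5, 5]) == -np.inf

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1], [1, 2])


class TestPermutationPvalue:
    def test_identical_series_p_one(self):
        s = np.arange(10)
        assert permutation_pvalue("ks", s, s, n_perm=50, seed=0) == 1.0

    def test_separated_series_p_near_zero(self):
        p = permutation_pvalue(
            "ks", np.zeros(101), np.full(101, 10), n_perm=500, seed=1
        )
        assert p <= 1 / 500

    def test_exact_enumeration_at_tiny_tau(self):
        """tau=3, all-0 vs all-10: of the C(6,3)=20 equal-size splits only
        the 2 degenerate ones reach the observed KS=1, so p -> 0.1."""
        c, d = np.zeros(3), np.full(3, 10.0)
        splits = list(itertools.combinations(range(6), 3))
        pool = np.concatenate([c, d])
        exact = np.mean(
            [brute_force_ks(pool[list(s)],
                            pool[[i for i in range(6) if i not in s]]) >= 1.0
             for s in splits]
        )
        assert exact == pytest.approx(0.1)
        p = permutation_pvalue("ks", c, d, n_perm=4000, seed=3)
        assert p == pytest.approx(exact, abs=0.02)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(0, 5, 40), rng.integers(0, 5, 40)
        p1 = permutation_pvalue("d", a, b, n_perm=200, seed=11)
        p2 = permutation_pvalue("d", a, b, n_perm=200, seed=11)
        assert p1 == p2

    def test_label_swap_invariance_equal_sizes(self):
        rng = np.random.default_rng(6)
        a, b = rng.integers(0, 8, 50), rng.integers(2, 10, 50)
        p1 = permutation_pvalue("ks", a, b, n_perm=1000, seed=2)
        p2 = permutation_pvalue("ks", b, a, n_perm=1000, seed=2)
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_unknown_statistic_and_bad_nperm(self):
        with pytest.raises(ValueError):
            permutation_pvalue("mean", [1, 2], [3, 4])
        with pytest.raises(ValueError):
            permutation_pvalue("ks", [1, 2], [3, 4], n_perm=0)

    def test_observed_statistic_matches_public_functions(self):
        """The internal vectorised statistics agree with ks_statistic and
        cohens_d on the unpermuted labelling."""
        from pathpersist.pathway_stats import _abs_d_many, _ks_many

        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.integers(0, 10, size=31).astype(float)
            b = rng.integers(0, 10, size=31).astype(float)
            pool = np.concatenate([a, b])
            mask = np.zeros((1, 62), dtype=bool)
            mask[0, :31] = True
            assert _ks_many(pool, mask)[0] == pytest.approx(ks_statistic(a, b))
            assert _abs_d_many(pool, mask)[0] == pytest.approx(abs(cohens_d(a, b)))


def make_results(pvals_by_pathway):
    out = []
    for pid, p in pvals_by_pathway.items():
        r = PathwayTestResult(pathway_id=pid)
        for dim in (0, 1):
            r.dims[dim] = DimensionStats(
                ks=0.5, d=1.0, mu_delta=0.0, s_pooled=1.0,
                p_ks=p[f"ks{dim}"], p_d=p[f"d{dim}"],
            )
        out.append(r)
    return out


class TestPathwaySignificance:
    def test_single_strong_pathway_flagged(self):
        null = {f"ks{d}": 0.8 for d in (0, 1)} | {f"d{d}": 0.7 for d in (0, 1)}
        strong = {k: 0.001 for k in null}
        results = make_results({"hit": strong} | {f"n{i}": null for i in range(9)})
        pathway_significance(results)
        flags = {r.pathway_id: r.significant for r in results}
        assert flags["hit"] and not any(v for k, v in flags.items() if k != "hit")

    def test_one_failing_family_blocks_significance(self):
        p = {"ks0": 0.001, "ks1": 0.001, "d0": 0.001, "d1": 0.2}
        results = make_results({"almost": p})
        pathway_significance(results)
        assert results[0].significant is False
        assert results[0].dims[1].q_d == pytest.approx(0.2)

    def test_bh_is_applied_within_each_family_across_pathways(self):
        results = make_results(
            {
                "a": {"ks0": 0.01, "ks1": 0.5, "d0": 0.5, "d1": 0.5},
                "b": {"ks0": 0.02, "ks1": 0.5, "d0": 0.5, "d1": 0.5},
                "c": {"ks0": 0.03, "ks1": 0.5, "d0": 0.5, "d1": 0.5},
            }
        )
        pathway_significance(results)
        assert [r.dims[0].q_ks for r in results] == pytest.approx([0.03, 0.03, 0.03])

    def test_planted_pvalue_signal_recovered_exactly(self):
        rng = np.random.default_rng(17)
        pvals = {}
        for i in range(20):
            if i < 5:
                pvals[f"p{i:02d}"] = {k: 1e-4 for k in ("ks0", "ks1", "d0", "d1")}
            else:
                pvals[f"p{i:02d}"] = {
                    k: float(rng.uniform(0.2, 1.0))
                    for k in ("ks0", "ks1", "d0", "d1")
                }
        results = make_results(pvals)
        pathway_significance(results)
        flagged = {r.pathway_id for r in results if r.significant}
        assert flagged == {f"p{i:02d}" for i in range(5)}

    def test_missing_dimension_rejected(self):
        results = make_results({"a": {"ks0": 0.5, "ks1": 0.5, "d0": 0.5, "d1": 0.5}})
        del results[0].dims[1]
        other = make_results({"b": {"ks0": 0.5, "ks1": 0.5, "d0": 0.5, "d1": 0.5}})
        with pytest.raises(ValueError, match="lacks dimensions"):
            pathway_significance(other + results)


def test_test_pathway_collects_all_statistics():
    rng = np.random.default_rng(23)
    c = {0: rng.integers(3, 10, 101).astype(float), 1: rng.integers(0, 3, 101).astype(float)}
    d = {0: rng.integers(2, 9, 101).astype(float), 1: rng.integers(0, 3, 101).astype(float)}
    res = score_pathway("pw", c, d, n_perm=100, seed=3)
    for dim in (0, 1):
        st = res.dims[dim]
        assert st.ks == pytest.approx(ks_statistic(c[dim], d[dim]))
        assert st.d == pytest.approx(cohens_d(c[dim], d[dim]))
        assert st.mu_delta == pytest.approx(c[dim].mean() - d[dim].mean())
        assert 0.0 <= st.p_ks <= 1.0 and 0.0 <= st.p_d <= 1.0


def test_null_type_one_error_calibrated_for_ks_permutation():
    """Both series i.i.d. from one continuous distribution: rejection rate
    at alpha=0.05 stays inside the 95% binomial band over 200 replicates."""
    rng = np.random.default_rng(31337)
    n_rep, rejections = 200, 0
    for _ in range(n_rep):
        a = rng.normal(size=101)
        b = rng.normal(size=101)
        p = permutation_pvalue("ks", a, b, n_perm=500, rng=rng)
        if p < 0.05:
            rejections += 1
    rate = rejections / n_rep
    ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
    assert 0.05 - ci <= rate <= 0.05 + ci
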