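"""Normalization, gene ranking, GSEA running sums and GSVA scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radigen.enrichment import (
    benjamini_hochberg,
    gsea_es,
    gsea_phenotype_significance,
    gsea_significance,
    gsva_scores,
    normalize_log,
    rank_genes,
    size_factors,
)

RNG = np.random.default_rng(41)


def counts_frame(X):
    X = np.asarray(X)
    return pd.DataFrame(
        X,
        index=[f"g{i:04d}" for i in range(X.shape[0])],
        columns=[f"s{j:03d}" for j in range(X.shape[1])],
    )


def running_sum_oracle(stats_desc, member_flags, p=1.0):
    """Literal step-by-step GSEA walk; returns the signed extreme deviation."""
    w = np.abs(stats_desc[member_flags]) ** p
    total_w = w.sum()
    n, m = len(stats_desc), member_flags.sum()
    cur, best = 0.0, 0.0
    wi = 0
    for i in range(n):
        if member_flags[i]:
            cur += np.abs(stats_desc[i]) ** p / total_w
            wi += 1
        else:
            cur -= 1.0 / (n - m)
        if abs(cur) > abs(best) or (abs(cur) == abs(best) and cur > best):
            best = cur
    return best


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        X = RNG.integers(1, 200, (50, 1))
        counts = counts_frame(np.repeat(X, 2, axis=1))
        f = size_factors(counts)
        np.testing.assert_allclose(f, [1.0, 1.0])

    def test_pure_depth_effect(self):
        a = RNG.integers(1, 500, 80)
        counts = counts_frame(np.column_stack([a, 2 * a]))
        f = size_factors(counts)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_matches_naive_median_oracle(self):
        X = RNG.negative_binomial(5, 0.1, (60, 8)) + 1
        counts = counts_frame(X)
        f = size_factors(counts)
        geo = np.exp(np.log(X).mean(axis=1))
        oracle = [np.median(X[:, j] / geo) for j in range(8)]
        np.testing.assert_allclose(f, oracle, rtol=1e-12)

    def test_no_universal_gene_raises(self):
        X = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts_frame(X))


class TestRankGenes:
    def _counts(self, shift=0.0):
        base = RNG.negative_binomial(10, 0.3, (40, 12)) + 1
        X = base.astype(float)
        X[0, 6:] *= 2**shift  # gene 0 shifted in the high group
        return counts_frame(X.astype(int))

    def test_identical_groups_give_zero(self):
        X = np.tile(RNG.integers(10, 100, (30, 6)), (1, 2))
        t = rank_genes(counts_frame(X), [False] * 6 + [True] * 6)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_matches_closed_form_welch_t(self):
        counts = self._counts(shift=1.5)
        labels = np.array([False] * 6 + [True] * 6)
        t = rank_genes(counts, labels)
        log_expr = normalize_log(counts)
        for gene in ("g0000", "g0017"):
            x1 = log_expr.loc[gene][labels.nonzero()[0]]
            x0 = log_expr.loc[gene][(~labels).nonzero()[0]]
            expected = stats.ttest_ind(x1, x0, equal_var=False).statistic
            assert t[gene] == pytest.approx(expected, rel=1e-9)

    def test_label_swap_negates(self):
        counts = self._counts(shift=1.0)
        labels = np.array([False] * 6 + [True] * 6)
        t1 = rank_genes(counts, labels).sort_index()
        t2 = rank_genes(counts, ~labels).sort_index()
        np.testing.assert_allclose(t1, -t2, atol=1e-12)


class TestGseaEs:
    def test_single_member_ranked_first(self):
        s = np.linspace(5, 0.1, 10)
        flags = np.zeros(10, dtype=bool)
        flags[0] = True
        assert gsea_es(s, flags) == pytest.approx(1.0)

    def test_single_member_ranked_last_enumerated(self):
        s = np.linspace(5, 0.1, 10)
        flags = np.zeros(10, dtype=bool)
        flags[-1] = True
        expected = running_sum_oracle(s, flags)
        assert gsea_es(s, flags) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-(9 / 9) * 1.0 + 0.0, abs=1.0)  # negative extreme
        assert gsea_es(s, flags) < 0

    def test_matches_brute_force_running_sum(self):
        s = np.sort(RNG.normal(0, 2, 300))[::-1]
        flags = np.zeros(300, dtype=bool)
        flags[RNG.choice(300, 20, replace=False)] = True
        assert gsea_es(s, flags) == pytest.approx(
            running_sum_oracle(s, flags), rel=1e-12
        )

    def test_bounded_and_monotone_invariant_at_p0(self):
        s = np.sort(RNG.normal(0, 1, 100))[::-1]
        flags = RNG.random(100) < 0.2
        flags[0] = True
        es1 = gsea_es(s, flags, p=0)
        es2 = gsea_es(np.exp(s), flags, p=0)  # monotone transform
        assert -1.0 <= es1 <= 1.0
        assert es1 == pytest.approx(es2, rel=1e-12)


class TestGseaSignificance:
    def _ranked(self, n=200):
        vals = np.sort(RNG.normal(0, 1, n))[::-1]
        return pd.Series(vals, index=[f"g{i:04d}" for i in range(n)])

    def test_single_set_q_equals_p(self):
        ranked = self._ranked()
        sets = {"A": list(ranked.index[50:70])}
        res = gsea_significance(ranked, sets, n_perm=100, seed=3)
        assert res.table.loc["A", "qval"] == res.table.loc["A", "pval"]

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for rep in range(60):
            rng = np.random.default_rng(rep)
            vals = np.sort(rng.normal(0, 1, 150))[::-1]
            ranked = pd.Series(vals, index=[f"g{i:04d}" for i in range(150)])
            members = rng.choice(ranked.index, 15, replace=False)
            res = gsea_significance(ranked, {"S": list(members)}, n_perm=100, seed=rep)
            pvals.append(res.table.loc["S", "pval"])
        # discrete p-values: check the mean is near 0.5, not KS-exactness
        assert 0.35 < np.mean(pvals) < 0.65

    def test_planted_top_set_is_significant(self):
        n = 300
        vals = np.sort(RNG.normal(0, 1, n))[::-1]
        ranked = pd.Series(vals, index=[f"g{i:04d}" for i in range(n)])
        sets = {
            "planted": list(ranked.index[:20]),
            "random": list(RNG.choice(ranked.index, 20, replace=False)),
        }
        res = gsea_significance(ranked, sets, n_perm=200, seed=5)
        assert res.table.loc["planted", "pval"] < 0.01
        assert res.table.loc["planted", "direction"] == "high"

    def test_bh_monotone_and_bounded(self):
        p = RNG.uniform(0, 1, 40)
        q = benjamini_hochberg(p)
        assert np.all(q <= 1.0) and np.all(q >= 0.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestGsvaScores:
    def _planted_counts(self, n=120, shift=1.0, seed=8):
        rng = np.random.default_rng(seed)
        G = 300
        base = rng.uniform(2, 5, G)
        mu = np.exp(np.tile(base[:, None], (1, n)))
        member = np.arange(20)
        half = np.arange(n) < n // 2
        mu[np.ix_(member, np.flatnonzero(half))] *= np.exp(shift)
        lam = rng.gamma(5.0, mu / 5.0)
        counts = counts_frame(rng.poisson(lam))
        sets = {"S": [f"g{i:04d}" for i in member]}
        return counts, sets, half

    def test_null_scores_centered(self):
        counts, sets, _ = self._planted_counts(n=200, shift=0.0)
        es = gsva_scores(counts, sets)
        assert abs(es.loc["S"].mean()) < 0.05
        assert es.to_numpy().min() >= -1.0 and es.to_numpy().max() <= 1.0

    def test_shifted_half_scores_higher(self):
        counts, sets, half = self._planted_counts(shift=1.0)
        es = gsva_scores(counts, sets)
        hi = es.loc["S"][half]
        lo = es.loc["S"][~half]
        t, p = stats.ttest_ind(hi, lo)
        assert t > 0 and p < 0.01

    def test_sample_permutation_equivariance(self):
        counts, sets, _ = self._planted_counts(n=40)
        es = gsva_scores(counts, sets)
        perm = RNG.permutation(counts.shape[1])
        es_perm = gsva_scores(counts.iloc[:, perm], sets)
        np.testing.assert_allclose(es_perm.to_numpy(), es.to_numpy()[:, perm], atol=1e-12)

    def test_needs_four_samples(self):
        counts = counts_frame(RNG.integers(1, 50, (30, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            gsva_scores(counts, {"S": ["g0000", "g0001"]})


class TestPhenotypeNull:
    def test_matches_observed_es_of_rank_based_route(self):
        counts = counts_frame(RNG.negative_binomial(8, 0.2, (120, 20)) + 1)
        labels = np.array([True] * 10 + [False] * 10)
        sets = {"S": [f"g{i:04d}" for i in range(25, 45)]}
        res = gsea_phenotype_significance(counts, labels, sets, n_perm=100, seed=2)
        ranked = rank_genes(counts, labels)
        member = ranked.index.isin(sets["S"])
        es_direct = gsea_es(ranked.to_numpy(), member)
        assert res.table.loc["S", "es"] == pytest.approx(es_direct, rel=1e-9)
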