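import itertools
from math import comb

import numpy as np
import pytest

from mvdst import (
    SRTDataset,
    differential_expression,
    evaluate_clustering,
    evaluate_mse,
    identify_domains,
)
from mvdst.downstream import exact_ranksum_pvalue, wilcoxon_rank_sum
from mvdst.exceptions import ContractError, ParameterError


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def ari_oracle(a, b):
    """Adjusted Rand index from the contingency table, first principles."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    cells = {}
    for x, y in zip(a, b):
        cells[(x, y)] = cells.get((x, y), 0) + 1
    index = sum(comb(c, 2) for c in cells.values())
    row = {}
    col = {}
    for (x, y), c in cells.items():
        row[x] = row.get(x, 0) + c
        col[y] = col.get(y, 0) + c
    sum_a = sum(comb(c, 2) for c in row.values())
    sum_b = sum(comb(c, 2) for c in col.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def ranksum_oracle(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, N = len(x), len(pooled)
    mu = n1 * (N + 1) / 2.0
    s_obs = ranks[:n1].sum()
    dev = abs(s_obs - mu) - 1e-12
    extreme = total = 0
    for idx in itertools.combinations(range(N), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            extreme += 1
    return extreme / total


def all_partitions(items):
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def partition_to_labels(part, n):
    lab = np.empty(n, dtype=int)
    for c, block in enumerate(part):
        lab[block] = c
    return lab


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

class TestIdentifyDomains:
    def test_single_cluster(self):
        Z = np.random.default_rng(0).standard_normal((8, 3))
        out = identify_domains(Z, k=1, seed=0)
        assert set(out.labels) == {0}

    def test_separated_blobs_perfect(self):
        rng = np.random.default_rng(1)
        Z = np.vstack([rng.standard_normal((20, 2)),
                       rng.standard_normal((20, 2)) + 100.0])
        truth = np.repeat([0, 1], 20)
        out = identify_domains(Z, k=2, seed=0)
        assert evaluate_clustering(out, truth=truth).ari == 1.0

    def test_deterministic(self):
        Z = np.random.default_rng(2).standard_normal((30, 4))
        a = identify_domains(Z, k=3, seed=5)
        b = identify_domains(Z, k=3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_out_of_range(self):
        with pytest.raises(ParameterError):
            identify_domains(np.zeros((3, 2)), k=4)


class TestEvaluateMse:
    def test_perfect(self):
        X = np.random.default_rng(0).standard_normal((5, 4))
        assert evaluate_mse(X, X) == 0.0

    def test_hand_examples(self):
        assert evaluate_mse(np.array([[1.0, 1.0]]), np.array([[0.0, 1.0]])) == 1.0
        assert evaluate_mse(np.array([[1.0], [3.0]]), np.array([[0.0], [0.0]])) == 5.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 6, 3))
        assert evaluate_mse(a, b) == evaluate_mse(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ContractError):
            evaluate_mse(np.zeros((2, 2)), np.zeros((3, 2)))


class TestEvaluateClustering:
    def test_identical_partitions(self):
        lab = np.array([0, 0, 1, 1, 2])
        assert evaluate_clustering(lab, truth=lab).ari == 1.0

    def test_label_permutation_invariant(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        lab = np.array([5, 5, 9, 9, 1, 1])
        assert evaluate_clustering(lab, truth=truth).ari == 1.0

    def test_hand_example_minus_half(self):
        ari = evaluate_clustering(
            np.array([0, 1, 0, 1]), truth=np.array([0, 0, 1, 1])
        ).ari
        assert ari == pytest.approx(-0.5)

    def test_matches_bruteforce_oracle_on_all_partitions(self):
        n = 5
        parts = [partition_to_labels(p, n) for p in all_partitions(list(range(n)))]
        from sklearn.metrics import adjusted_rand_score

        for a in parts:
            for b in parts:
                assert adjusted_rand_score(a, b) == pytest.approx(
                    ari_oracle(a, b), abs=1e-12
                )

    def test_ari_one_iff_identical_partition(self):
        n = 5
        parts = [partition_to_labels(p, n) for p in all_partitions(list(range(n)))]
        from sklearn.metrics import adjusted_rand_score

        for a in parts:
            for b in parts:
                same = ari_oracle(a, b) == 1.0
                identical = len(set(zip(a, b))) == len(set(a)) == len(set(b))
                assert same == identical

    def test_silhouette_and_dbi_ranges(self):
        rng = np.random.default_rng(0)
        Z = np.vstack([rng.standard_normal((15, 2)),
                       rng.standard_normal((15, 2)) + 8.0])
        lab = np.repeat([0, 1], 15)
        rep = evaluate_clustering(lab, features=Z)
        assert -1.0 <= rep.silhouette <= 1.0
        assert rep.davies_bouldin >= 0.0

    def test_single_cluster_metrics_absent_with_warning(self):
        Z = np.random.default_rng(0).standard_normal((6, 2))
        with pytest.warns(UserWarning):
            rep = evaluate_clustering(np.zeros(6, dtype=int), features=Z)
        assert rep.silhouette is None
        assert rep.davies_bouldin is None


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum + DE
# ---------------------------------------------------------------------------

class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 7))
        x = rng.integers(0, 4, size=n1).astype(float)
        y = rng.integers(0, 4, size=n2).astype(float)
        assert exact_ranksum_pvalue(x, y) == pytest.approx(
            ranksum_oracle(x, y), abs=1e-12
        )

    def test_three_vs_three_constant_shift(self):
        p = exact_ranksum_pvalue(np.array([4.0, 4.0, 4.0]),
                                 np.array([0.0, 0.0, 0.0]))
        assert p == pytest.approx(0.1)

    def test_five_vs_five_constant_shift(self):
        p = exact_ranksum_pvalue(np.full(5, 4.0), np.zeros(5))
        assert p == pytest.approx(2.0 / 252.0)

    def test_identical_groups_p_one(self):
        assert exact_ranksum_pvalue(np.ones(3), np.ones(4)) == 1.0

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40) + 1.0
        y = rng.standard_normal(40)
        p = wilcoxon_rank_sum(x, y)
        from scipy.stats import mannwhitneyu

        expected = mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").pvalue
        assert p == pytest.approx(expected)


class TestBenjaminiHochberg:
    def test_single_test_fdr_equals_p(self):
        from statsmodels.stats.multitest import multipletests

        assert multipletests([0.03], method="fdr_bh")[1][0] == pytest.approx(0.03)

    @pytest.mark.parametrize("seed", range(5))
    def test_step_up_oracle(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(12)
        got = multipletests(p, method="fdr_bh")[1]
        # step-up from first principles
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(got, adj, atol=1e-12)
        assert np.all((got >= 0) & (got <= 1))


def _de_dataset(in_vals, out_vals):
    """Single-gene dataset: first len(in_vals) spots form domain 0."""
    vals = np.concatenate([in_vals, out_vals]).astype(float)[:, None]
    n = len(vals)
    ds = SRTDataset(
        expression=vals,
        coords=np.zeros((n, 2)),
        spot_ids=[f"s{i}" for i in range(n)],
        gene_ids=["g"],
        normalized=True,
    )
    labels = np.array([0] * len(in_vals) + [1] * len(out_vals))
    return ds, labels


class TestDifferentialExpression:
    def test_null_gene_never_reported(self):
        ds, labels = _de_dataset([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert differential_expression(ds, labels) == []

    def test_three_vs_three_rejected_at_fdr(self):
        # passes pct and lfc filters, but exact two-sided p = 0.1 > 0.05
        ds, labels = _de_dataset([4.0, 4.0, 4.0], [0.0, 0.0, 0.0])
        records = differential_expression(ds, labels)
        assert records == []

    def test_five_vs_five_reported(self):
        ds, labels = _de_dataset([4.0] * 5, [0.0] * 5)
        records = differential_expression(ds, labels)
        domains = {r.domain for r in records}
        assert 0 in domains
        rec = next(r for r in records if r.domain == 0)
        assert rec.p_value == pytest.approx(2.0 / 252.0)
        assert rec.fdr <= 0.05
        assert rec.pct_in_domain == 1.0
        assert rec.log2_fold_change >= 2.0

    def test_small_domain_error_names_domain(self):
        ds, labels = _de_dataset([4.0], [0.0, 0.0, 0.0])
        with pytest.raises(ParameterError, match="domain 0"):
            differential_expression(ds, labels)

    def test_requires_normalized(self):
        ds, labels = _de_dataset([4.0] * 3, [0.0] * 3)
        ds.normalized = False
        with pytest.raises(ParameterError):
            differential_expression(ds, labels)

    def test_reported_records_respect_filters(self):
        rng = np.random.default_rng(0)
        n, g = 30, 8
        X = rng.exponential(1.0, size=(n, g))
        X[:15, 0] += 6.0  # strong marker for domain 0
        ds = SRTDataset(
            expression=X,
            coords=np.zeros((n, 2)),
            spot_ids=[f"s{i}" for i in range(n)],
            gene_ids=[f"g{j}" for j in range(g)],
            normalized=True,
        )
        labels = np.repeat([0, 1], 15)
        for rec in differential_expression(ds, labels):
            assert rec.pct_in_domain > 0.8
            assert abs(rec.log2_fold_change) >= 2.0
            assert rec.fdr <= 0.05
            assert 0.0 <= rec.p_value <= 1.0
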