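import numpy as np
import pandas as pd
import pytest

import tinstab as ts
from tinstab.io import ValidationError
from tinstab.sf import (cluster_association, compare_mean_r, correlate_genes,
                        hierarchical_cluster, permutation_null,
                        random_geneset_null)


def expr_frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


def rel_series(values, samples=None):
    samples = samples or [f"S{j}" for j in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=samples)


class TestCorrelateGenes:
    def test_self_correlation(self):
        y = rel_series([0.1, -0.4, 0.9, 0.2])
        res = correlate_genes(expr_frame([y.to_numpy()]), y)
        assert res.table["r"].iloc[0] == pytest.approx(1.0)
        assert res.table["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        y = rel_series([0.1, -0.4, 0.9, 0.2])
        res = correlate_genes(expr_frame([-y.to_numpy()]), y)
        assert res.table["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        res = correlate_genes(expr_frame([[2.0, 1.0, 4.0, 3.0]]),
                              rel_series([1.0, 2.0, 3.0, 4.0]))
        assert res.table["r"].iloc[0] == pytest.approx(0.6, abs=1e-9)

    def test_matches_covariance_formula_oracle(self, rng):
        expr = expr_frame(rng.normal(size=(30, 12)))
        y = rel_series(rng.normal(size=12))
        res = correlate_genes(expr, y)
        yv = y.to_numpy()
        for g in expr.index:
            x = expr.loc[g].to_numpy()
            r = (np.mean(x * yv) - x.mean() * yv.mean()) / (x.std() * yv.std())
            assert res.table.loc[g, "r"] == pytest.approx(r, abs=1e-9)

    def test_constant_gene_excluded(self):
        expr = expr_frame([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        res = correlate_genes(expr, rel_series([1.0, 2.0, 3.0, 4.0]))
        assert res.excluded == ["G0"]
        assert list(res.table.index) == ["G1"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="3 samples"):
            correlate_genes(expr_frame([[1.0, 2.0]]), rel_series([1.0, 2.0]))


class TestCompareMeanR:
    def test_identical_groups(self):
        t, p = compare_mean_r([-0.3, -0.2, -0.4], [-0.3, -0.2, -0.4])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        a = np.array([-0.5, -0.4, -0.6])
        b = np.array([0.1, 0.0, 0.2])
        t, p = compare_mean_r(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(expected, abs=1e-9)

    def test_swap_flips_sign(self):
        t1, p1 = compare_mean_r([-0.5, -0.4], [0.1, 0.2])
        t2, p2 = compare_mean_r([0.1, 0.2], [-0.5, -0.4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_mean_r([0.1], [0.2, 0.3])


class TestRandomSets:
    def test_degenerate_full_size_sets_have_no_variance(self, rng):
        expr = expr_frame(rng.normal(size=(20, 10)))
        y = rel_series(rng.normal(size=10))
        null = random_geneset_null(expr, y, n_sets=5, set_size=20, seed=0)
        assert null.table["n_significant"].nunique() == 1

    def test_null_significant_count_near_alpha_expectation(self, rng):
        """Independent expression: per-set significant count ~ Binomial(size, alpha)."""
        n_genes, set_size, alpha = 400, 100, 0.05
        expr = expr_frame(rng.normal(size=(n_genes, 40)))
        y = rel_series(rng.normal(size=40))
        null = random_geneset_null(expr, y, n_sets=50, set_size=set_size,
                                   seed=1, alpha=alpha)
        mean = null.table["n_significant"].mean()
        sd = np.sqrt(set_size * alpha * (1 - alpha))
        assert abs(mean - alpha * set_size) < 3 * sd

    def test_seed_determinism(self, rng):
        expr = expr_frame(rng.normal(size=(50, 10)))
        y = rel_series(rng.normal(size=10))
        a = random_geneset_null(expr, y, n_sets=10, set_size=20, seed=3)
        b = random_geneset_null(expr, y, n_sets=10, set_size=20, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_oversized_set_rejected(self, rng):
        expr = expr_frame(rng.normal(size=(10, 8)))
        with pytest.raises(ValidationError, match="set_size"):
            random_geneset_null(expr, rel_series(rng.normal(size=8)),
                                n_sets=2, set_size=11)


class TestPermutationNull:
    def test_add_one_rule_lower_bound(self, rng):
        """The observed vector bounds its own p: p >= 1/(n_perm+1)."""
        y = rel_series(rng.normal(size=20))
        expr = expr_frame(np.tile(-y.to_numpy(), (5, 1)) + rng.normal(0, 0.01, (5, 20)))
        null = permutation_null(expr, y, n_perm=99, seed=0)
        assert null.p_median_r >= 1 / 100
        assert null.p_median_r == pytest.approx(1 / 100)

    def test_seed_determinism(self, rng):
        expr = expr_frame(rng.normal(size=(10, 15)))
        y = rel_series(rng.normal(size=15))
        a = permutation_null(expr, y, n_perm=50, seed=9)
        b = permutation_null(expr, y, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValidationError):
            permutation_null(expr_frame(np.zeros((2, 5))),
                             rel_series(np.arange(5.0)), n_perm=0)


class TestClustering:
    def test_two_separated_blobs_recovered(self, rng):
        a = rng.normal(0, 0.3, size=(15, 10))
        b = rng.normal(5, 0.3, size=(15, 10))
        expr = expr_frame(np.hstack([a, b]))
        part = hierarchical_cluster(expr, center=False)
        labels = part.labels
        blob = pd.Series(["A"] * 10 + ["B"] * 10, index=expr.columns)
        ct = pd.crosstab(labels, blob.loc[labels.index])
        assert (ct.max(axis=1) == ct.sum(axis=1)).all()  # pure clusters

    def test_duplicate_sample_merges_first_at_zero_distance(self, rng):
        expr = expr_frame(rng.normal(size=(8, 4)))
        expr["S1b"] = expr["S1"]
        part = hierarchical_cluster(expr, center=False)
        assert part.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValidationError):
            hierarchical_cluster(expr_frame(rng.normal(size=(5, 1))))

    def test_generative_recovery_separates_otin_directions(self):
        """With SF expression negatively coupled to burden, oTIN-high and
        oTIN-low samples land in different clusters (>= 90% agreement)."""
        rng = np.random.default_rng(11)
        n = 40
        burden = rel_series(np.concatenate([rng.normal(-2, 0.3, 8),
                                            rng.normal(0, 0.3, 24),
                                            rng.normal(2, 0.3, 8)]))
        cfg = ts.SimulationConfig(n_sf_genes=30, sf_coupling_beta=1.0,
                                  sf_noise_sigma=0.3)
        expr = ts.generate_sf_expression(burden, cfg, rng, n_null_genes=0)
        profiles = pd.DataFrame({
            "rel_total": burden,
            "is_oTIN": np.abs(burden) > 1.0,
        })
        otin = list(profiles.index[profiles["is_oTIN"]])
        part = hierarchical_cluster(expr, restrict_to=otin)
        truth = (profiles.loc[part.labels.index, "rel_total"] > 0)
        agree = max((part.labels == 1).eq(truth).mean(),
                    (part.labels == 2).eq(truth).mean())
        assert agree >= 0.9

    def test_association_contingency_and_fisher(self, firma_default, tin_default,
                                                default_sim):
        part = hierarchical_cluster(
            firma_default.expression.loc[default_sim.sf_genes])
        table, p = cluster_association(part, tin_default.profiles)
        assert table.to_numpy().sum() == len(part.labels)
        assert 0.0 <= p <= 1.0


def test_sf_model_negative_coupling_pattern(firma_default, tin_default, default_sim):
    """End to end on the synthetic cohort: splicing-factor genes are mostly
    significantly *negatively* correlated with deviating exon usage, more so
    than random gene sets, and the permutation null is beaten."""
    res = ts.SplicingFactorModel(firma_default.expression, tin_default.rel_total,
                                 default_sim.sf_genes).fit(
        n_random_sets=50, n_perm=200, seed=0)
    corr = res.correlations
    assert corr.n_significant > 0.5 * corr.n_genes
    assert corr.n_negative_significant > 0.9 * corr.n_significant
    assert corr.n_significant > res.random_null.table["n_significant"].mean()
    assert res.permutation.p_median_r < 0.05
    assert res.t_mean_r_vs_random < 0  # shifted towards negative correlation
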