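"""Species ages, Brownian covariance, PGLS, LRT stepwise, correlation tests."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import multivariate_normal

from cladediv.comparative import (
    CovarianceSpec,
    backward_stepwise,
    brownian_covariance,
    brownian_covariance_from_tree,
    correlation_test,
    lrt,
    pearson_correlation,
    pgls_fit,
    species_age,
    upgma_cophenetic,
)
from cladediv.distance import DistanceMatrix
from cladediv.simulate import simulate_chronogram
from cladediv.trees import node_depths, parse_newick


# ---------------------------------------------------------------------------
# species ages
# ---------------------------------------------------------------------------

class TestSpeciesAge:
    def test_cherry_stem_age_is_root_age(self):
        tree = parse_newick("(A:95,B:95);")
        ages = species_age(tree, {"A": "A", "B": "B"}, mode="stem")
        assert ages["A"] == 95.0 and ages["B"] == 95.0

    def test_three_taxon_stem_and_crown(self):
        tree = parse_newick("((A:10,B:10):85,C:95);")
        stem = species_age(tree, {"A": "A", "B": "B", "C": "C"})
        assert stem["A"] == pytest.approx(10.0)
        assert stem["B"] == pytest.approx(10.0)
        assert stem["C"] == pytest.approx(95.0)
        # the two-tip clade {A,B}: stem from the root, crown at its MRCA
        grouped = {"A": "AB", "B": "AB", "C": "C"}
        assert species_age(tree, grouped, mode="stem")["AB"] == pytest.approx(95.0)
        assert species_age(tree, grouped, mode="crown")["AB"] == pytest.approx(10.0)

    def test_matches_depth_table_traversal_oracle(self):
        tree = simulate_chronogram(20, seed=7)
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        ages = species_age(tree, {x: x for x in labels})
        depths = node_depths(tree)
        depth = max(depths[leaf] for leaf in tree.leaf_node_iter())
        for leaf in tree.leaf_node_iter():
            expected = depth - depths[leaf.parent_node]
            assert ages[leaf.taxon.label] == pytest.approx(expected, abs=1e-9)

    def test_stem_at_least_crown(self):
        tree = simulate_chronogram(12, seed=3)
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        # group tips into 4 clades of 3 consecutive labels only if monophyletic;
        # use the two children of the root instead, which are always monophyletic
        kids = tree.seed_node.child_nodes()
        cmap = {}
        for i, kid in enumerate(kids):
            for leaf in kid.leaf_iter():
                cmap[leaf.taxon.label] = f"c{i}"
        stem = species_age(tree, cmap, mode="stem")
        crown = species_age(tree, cmap, mode="crown")
        assert (stem >= crown - 1e-9).all()

    def test_non_monophyletic_clade_lists_intruders(self):
        tree = parse_newick("((A:10,B:10):85,C:95);")
        with pytest.raises(ValueError, match="B"):
            species_age(tree, {"A": "AC", "C": "AC", "B": "B"})

    def test_non_ultrametric_rejected(self):
        tree = parse_newick("((A:10,B:20):85,C:95);")
        with pytest.raises(ValueError, match="ultrametric"):
            species_age(tree, {"A": "A", "B": "B", "C": "C"})

    def test_crown_of_single_tip_falls_back_to_stem(self):
        tree = parse_newick("((A:10,B:10):85,C:95);")
        with pytest.warns(UserWarning, match="crown"):
            ages = species_age(tree, {"A": "A"}, mode="crown")
        assert ages["A"] == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

class TestBrownianCovariance:
    def test_two_species_share_nothing(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 0.10], [0.10, 0.0]]))
        cov = brownian_covariance(dm)
        assert np.allclose(cov.matrix, np.array([[0.05, 0.0], [0.0, 0.05]]))

    def test_hand_worked_upgma_example(self):
        """UPGMA joins A,B at height 0.01; depth T = 0.05; C_AB = 0.04."""
        d = np.array([[0.0, 0.02, 0.10], [0.02, 0.0, 0.10], [0.10, 0.10, 0.0]])
        cov = brownian_covariance(DistanceMatrix(("A", "B", "C"), d))
        expected = np.array([[0.05, 0.04, 0.0], [0.04, 0.05, 0.0], [0.0, 0.0, 0.05]])
        assert np.allclose(cov.matrix, expected, atol=1e-12)

    def test_ultrametric_input_is_fixed_point(self):
        tree = simulate_chronogram(10, seed=11)
        from cladediv.trees import patristic_matrix

        dm = patristic_matrix(tree)
        u = upgma_cophenetic(dm)
        assert np.allclose(u, dm.values, atol=1e-8)

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            m = rng.uniform(0.01, 1.0, size=(n, n))
            m = (m + m.T) / 2.0
            np.fill_diagonal(m, 0.0)
            dm = DistanceMatrix(tuple(f"x{i}" for i in range(n)), m)
            u = upgma_cophenetic(dm)
            z = linkage(squareform(m), method="average")
            u_scipy = squareform(cophenet(z))
            assert np.allclose(u, u_scipy, atol=1e-10)

    def test_output_is_psd(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 15))
            m = rng.uniform(0.001, 0.5, size=(n, n))
            m = (m + m.T) / 2.0
            np.fill_diagonal(m, 0.0)
            cov = brownian_covariance(DistanceMatrix(tuple(f"x{i}" for i in range(n)), m))
            assert np.linalg.eigvalsh(cov.matrix).min() >= -1e-10

    def test_tree_route_matches_shared_depths(self):
        tree = parse_newick("((A:10,B:10):85,C:95);")
        cov = brownian_covariance_from_tree(tree, {"A": "A", "B": "B", "C": "C"})
        i = {lbl: k for k, lbl in enumerate(cov.labels)}
        assert cov.matrix[i["A"], i["B"]] == pytest.approx(85.0)
        assert cov.matrix[i["A"], i["C"]] == pytest.approx(0.0)
        assert cov.depth == pytest.approx(95.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            CovarianceSpec(("A", "B"), np.array([[1.0, 0.2], [0.4, 1.0]]))


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def identity_cov(labels):
    return CovarianceSpec(tuple(labels), np.eye(len(labels)), {"method": "identity"})


def random_dataset(rng, n=20):
    clades = [f"c{i:02d}" for i in range(n)]
    return pd.DataFrame(
        {
            "clade": clades,
            "avg_divergence": rng.normal(0.03, 0.01, n),
            "age": rng.uniform(1, 90, n),
            "avg_geodist": rng.uniform(50, 500, n),
            "env_het": rng.uniform(0.5, 5.0, n),
        }
    )


def random_psd_cov(rng, labels):
    n = len(labels)
    a = rng.normal(size=(n, n))
    m = a @ a.T + n * np.eye(n)
    d = np.sqrt(np.diagonal(m))
    corr = m / np.outer(d, d)
    return CovarianceSpec(tuple(labels), corr * 3.7, {"method": "random"})


class TestPglsFit:
    def test_identity_covariance_equals_ols(self, rng):
        """With C = I the PGLS estimator, SEs, t and F reduce to OLS."""
        for _ in range(10):
            data = random_dataset(rng)
            cov = identity_cov(data["clade"])
            fit = pgls_fit(data, ["age", "avg_geodist"], cov)
            x = sm.add_constant(data[["age", "avg_geodist"]].to_numpy())
            ols = sm.OLS(data["avg_divergence"].to_numpy(), x).fit()
            assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-9)
            assert np.allclose(fit.bse.to_numpy(), ols.bse, atol=1e-9)
            assert np.allclose(fit.tvalues.to_numpy(), ols.tvalues, atol=1e-9)
            assert fit.loglik == pytest.approx(ols.llf, abs=1e-9)

    def test_sequential_f_matches_nested_ols(self, rng):
        data = random_dataset(rng)
        cov = identity_cov(data["clade"])
        terms = ["age", "avg_geodist", "env_het"]
        fit = pgls_fit(data, terms, cov)
        y = data["avg_divergence"].to_numpy()
        rss = []
        for k in range(len(terms) + 1):
            x = sm.add_constant(data[terms[:k]].to_numpy()) if k else np.ones((len(y), 1))
            rss.append(sm.OLS(y, x).fit().ssr)
        mse_full = rss[-1] / (len(y) - len(terms) - 1)
        for k, term in enumerate(terms):
            f_expected = (rss[k] - rss[k + 1]) / mse_full
            assert fit.anova.loc[fit.anova["term"] == term, "F"].item() == pytest.approx(
                f_expected, rel=1e-9
            )

    def test_hand_worked_two_point_regression(self):
        """y=(1,2,4) on x=(0,1,2) with C=I: slope 3/2, intercept 5/6."""
        data = pd.DataFrame(
            {"clade": ["a", "b", "c"], "avg_divergence": [1.0, 2.0, 4.0], "x": [0.0, 1.0, 2.0]}
        )
        fit = pgls_fit(data, ["x"], identity_cov(data["clade"]))
        assert fit.params["x"] == pytest.approx(1.5, abs=1e-12)
        assert fit.params["(Intercept)"] == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_matches_statsmodels_gls_under_random_covariance(self, rng):
        data = random_dataset(rng)
        cov = random_psd_cov(rng, data["clade"])
        fit = pgls_fit(data, ["age", "env_het"], cov)
        x = sm.add_constant(data[["age", "env_het"]].to_numpy())
        gls = sm.GLS(data["avg_divergence"].to_numpy(), x, sigma=cov.matrix / cov.depth).fit()
        assert np.allclose(fit.params.to_numpy(), gls.params, atol=1e-9)
        assert np.allclose(fit.bse.to_numpy(), gls.bse, atol=1e-9)

    def test_loglik_matches_multivariate_normal_density(self, rng):
        """Profiled ML log-likelihood equals the explicit Gaussian density."""
        data = random_dataset(rng, n=12)
        cov = random_psd_cov(rng, data["clade"])
        fit = pgls_fit(data, ["age"], cov)
        x = np.column_stack([np.ones(12), data["age"].to_numpy()])
        mean = x @ fit.params.to_numpy()
        sigma = fit.sigma2_ml * (cov.matrix / cov.depth)
        expected = multivariate_normal.logpdf(data["avg_divergence"].to_numpy(), mean, sigma)
        assert fit.loglik == pytest.approx(expected, abs=1e-9)

    def test_loglik_invariant_to_covariance_scale(self, rng):
        data = random_dataset(rng, n=15)
        cov = random_psd_cov(rng, data["clade"])
        big = CovarianceSpec(cov.labels, cov.matrix * 10.0, cov.meta)
        f1 = pgls_fit(data, ["age"], cov)
        f2 = pgls_fit(data, ["age"], big)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-9)
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-12)

    def test_refit_reproduces_loglik(self, rng):
        data = random_dataset(rng)
        cov = random_psd_cov(rng, data["clade"])
        assert pgls_fit(data, ["age"], cov).loglik == pytest.approx(
            pgls_fit(data, ["age"], cov).loglik, abs=1e-12
        )

    def test_categorical_reference_level_changes_coefs_not_f(self, rng):
        data = random_dataset(rng, n=18)
        data["eco"] = rng.permutation(["a-type"] * 6 + ["b-type"] * 6 + ["c-type"] * 6)
        cov = identity_cov(data["clade"])
        fit1 = pgls_fit(data, ["age", "eco"], cov)
        data2 = data.copy()
        data2["eco"] = data2["eco"].replace({"a-type": "z-type"})  # new reference level
        fit2 = pgls_fit(data2, ["age", "eco"], cov)
        assert not np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy())
        assert np.allclose(fit1.anova["F"].to_numpy(), fit2.anova["F"].to_numpy(), atol=1e-9)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-9)

    def test_collinear_terms_rejected(self, rng):
        data = random_dataset(rng)
        data["age2"] = 2.0 * data["age"]
        with pytest.raises(ValueError, match="singular|collinear"):
            pgls_fit(data, ["age", "age2"], identity_cov(data["clade"]))

    def test_too_few_rows_rejected(self, rng):
        data = random_dataset(rng, n=3)
        with pytest.raises(ValueError):
            pgls_fit(data, ["age", "avg_geodist", "env_het"], identity_cov(data["clade"]))


class TestLrt:
    def test_identical_models(self, rng):
        data = random_dataset(rng)
        cov = identity_cov(data["clade"])
        fit = pgls_fit(data, ["age"], cov)
        res = lrt(fit, fit)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_chi_square_quantile_identity(self):
        assert stats.chi2.sf(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_statistic_matches_recomputed_logliks(self, rng):
        data = random_dataset(rng)
        cov = random_psd_cov(rng, data["clade"])
        full = pgls_fit(data, ["age", "avg_geodist", "env_het"], cov)
        red = pgls_fit(data, ["age"], cov)
        res = lrt(full, red)
        assert res.statistic == pytest.approx(2.0 * (full.loglik - red.loglik), abs=1e-12)
        assert res.df == 2
        assert res.statistic >= 0.0
        assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 2), abs=1e-12)

    def test_dropping_terms_never_increases_loglik(self, rng):
        for _ in range(5):
            data = random_dataset(rng)
            cov = random_psd_cov(rng, data["clade"])
            full = pgls_fit(data, ["age", "avg_geodist", "env_het"], cov)
            for drop in ["age", "avg_geodist", "env_het"]:
                red = pgls_fit(data, [t for t in full.terms if t != drop], cov)
                assert red.loglik <= full.loglik + 1e-8

    def test_non_nested_rejected(self, rng):
        data = random_dataset(rng)
        cov = identity_cov(data["clade"])
        f1 = pgls_fit(data, ["age"], cov)
        f2 = pgls_fit(data, ["env_het"], cov)
        with pytest.raises(ValueError, match="nested"):
            lrt(f1, f2)


class TestBackwardStepwise:
    def test_strong_effects_keep_full_model(self, rng):
        data = random_dataset(rng, n=24)
        data["avg_divergence"] = (
            0.002 * data["age"] + 0.0001 * data["avg_geodist"] + rng.normal(0, 1e-4, 24)
        )
        cov = identity_cov(data["clade"])
        res = backward_stepwise(data, ["age", "avg_geodist"], cov)
        assert res.final.terms == ("age", "avg_geodist")
        assert res.trace.empty

    def test_pure_noise_terms_eliminated(self, rng):
        data = random_dataset(rng, n=24)
        data["avg_divergence"] = rng.normal(0, 1.0, 24)
        res = backward_stepwise(
            data, ["age", "avg_geodist", "env_het"], identity_cov(data["clade"])
        )
        # with this fixed seed all three null terms fall out
        assert res.final.terms == ()
        assert list(res.trace["rule"].unique()) == ["lrt"]

    def test_interactions_dropped_before_main_effects(self, rng):
        data = random_dataset(rng, n=24)
        data["avg_divergence"] = 0.002 * data["age"] + rng.normal(0, 5e-4, 24)
        res = backward_stepwise(
            data, ["age", "avg_geodist", "age:avg_geodist"], identity_cov(data["clade"])
        )
        dropped = list(res.trace["term"])
        if "age:avg_geodist" in dropped and "avg_geodist" in dropped:
            assert dropped.index("age:avg_geodist") < dropped.index("avg_geodist")
        assert "age" in res.final.terms

    def test_interaction_main_effect_rule(self, rng):
        """A main effect held only by a retained interaction is dropped unless
        it was significant in the full model."""
        n = 40
        clades = [f"c{i:02d}" for i in range(n)]
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        data = pd.DataFrame(
            {
                "clade": clades,
                "avg_divergence": 2.0 * a * b + rng.normal(0, 0.1, n),
                "a": a,
                "b": b,
            }
        )
        res = backward_stepwise(data, ["a", "b", "a:b"], identity_cov(clades))
        assert "a:b" in res.final.terms
        rules = set(res.trace["rule"])
        # pure-interaction signal: both mains were null in the full model
        assert "not-significant-in-full-model" in rules
        assert "a" not in res.final.terms and "b" not in res.final.terms


class TestCorrelation:
    def test_range_size_worked_example(self):
        """Printed r = 0.8509 (df 24) reproduces t ≈ 7.94, p ≈ 3.6e-8.

        The source prints t = 7.9375; the closed form from the 4-d.p. r gives
        7.9351, so agreement is asserted at the precision the rounded r
        supports.
        """
        res = correlation_test(0.8509, 24)
        assert res.t == pytest.approx(7.9375, abs=0.005)
        assert res.p == pytest.approx(3.625e-8, rel=0.05)

    def test_age_range_worked_example(self):
        res = correlation_test(0.0428, 24)
        assert res.t == pytest.approx(0.210, abs=5e-4)
        assert res.p == pytest.approx(0.8356, abs=5e-4)

    def test_zero_correlation(self):
        res = correlation_test(0.0, 24)
        assert res.t == 0.0 and res.p == 1.0

    def test_perfect_correlation_convention(self):
        res = correlation_test(1.0, 10)
        assert np.isinf(res.t) and res.p == 0.0

    def test_t_identity(self, rng):
        for r in rng.uniform(-0.95, 0.95, 10):
            for df in (3, 24, 100):
                res = correlation_test(r, df)
                assert res.t == pytest.approx(r * np.sqrt(df) / np.sqrt(1 - r * r), abs=1e-9)

    def test_from_data_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = pearson_correlation(x, y)
        r_sp, p_sp = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp, abs=1e-12)
        assert res.p == pytest.approx(p_sp, abs=1e-12)
        assert res.df == 28
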