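"""Brownian-motion comparative statistics against independent oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats

from earmorph import phylo
from earmorph.io_formats import parse_newick
from earmorph.synthetic import simulate_tree


def star_tree(n=8, depth=2.0):
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return parse_newick(f"({tips});")


def brute_force_covariance(phy):
    """Independent oracle: shared path length via explicit root-to-tip
    edge path enumeration, no MRCA logic shared with the implementation."""
    paths = {}
    for leaf in phy.tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(edges))
    species = phy.tip_labels
    n = len(species)
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            shared = 0.0
            for (ia, la), (ib, lb) in zip(paths[a], paths[b]):
                if ia != ib:
                    break
                shared += la
            C[i, j] = shared
    return C


class TestBMCovariance:
    def test_three_tip_example(self):
        phy = parse_newick("((A:1,B:1):1,C:2);")
        cov = phylo.bm_covariance(phy)
        assert cov.species == ["A", "B", "C"]
        np.testing.assert_allclose(
            cov.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_diagonal(self):
        cov = phylo.bm_covariance(star_tree(6, depth=3.0))
        np.testing.assert_allclose(cov.matrix, 3.0 * np.eye(6))

    def test_random_tree_matches_path_oracle(self):
        phy = simulate_tree(12, seed=7)
        np.testing.assert_allclose(
            phylo.bm_covariance(phy).matrix, brute_force_covariance(phy),
            rtol=1e-12)


class TestSimulateBM:
    def test_zero_rate(self, balanced_tree):
        X = phylo.simulate_bm(balanced_tree, rate=0.0, root_state=3.0,
                              seed=1, n_reps=5)
        np.testing.assert_array_equal(X, 3.0)

    def test_monte_carlo_covariance(self, balanced_tree):
        n = 10_000
        X = phylo.simulate_bm(balanced_tree, rate=1.5, seed=2, n_reps=n)
        emp = np.cov(X)
        C = 1.5 * phylo.bm_covariance(balanced_tree).matrix
        # s.e. of a covariance entry is ~ sqrt((c_ii c_jj + c_ij^2)/n)
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n)
        assert np.all(np.abs(emp - C) < 3.5 * se)

    def test_monte_carlo_mean(self, balanced_tree):
        X = phylo.simulate_bm(balanced_tree, rate=1.0, root_state=-2.0,
                              seed=3, n_reps=10_000)
        sd = np.sqrt(np.diag(phylo.bm_covariance(balanced_tree).matrix))
        assert np.all(np.abs(X.mean(axis=1) + 2.0) < 4 * sd / 100)

    def test_deterministic_per_seed(self, balanced_tree):
        a = phylo.simulate_bm(balanced_tree, seed=9, n_reps=3)
        b = phylo.simulate_bm(balanced_tree, seed=9, n_reps=3)
        np.testing.assert_array_equal(a, b)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        rng = np.random.default_rng(0)
        phy = star_tree(20, depth=1.0)
        x = rng.normal(size=20)
        y = 1.0 + 2.0 * x + rng.normal(size=20)
        C = phylo.bm_covariance(phy).matrix
        fit = phylo.pgls_fit(y, x, C)
        res = scipy.stats.linregress(x, y)
        assert fit.coef[1] == pytest.approx(res.slope, rel=1e-10)
        assert fit.coef[0] == pytest.approx(res.intercept, rel=1e-10)
        assert fit.r2 == pytest.approx(res.rvalue**2, rel=1e-10)
        assert fit.p_t[1] == pytest.approx(res.pvalue, rel=1e-8)

    def test_whitening_oracle_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        phy = simulate_tree(12, seed=3)
        C = phylo.bm_covariance(phy).matrix
        x = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        fit = phylo.pgls_fit(y, x, C)
        gls = sm.GLS(y, sm.add_constant(x), sigma=C).fit()
        np.testing.assert_allclose(fit.coef, gls.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, gls.bse, atol=1e-10)
        np.testing.assert_allclose(fit.p_t, gls.pvalues, atol=1e-10)

    def test_slope_recovery(self, tree33):
        C = phylo.bm_covariance(tree33).matrix
        x = phylo.simulate_bm(tree33, rate=1.0, seed=5, n_reps=1)[:, 0]
        noise = phylo.simulate_bm(tree33, rate=0.5, seed=6, n_reps=200)
        betas = [phylo.pgls_fit(2.0 * x + noise[:, r], x, C).coef[1]
                 for r in range(200)]
        assert np.mean(betas) == pytest.approx(2.0, rel=0.05)

    def test_singular_design_rejected(self):
        phy = star_tree(10)
        C = phylo.bm_covariance(phy).matrix
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="singular"):
            phylo.pgls_fit(np.ones(10), np.column_stack([x, 2 * x]), C)


class TestBlombergK:
    def test_star_tree_k_is_one(self):
        rng = np.random.default_rng(4)
        phy = star_tree(9, depth=2.5)
        for _ in range(3):
            x = rng.normal(size=9) * rng.uniform(0.5, 10)
            assert phylo.k_statistic(x, phy) == pytest.approx(1.0, abs=1e-12)

    def test_mean_k_near_one_under_bm(self, tree33):
        X = phylo.simulate_bm(tree33, rate=1.0, seed=8, n_reps=500)
        ks = np.array([phylo.k_statistic(X[:, r], tree33) for r in range(500)])
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 3 * se

    def test_clade_indicator_exceeds_one(self):
        phy = parse_newick("((A:0.1,B:0.1):1.9,(C:0.1,D:0.1):1.9);")
        x = np.array([1.0, 1.0, -1.0, -1.0])  # deep two-clade contrast
        assert phylo.k_statistic(x, phy) > 1.0

    def test_permutation_p_detects_signal(self):
        phy = parse_newick(
            "(((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4):1.5,"
            "((E:0.1,F:0.1):0.4,(G:0.1,H:0.1):0.4):1.5);")
        x = np.array([1.0, 1.1, 0.9, 1.2, -1.0, -1.1, -0.9, -1.2])
        res = phylo.blomberg_k(x, phy, n_perm=199, seed=0)
        assert res.statistic > 1.0
        assert res.p <= 0.05

    def test_permutation_p_uniform_under_shuffled_traits(self):
        # under random trait assignment the permutation p-value is uniform
        phy = simulate_tree(12, seed=13)
        rng = np.random.default_rng(14)
        ps = [phylo.blomberg_k(rng.normal(size=12), phy, n_perm=99,
                               seed=int(rng.integers(2**31))).p
              for _ in range(250)]
        stat = scipy.stats.kstest(ps, "uniform").statistic
        # discrete p grid of 100 values adds ~0.01 to the KS distance
        assert stat < scipy.stats.ksone.ppf(0.99, 250) + 0.01


class TestKmult:
    def test_single_column_equals_k(self, tree33):
        x = phylo.simulate_bm(tree33, seed=10, n_reps=1)[:, 0]
        k1 = phylo.blomberg_k(x, tree33, n_perm=99, seed=1).statistic
        km = phylo.kmult(x.reshape(-1, 1), tree33, n_perm=99, seed=1).statistic
        assert km == pytest.approx(k1, rel=1e-12)

    def test_duplicated_column_invariant(self, tree33):
        x = phylo.simulate_bm(tree33, seed=11, n_reps=1)[:, 0]
        km1 = phylo.k_statistic(x.reshape(-1, 1), tree33)
        km2 = phylo.k_statistic(np.column_stack([x, x]), tree33)
        assert km2 == pytest.approx(km1, rel=1e-12)

    def test_mean_near_one_under_bm(self, tree33):
        rng = np.random.default_rng(12)
        ks = []
        for r in range(200):
            X = phylo.simulate_bm(tree33, rate=1.0, seed=2000 + r, n_reps=3)
            ks.append(phylo.k_statistic(X, tree33))
        ks = np.array(ks)
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 4 * se


class TestAncestralStates:
    def test_two_tips_root_is_mean(self):
        phy = parse_newick("(A:1,B:1);")
        est, var, _ = phylo.ancestral_states(np.array([2.0, 6.0]), phy)
        assert est[0] == pytest.approx(4.0, abs=1e-12)

    def test_constant_trait(self, balanced_tree):
        est, var, _ = phylo.ancestral_states(np.full(4, 7.0), balanced_tree)
        for v in est.values():
            assert v == pytest.approx(7.0, abs=1e-10)

    def test_root_equals_gls_mean(self, tree33):
        x = phylo.simulate_bm(tree33, seed=15, n_reps=1)[:, 0]
        C = phylo.bm_covariance(tree33).matrix
        Cinv = np.linalg.inv(C)
        est, _, _ = phylo.ancestral_states(x, tree33)
        assert est[0] == pytest.approx(phylo.gls_mean(x, Cinv), abs=1e-10)

    def test_gaussian_conditioning_oracle(self):
        # explicit joint tip+node covariance, conditioned by linear algebra
        phy = parse_newick(
            "(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,(E:2,F:2):1);")
        x = np.array([1.0, 1.4, -0.2, 0.1, 2.2, 2.0])
        est, _, _ = phylo.ancestral_states(x, phy)
        depths = {}
        chains = {}
        for node in phy.tree.preorder_node_iter():
            depths[id(node)] = (0.0 if node.parent_node is None
                                else depths[id(node.parent_node)] + node.edge.length)
            chain = []
            nn = node
            while nn is not None:
                chain.append(id(nn))
                nn = nn.parent_node
            chains[id(node)] = set(chain)

        def shared(a, b):
            common = chains[id(a)] & chains[id(b)]
            return max(depths[c] for c in common)

        leaves = sorted(phy.tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        internal = [nd for nd in phy.tree.preorder_node_iter() if not nd.is_leaf()]
        Ctt = np.array([[shared(a, b) for b in leaves] for a in leaves])
        Cit = np.array([[shared(nd, b) for b in leaves] for nd in internal])
        one = np.ones(6)
        Cinv = np.linalg.inv(Ctt)
        a_hat = one @ Cinv @ x / (one @ Cinv @ one)
        expected = a_hat + Cit @ Cinv @ (x - a_hat)
        got = np.array([est[i] for i in range(len(internal))])
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        u, p = phylo.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        u, p = phylo.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_symmetry(self):
        a, b = [1.0, 3, 5, 7], [2.0, 4, 6]
        _, p1 = phylo.mann_whitney_u(a, b)
        _, p2 = phylo.mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(20)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=6) + 0.5
            u, p = phylo.mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="exact")
            assert u == ref.statistic
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_samples_normal_approximation(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=30)
        b = rng.normal(size=25) + 0.8
        _, p = phylo.mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-10)
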