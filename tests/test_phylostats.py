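"""Brownian covariance, phylogenetic t-test / PGLS, simulation ANOVA."""

import numpy as np
import pytest

from plastevol.molevol import BranchTree
from plastevol.phylostats import (
    brownian_vcv,
    gls_fit,
    holm,
    pgls,
    phylo_anova,
    phylo_ttest,
)
from plastevol.synthetic_data import simulate_brownian_traits


class TestBrownianVCV:
    def test_star_tree_is_diagonal(self):
        tree = BranchTree.from_newick("(a:2,b:2,c:2,d:2);")
        C, labels = brownian_vcv(tree)
        assert np.allclose(C, 2.0 * np.eye(4))

    def test_sisters_share_stem_depth(self):
        tree = BranchTree.from_newick("((a:1,b:1):3,c:4);")
        C, labels = brownian_vcv(tree)
        i, j = labels.index("a"), labels.index("b")
        assert C[i, j] == pytest.approx(3.0)
        assert C[i, i] == pytest.approx(4.0)
        assert C[i, labels.index("c")] == pytest.approx(0.0)

    def test_positive_semidefinite_on_random_trees(self):
        import random

        import dendropy

        rng = random.Random(0)
        for rep in range(30):
            n = rng.randint(4, 15)
            tns = dendropy.TaxonNamespace([f"x{i}" for i in range(n)])
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=n, rng=rng,
            )
            C, _ = brownian_vcv(BranchTree.from_dendropy(t))
            assert np.linalg.eigvalsh(C).min() > -1e-9

    def test_zero_depth_rejected(self):
        tree = BranchTree.from_newick("(a:0,b:0);")
        with pytest.raises(ValueError, match="zero-depth"):
            brownian_vcv(tree)


class TestPhyloTTest:
    TREE = BranchTree.from_newick("((a:1,b:1):1,c:2);")

    def test_constant_trait_gives_p_one(self):
        r = phylo_ttest({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 0, "b": 0, "c": 1}, self.TREE)
        assert r.estimates["difference"] == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        # solve the GLS normal equations explicitly with numpy linear algebra
        y = np.array([2.0, 1.0, 4.0])
        g = np.array([0.0, 0.0, 1.0])
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        X = np.column_stack([np.ones(3), g])
        Ci = np.linalg.inv(C)
        beta_hand = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        resid = y - X @ beta_hand
        sigma2 = resid @ Ci @ resid / 1
        se_hand = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ Ci @ X)))
        r = phylo_ttest(
            {"a": 2.0, "b": 1.0, "c": 4.0}, {"a": 0, "b": 0, "c": 1}, self.TREE, ridge=0
        )
        assert r.estimates["difference"] == pytest.approx(beta_hand[1], rel=1e-10)
        t_hand = beta_hand[1] / se_hand[1]
        assert r.statistic == pytest.approx(t_hand, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty|groups"):
            phylo_ttest({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 0, "b": 0, "c": 0}, self.TREE)

    def test_type_i_calibration(self, balanced_22_tree):
        C, labels = brownian_vcv(balanced_22_tree)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
        groups = {t: (0 if i < 11 else 1) for i, t in enumerate(labels)}
        rng = np.random.default_rng(0)
        rej = 0
        n = 500
        for _ in range(n):
            y = L @ rng.standard_normal(len(labels))
            if phylo_ttest(dict(zip(labels, y)), groups, balanced_22_tree).p < 0.05:
                rej += 1
        assert rej / n == pytest.approx(0.05, abs=0.02)


class TestPGLS:
    def test_exact_linear_relation(self):
        tree = BranchTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        y = {k: 2 * v for k, v in x.items()}
        r = pgls(y, x, tree, ridge=0)
        assert r.estimates["slope"] == pytest.approx(2.0, rel=1e-8)
        assert r.p < 1e-6

    def test_star_tree_equals_ols(self):
        tree = BranchTree.from_newick("(a:1,b:1,c:1,d:1,e:1);")
        x = np.array([0.1, 0.9, 0.4, 1.2, 0.8])
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.2])
        labels = ["a", "b", "c", "d", "e"]
        r = pgls(dict(zip(labels, y)), dict(zip(labels, x)), tree, ridge=0)
        slope_ols, inter_ols = np.polyfit(x, y, 1)
        assert abs(r.estimates["slope"] - slope_ols) < 1e-10
        assert abs(r.estimates["intercept"] - inter_ols) < 1e-10

    def test_constant_predictor_rejected(self):
        tree = BranchTree.from_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="constant"):
            pgls({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 5.0, "b": 5.0, "c": 5.0}, tree)

    def test_type_i_calibration(self, balanced_22_tree):
        C, labels = brownian_vcv(balanced_22_tree)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
        rng = np.random.default_rng(1)
        rej = 0
        n = 500
        for _ in range(n):
            y = L @ rng.standard_normal(len(labels))
            x = L @ rng.standard_normal(len(labels))
            if pgls(dict(zip(labels, y)), dict(zip(labels, x)), balanced_22_tree).p < 0.05:
                rej += 1
        assert rej / n == pytest.approx(0.05, abs=0.02)


class TestHolm:
    def test_monotone_and_bounded(self):
        raw = [0.01, 0.04, 0.03, 0.5]
        adj = holm(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(a <= 1.0 for a in adj)
        # step-down ordering preserved
        order = np.argsort(raw)
        assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(3))


class TestPhyloANOVA:
    def test_reproducible_and_order_invariant(self, balanced_22_tree):
        C, labels = brownian_vcv(balanced_22_tree)
        rng = np.random.default_rng(5)
        y = dict(zip(labels, rng.standard_normal(len(labels))))
        groups = {t: ("A" if i < 8 else ("B" if i < 15 else "C")) for i, t in enumerate(labels)}
        r1 = phylo_anova(y, groups, balanced_22_tree, n_sim=500, seed=9)
        r2 = phylo_anova(y, groups, balanced_22_tree, n_sim=500, seed=9)
        assert r1.p == r2.p
        assert r1.posthoc.equals(r2.posthoc)

    def test_two_group_sign_agrees_with_ttest(self, balanced_22_tree):
        C, labels = brownian_vcv(balanced_22_tree)
        groups = {t: ("A" if i < 11 else "B") for i, t in enumerate(labels)}
        dummy = {t: (0 if g == "A" else 1) for t, g in groups.items()}
        rng = np.random.default_rng(6)
        for rep in range(5):
            y = dict(zip(labels, rng.standard_normal(len(labels))))
            ra = phylo_anova(y, groups, balanced_22_tree, n_sim=500, seed=rep)
            rt = phylo_ttest(y, dummy, balanced_22_tree)
            diff_anova = ra.estimates["mean_B"] - ra.estimates["mean_A"]
            # same direction of group difference
            assert np.sign(diff_anova) == np.sign(rt.estimates["difference"]) or diff_anova == 0

    def test_planted_shift_detected(self, balanced_22_tree):
        C, labels = brownian_vcv(balanced_22_tree)
        groups = {t: ("A" if i < 8 else ("B" if i < 15 else "C")) for i, t in enumerate(labels)}
        scale = float(np.sqrt(np.mean(np.diag(C))))
        df = simulate_brownian_traits(
            balanced_22_tree, 1.0, groups,
            group_shifts={"trait": {"A": 10 * scale}}, seed=2,
        )
        r = phylo_anova(df["trait"].to_dict(), groups, balanced_22_tree, n_sim=1000, seed=3)
        assert r.p < 0.01

    def test_constant_trait_rejected(self, balanced_22_tree):
        _, labels = brownian_vcv(balanced_22_tree)
        groups = {t: ("A" if i < 11 else "B") for i, t in enumerate(labels)}
        with pytest.raises(ValueError, match="F undefined|variance"):
            phylo_anova({t: 1.0 for t in labels}, groups, balanced_22_tree, n_sim=500)

    def test_posthoc_symmetric_and_corrected(self, balanced_22_tree):
        _, labels = brownian_vcv(balanced_22_tree)
        rng = np.random.default_rng(8)
        y = dict(zip(labels, rng.standard_normal(len(labels))))
        groups = {t: ("A" if i < 8 else ("B" if i < 15 else "C")) for i, t in enumerate(labels)}
        holm_r = phylo_anova(y, groups, balanced_22_tree, n_sim=500, seed=1, correction="holm")
        bonf_r = phylo_anova(y, groups, balanced_22_tree, n_sim=500, seed=1, correction="bonferroni")
        P = holm_r.posthoc.to_numpy()
        assert np.allclose(P, P.T, equal_nan=True)
        # Holm is uniformly no larger than Bonferroni
        assert (holm_r.posthoc.to_numpy() <= bonf_r.posthoc.to_numpy() + 1e-12).all()


class TestGLSFit:
    def test_weighted_solution_matches_direct_inverse(self):
        rng = np.random.default_rng(3)
        n = 10
        A = rng.standard_normal((n, n))
        C = A @ A.T + n * np.eye(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        beta, se, s2, df = gls_fit(X, y, C)
        Ci = np.linalg.inv(C)
        beta_direct = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert np.allclose(beta, beta_direct, rtol=1e-10)
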