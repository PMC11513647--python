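import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylodem.phylo import (
    bm_covariance,
    bonferroni_adjust,
    compact_letters,
    fit_pagel_lambda,
    grafen_lengths,
    holm_adjust,
    pagel_transform,
    pgls_residuals,
    phylo_anova,
    ppca,
    spearman_prune,
)
from phylodem.synthetic import simulate_bm_trait, simulate_sociality, simulate_tree


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestBMCovariance:
    def test_independent_tips(self):
        C, labels = bm_covariance(newick("(a:1,b:1);"))
        np.testing.assert_allclose(C, np.eye(2))

    def test_shared_path_lengths(self):
        C, labels = bm_covariance(newick("((a:1,b:1):1,c:2);"))
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["a"], i["b"]] == pytest.approx(1.0)
        assert C[i["a"], i["c"]] == 0.0
        np.testing.assert_allclose(np.diag(C), 2.0)

    def test_star_tree_diagonal(self):
        C, _ = bm_covariance(newick("(a:1,b:1,c:1,d:1);"))
        np.testing.assert_allclose(C, np.eye(4))

    def test_grafen_fallback_for_bare_topology(self):
        C, labels = bm_covariance(newick("((a,b),c);"))
        assert np.all(np.diag(C) == pytest.approx(1.0))
        i = {lab: k for k, lab in enumerate(labels)}
        assert 0 < C[i["a"], i["b"]] < 1

    def test_pagel_transform_limits(self):
        C, _ = bm_covariance(newick("((a:1,b:1):1,c:2);"))
        np.testing.assert_array_equal(pagel_transform(C, 1.0), C)
        np.testing.assert_array_equal(pagel_transform(C, 0.0), np.diag(np.diag(C)))
        half = pagel_transform(C, 0.5)
        assert half[0, 1] == pytest.approx(C[0, 1] / 2)
        with pytest.raises(ValueError):
            pagel_transform(C, 1.2)


class TestPagelFit:
    def test_lambda_zero_reproduces_ols(self):
        rng = np.random.default_rng(0)
        tree = simulate_tree(40, seed=1)
        C, labels = bm_covariance(tree)
        y = rng.normal(size=40)
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x])
        fit = fit_pagel_lambda(y, X, np.eye(40) * np.diag(C), ci=False)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_bm_signal_recovered(self):
        # median estimate near 1 when traits evolve by pure BM
        tree = simulate_tree(150, seed=3)
        C, labels = bm_covariance(tree)
        X = np.ones((150, 1))
        ests = []
        for s in range(30):
            y = simulate_bm_trait(tree, 1.0, 1.0, seed=s).loc[labels].to_numpy()
            ests.append(fit_pagel_lambda(y, X, C, ci=False).lambda_hat)
        assert abs(np.median(ests) - 1.0) < 0.05

    def test_iid_noise_estimates_near_zero(self):
        tree = simulate_tree(150, seed=4)
        C, labels = bm_covariance(tree)
        X = np.ones((150, 1))
        rng = np.random.default_rng(8)
        ests = [
            fit_pagel_lambda(rng.normal(size=150), X, C, ci=False).lambda_hat
            for _ in range(30)
        ]
        assert np.median(ests) < 0.1

    def test_profile_ci_brackets_estimate(self):
        tree = simulate_tree(80, seed=5)
        C, labels = bm_covariance(tree)
        y = simulate_bm_trait(tree, 1.0, 0.7, seed=9).loc[labels].to_numpy()
        fit = fit_pagel_lambda(y, np.ones((80, 1)), C)
        lo, hi = fit.lambda_ci
        assert 0.0 <= lo <= fit.lambda_hat <= hi <= 1.0

    def test_ci_coverage_under_bm(self):
        # profile CIs should cover the true lambda about 95% of the time
        tree = simulate_tree(100, seed=6)
        C, labels = bm_covariance(tree)
        X = np.ones((100, 1))
        true = 0.8
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            y = simulate_bm_trait(tree, 1.0, true, seed=1000 + s).loc[labels].to_numpy()
            lo, hi = fit_pagel_lambda(y, X, C).lambda_ci
            hits += lo <= true <= hi
        lo_ok, hi_ok = stats.binom.interval(0.999, n_rep, 0.95)
        assert lo_ok <= hits  # not anti-conservative beyond noise


class TestPGLSResiduals:
    def test_exact_linear_trait_gives_zero_residuals(self):
        tree = simulate_tree(30, seed=7)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        mass = pd.Series(np.linspace(1, 5, 30), index=labels)
        trait = 2.0 + 0.25 * mass
        resid, fit = pgls_residuals(trait, mass, tree)
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-8)
        assert fit.beta[1] == pytest.approx(0.25)

    def test_missing_species_dropped(self):
        tree = simulate_tree(30, seed=7)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        mass = pd.Series(np.linspace(1, 5, 30), index=labels)
        trait = 2.0 + 0.25 * mass
        trait.iloc[:5] = np.nan
        resid, _ = pgls_residuals(trait, mass, tree)
        assert len(resid) == 25

    def test_allometric_slope_unbiased(self):
        # mean slope over replicates within 2 standard errors of the mean
        tree = simulate_tree(150, seed=8)
        mass = simulate_bm_trait(tree, 4.0, 1.0, seed=11, mean=5.0)
        slopes, ses = [], []
        for s in range(12):
            noise = simulate_bm_trait(tree, 0.25, 1.0, seed=100 + s)
            trait = 1.0 + 0.25 * mass + noise
            _, fit = pgls_residuals(trait, mass, tree)
            slopes.append(fit.beta[1])
            ses.append(fit.se_beta[1])
        sem = np.mean(ses) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.25) < 2 * sem


class TestPhyloANOVA:
    def test_star_tree_matches_classical_f_test(self):
        tree = newick("(" + ",".join(f"t{i}:1" for i in range(60)) + ");")
        rng = np.random.default_rng(13)
        labels = [f"t{i}" for i in range(60)]
        y = pd.Series(rng.normal(size=60), index=labels)
        g = pd.Series(np.repeat(list("ABC"), 20), index=labels)
        res = phylo_anova(y, g, tree, nsim=4000, seed=14)
        F, p_classical = stats.f_oneway(*[y[g == k] for k in "ABC"])
        assert res.F_obs == pytest.approx(float(F), rel=1e-9)
        assert res.p_phylo == pytest.approx(p_classical, abs=0.03)

    def test_extreme_shift_detected(self):
        tree = simulate_tree(60, seed=15)
        soc = simulate_sociality(tree, signal=0.8, seed=16)
        y = simulate_bm_trait(tree, 1.0, 1.0, seed=17) + 10.0 * (soc == 4)
        res = phylo_anova(y, soc.astype(str), tree, nsim=400, seed=18)
        assert res.p_phylo <= 2 / 401
        # the shifted group gets its own letter
        social_letters = set(res.letters["4"])
        others = set("".join(v for k, v in res.letters.items() if k != "4"))
        assert social_letters.isdisjoint(others)

    def test_group_count_validation(self):
        tree = simulate_tree(10, seed=19)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        y = pd.Series(np.arange(10.0), index=labels)
        g = pd.Series(["only"] * 10, index=labels)
        with pytest.raises(ValueError, match="two non-empty groups"):
            phylo_anova(y, g, tree, nsim=100, seed=1)


class TestAdjustmentsAndLetters:
    def test_bonferroni_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.04]), [0.02, 0.08])
        np.testing.assert_allclose(bonferroni_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bonferroni_adjust([0.9], m=5), [1.0])

    def test_holm_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=10)
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_letters_partition(self):
        # groups 0,1 alike; 2,3 alike; the pairs differ from each other
        diff = np.array(
            [
                [False, False, True, True],
                [False, False, True, True],
                [True, True, False, False],
                [True, True, False, False],
            ]
        )
        letters = compact_letters(diff, ["g0", "g1", "g2", "g3"])
        assert letters["g0"] == letters["g1"]
        assert letters["g2"] == letters["g3"]
        assert set(letters["g0"]).isdisjoint(letters["g2"])

    def test_letters_chain_overlap(self):
        # 0 != 2 but 1 overlaps both: middle group shares letters
        diff = np.array(
            [
                [False, False, True],
                [False, False, False],
                [True, False, False],
            ]
        )
        letters = compact_letters(diff, ["lo", "mid", "hi"])
        assert set(letters["lo"]) & set(letters["mid"])
        assert set(letters["mid"]) & set(letters["hi"])
        assert set(letters["lo"]).isdisjoint(letters["hi"])


class TestPPCA:
    def test_star_tree_reduces_to_ordinary_pca(self):
        tree = newick("(" + ",".join(f"t{i}:1" for i in range(50)) + ");")
        rng = np.random.default_rng(23)
        X = pd.DataFrame(
            rng.normal(size=(50, 4)),
            index=[f"t{i}" for i in range(50)],
            columns=list("abcd"),
        )
        X = (X - X.mean()) / X.std(ddof=1)
        res = ppca(X, tree)
        Xc = X - X.mean()
        evals, evecs = np.linalg.eigh(np.cov(Xc.T))
        evals = evals[::-1]
        np.testing.assert_allclose(res.eigenvalues, evals, atol=1e-6)
        for j in range(4):
            dot = abs(res.loadings.iloc[:, j] @ evecs[:, ::-1][:, j])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_pct_variance_sums_to_100(self, small_study):
        tree = simulate_tree(40, seed=24)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        X = pd.DataFrame(
            np.random.default_rng(1).normal(size=(40, 3)),
            index=labels,
            columns=list("xyz"),
        )
        res = ppca(X, tree)
        assert res.pct_variance.sum() == pytest.approx(100.0)

    def test_kaiser_retention_counts_large_eigenvalues(self):
        tree = simulate_tree(60, seed=25)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        rng = np.random.default_rng(26)
        base = rng.normal(size=60)
        X = pd.DataFrame(
            {
                "a": base + 0.1 * rng.normal(size=60),
                "b": base + 0.1 * rng.normal(size=60),
                "c": rng.normal(size=60),
                "d": rng.normal(size=60),
            },
            index=labels,
        )
        X = (X - X.mean()) / X.std(ddof=1)
        res = ppca(X, tree)
        assert res.retained_axes == int(np.sum(res.eigenvalues > 1.0))

    def test_scores_uncorrelated_in_phylogenetic_metric(self):
        tree = simulate_tree(50, seed=27)
        C, labels = bm_covariance(tree)
        X = pd.DataFrame(
            np.random.default_rng(28).normal(size=(50, 4)),
            index=labels,
            columns=list("abcd"),
        )
        res = ppca(X, tree)
        Cl = pagel_transform(C, res.lambda_hat)
        S = res.scores.loc[labels].to_numpy()
        M = S.T @ np.linalg.solve(Cl, S)
        off = np.abs(M - np.diag(np.diag(M))).max()
        assert off / np.abs(np.diag(M)).max() < 1e-8


class TestSpearmanPrune:
    @staticmethod
    def _table(rho_pairs, n=200, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        cols = {}
        for name, r in rho_pairs.items():
            cols[name] = r * base + np.sqrt(1 - r**2) * rng.normal(size=n)
        return pd.DataFrame(cols)

    def test_high_correlation_drops_one(self):
        df = self._table({"a": 0.99, "b": 0.98, "c": 0.0})
        kept, log = spearman_prune(df, threshold=0.70)
        assert "c" in kept and len(kept) == 2
        assert len(log) == 1 and abs(log[0][2]) > 0.7

    def test_moderate_correlation_keeps_both(self):
        df = self._table({"a": 0.6, "b": 0.0})
        kept, log = spearman_prune(df, threshold=0.70)
        assert kept == ["a", "b"] and not log

    def test_exact_threshold_keeps_both(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [1, 2, 4, 3]})
        rho = df.corr(method="spearman").loc["a", "b"]
        kept, _ = spearman_prune(df, threshold=float(rho))  # strict >
        assert kept == ["a", "b"]

    def test_row_order_invariant(self):
        df = self._table({"a": 0.95, "b": 0.94, "c": 0.2, "d": 0.9}, seed=3)
        kept1, _ = spearman_prune(df, 0.70)
        kept2, _ = spearman_prune(df.sample(frac=1.0, random_state=5), 0.70)
        assert kept1 == kept2

    def test_lower_missingness_wins(self):
        df = self._table({"a": 0.99, "b": 0.99}, seed=4)
        df.loc[:20, "a"] = np.nan
        kept, _ = spearman_prune(df, 0.70)
        assert kept == ["b"]
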