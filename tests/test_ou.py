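"""OU/BM covariance structure, regime weights, likelihoods, model comparison."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import phyloexpr as px
from phyloexpr.ou import (GeneFit, OUParams, RegimePainting, bm_covariance,
                          classify_selection, compare_models, de_by_regime,
                          de_gene_sets, fit_gene, fit_genes, msd_vs_distance,
                          ou_covariance, regime_weights)

TWO_TIP = "(A:1,B:1);"


@pytest.fixture(scope="module")
def two_tip():
    return px.Phylogeny.from_newick(TWO_TIP)


class TestCovariance:
    def test_two_tip_closed_forms(self, two_tip):
        alpha, sigma2 = 0.5, 1.0
        V = ou_covariance(two_tip, alpha, sigma2)
        # tips diverge at the root: variance sigma2/(2a)(1-e^{-2a}), cov 0
        vii = sigma2 / (2 * alpha) * (1 - np.exp(-2 * alpha))
        assert V.loc["A", "A"] == pytest.approx(vii)
        assert V.loc["A", "B"] == pytest.approx(0.0, abs=1e-15)
        B = bm_covariance(two_tip, sigma2)
        assert B.loc["A", "A"] == pytest.approx(1.0)
        assert B.loc["A", "B"] == pytest.approx(0.0)

    def test_nested_tree_entries(self, small_tree):
        # D and E share 1.7 of their 2.0 root paths
        alpha, sigma2 = 0.4, 0.8
        V = ou_covariance(small_tree, alpha, sigma2)
        ta = 1.7
        expect = (sigma2 / (2 * alpha) * np.exp(-2 * alpha * (2.0 - ta))
                  * (1 - np.exp(-2 * alpha * ta)))
        assert V.loc["D", "E"] == pytest.approx(expect, rel=1e-12)

    def test_bm_limit_of_ou(self, small_tree):
        V = ou_covariance(small_tree, 1e-12, 0.7)
        B = bm_covariance(small_tree, 0.7)
        assert np.abs(V.to_numpy() - B.to_numpy()).max() < 1e-9

    def test_stationary_root_variant(self, two_tip):
        V = ou_covariance(two_tip, 0.5, 1.0, stationary_root=True)
        assert V.loc["A", "A"] == pytest.approx(1.0)  # sigma2/(2 alpha)
        assert V.loc["A", "B"] == pytest.approx(np.exp(-2 * 0.5))

    def test_within_adds_to_diagonal_only(self, two_tip):
        w = pd.Series({"A": 0.3, "B": 0.1})
        V0 = ou_covariance(two_tip, 0.5, 1.0)
        V1 = ou_covariance(two_tip, 0.5, 1.0, within=w)
        assert V1.loc["A", "A"] - V0.loc["A", "A"] == pytest.approx(0.3)
        assert V1.loc["A", "B"] == V0.loc["A", "B"]

    def test_rejects_nonpositive_alpha(self, two_tip):
        with pytest.raises(ValueError):
            ou_covariance(two_tip, 0.0, 1.0)

    def test_euler_maruyama_path_oracle(self, small_tree):
        """Independent oracle: discretize the OU SDE along the tree
        (x += -a(x-theta)dt + sigma sqrt(dt) N) and compare the empirical tip
        covariance to the analytic matrix within Monte-Carlo error."""
        alpha, sigma2, theta = 0.8, 1.0, 0.0
        dt = 0.002
        n_rep = 4000
        rng = np.random.default_rng(2024)
        tips = small_tree.tip_labels
        tree = small_tree.dendropy_tree
        X = np.zeros((n_rep, len(tips)))

        state = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                state[node._pid] = np.full(n_rep, theta)
                continue
            x = state[node.parent_node._pid].copy()
            steps = int(round(node.edge.length / dt))
            for _ in range(steps):
                x += (-alpha * (x - theta) * dt
                      + np.sqrt(sigma2 * dt) * rng.standard_normal(n_rep))
            state[node._pid] = x
            if node.is_leaf():
                X[:, tips.index(node._pid)] = x

        emp = np.cov(X, rowvar=False, bias=True)
        V = ou_covariance(small_tree, alpha, sigma2).to_numpy()
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V ** 2) / n_rep)
        # allow an O(dt) discretization margin on top of sampling error
        assert (np.abs(emp - V) <= 3 * se + 5 * dt).all()


class TestRegimeWeights:
    def test_rows_sum_to_one(self, primate):
        painting = RegimePainting.focal_clade(primate, list(px.HOMINOIDS))
        for alpha in (1e-6, 0.01, 0.5, 10.0):
            W = regime_weights(primate, painting, alpha)
            assert np.allclose(W.sum(axis=1), 1.0)
            assert (W.to_numpy() >= -1e-12).all()

    def test_strong_selection_weights_are_indicators(self, primate):
        painting = RegimePainting.focal_clade(primate, list(px.HOMINOIDS))
        W = regime_weights(primate, painting, alpha=100.0 / primate.depth)
        for tip in primate.tip_labels:
            expect = 1.0 if tip in px.HOMINOIDS else 0.0
            assert W.loc[tip, "focal"] == pytest.approx(expect, abs=1e-3)

    def test_weak_selection_concentrates_on_root_regime(self, primate):
        painting = RegimePainting.focal_clade(primate, list(px.HOMINOIDS))
        W = regime_weights(primate, painting, alpha=1e-9)
        assert (W["background"] > 1 - 1e-6).all()

    def test_two_tip_focal_branch_weight(self, two_tip):
        """Single focal terminal edge of length 1 on a depth-1 tree:
        w_focal(A) = 1 - e^{-alpha}, exactly."""
        painting = RegimePainting.focal_clade(two_tip, ["A"])
        for alpha in (0.3, 1.0, 4.0):
            W = regime_weights(two_tip, painting, alpha)
            assert W.loc["A", "focal"] == pytest.approx(1 - np.exp(-alpha))
            assert W.loc["B", "focal"] == 0.0

    def test_focal_clade_validation(self, primate):
        with pytest.raises(ValueError, match="not in tree"):
            RegimePainting.focal_clade(primate, ["Martian"])
        with pytest.raises(ValueError, match="all tips"):
            RegimePainting.focal_clade(primate, primate.tip_labels)

    def test_incomplete_painting_rejected(self, two_tip):
        painting = RegimePainting({"A": "x"}, root_regime="x")
        with pytest.raises(ValueError, match="unpainted"):
            regime_weights(two_tip, painting, 1.0)


class TestLikelihood:
    def test_matches_scipy_mvn_logpdf(self, small_tree, rng):
        """The fitted lnL equals the explicit multivariate-normal log-density
        at the fitted parameters, for BM, OU1 and a regime model."""
        painting = RegimePainting.focal_clade(small_tree, ["D", "E"])
        x = pd.Series(rng.normal(5, 1, size=5), index=small_tree.tip_labels)
        for model, paint in [("BM", None), ("OU1", None),
                             ("OU-regime", painting)]:
            fit = fit_gene(small_tree, x, model, painting=paint)
            p = fit.params
            if model == "BM":
                mean = np.full(5, p.x0)
                V = bm_covariance(small_tree, p.sigma2).to_numpy()
            else:
                V = ou_covariance(small_tree, p.alpha, p.sigma2).to_numpy()
                if paint is None:
                    mean = np.full(5, p.theta["all"])
                else:
                    W = regime_weights(small_tree, paint, p.alpha)
                    th = np.array([p.theta[r] for r in W.columns])
                    mean = W.to_numpy() @ th
            oracle = sps.multivariate_normal(mean, V).logpdf(
                x.loc[small_tree.tip_labels].to_numpy())
            assert fit.lnL == pytest.approx(oracle, abs=1e-8)

    def test_bm_two_tip_closed_form(self, two_tip):
        """n=2 independent tips: x0-hat = mean, sigma2-hat = mean squared
        deviation, lnL from the scalar normal density."""
        x = pd.Series({"A": 1.0, "B": 3.0})
        with pytest.warns(UserWarning, match="fewer than 4"):
            fit = fit_gene(two_tip, x, "BM")
        assert fit.params.x0 == pytest.approx(2.0)
        assert fit.params.sigma2 == pytest.approx(1.0)  # mean of (±1)^2
        expect = sum(sps.norm(2.0, 1.0).logpdf(v) for v in (1.0, 3.0))
        assert fit.lnL == pytest.approx(expect, abs=1e-10)

    def test_ou1_never_below_bm(self, primate, rng):
        """Nesting: the OU1 maximum includes the alpha -> 0 boundary."""
        for _ in range(20):
            x = pd.Series(rng.normal(0, 1, len(primate)),
                          index=primate.tip_labels)
            bm = fit_gene(primate, x, "BM")
            ou = fit_gene(primate, x, "OU1")
            assert ou.lnL >= bm.lnL - 1e-6

    def test_bm_limit_alpha_near_zero(self, primate, rng):
        from phyloexpr.ou import GeneFitter
        fitter = GeneFitter(primate)
        for _ in range(20):
            x = rng.normal(2, 1, len(primate))
            lnL_bm = fitter.fit_bm(x).lnL
            lnL_near0, *_ = fitter.profile_lnL(1e-8 / primate.depth, x)
            assert abs(lnL_bm - lnL_near0) < 1e-5

    def test_constant_gene_is_degenerate(self, primate):
        x = pd.Series(4.0, index=primate.tip_labels)
        fit = fit_gene(primate, x, "BM")
        assert fit.degenerate

    def test_within_variance_lowers_certainty(self, primate, rng):
        x = pd.Series(rng.normal(0, 1, len(primate)), index=primate.tip_labels)
        w = pd.Series(0.5, index=primate.tip_labels)
        plain = fit_gene(primate, x, "BM")
        noisy = fit_gene(primate, x, "BM", within=w)
        assert noisy.params.sigma2 < plain.params.sigma2

    def test_small_tree_warns(self):
        t = px.Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        x = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.warns(UserWarning, match="fewer than 4"):
            fit_gene(t, x, "BM")


class TestModelComparison:
    @staticmethod
    def _fake(lnL, k=2, n=18):
        return GeneFit("BM", OUParams(0, 1, {"x0": 0.0}, 0.0), lnL, k, n)

    def test_equal_likelihoods_give_p_one(self):
        lam, p = compare_models(self._fake(-10.0), self._fake(-10.0), df=1)
        assert lam == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        lam, p = compare_models(self._fake(0.0), self._fake(3.841459 / 2), df=1)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_alt_below_null_is_contract_breach(self):
        with pytest.raises(RuntimeError, match="contract"):
            compare_models(self._fake(-1.0), self._fake(-2.0), df=1)

    def test_aic_bic_formulas(self):
        f = self._fake(-100.0, k=3, n=18)
        assert f.aic == pytest.approx(2 * 3 + 200.0)
        assert f.bic == pytest.approx(3 * np.log(18) + 200.0)

    def test_classify_all_null_genes_mostly_drift(self, primate):
        specs = [px.GeneSimSpec(f"g{i}", "BM", sigma2=0.2, x0=5.0)
                 for i in range(100)]
        _, truth = px.simulate_expression(primate, specs, 1, seed=21)
        bm = fit_genes(primate, truth.species_means, "BM")
        ou = fit_genes(primate, truth.species_means, "OU1")
        cls = classify_selection(bm, ou)
        assert cls.attrs["fraction_stabilizing"] <= 0.05

    def test_classify_detects_strong_ou_mixture(self, primate):
        alpha = 5.0 / primate.depth
        specs = ([px.GeneSimSpec(f"b{i}", "BM", sigma2=0.2, x0=5.0)
                  for i in range(50)]
                 + [px.GeneSimSpec(f"o{i}", "OU", sigma2=2 * alpha * 0.25,
                                   alpha=alpha, theta={"all": 5.0}, x0=5.0)
                    for i in range(50)])
        _, truth = px.simulate_expression(primate, specs, 1, seed=22)
        bm = fit_genes(primate, truth.species_means, "BM")
        ou = fit_genes(primate, truth.species_means, "OU1")
        cls = classify_selection(bm, ou).set_index("gene")
        ou_called = cls.loc[[f"o{i}" for i in range(50)],
                            "classification"].eq("stabilizing").mean()
        bm_called = cls.loc[[f"b{i}" for i in range(50)],
                            "classification"].eq("stabilizing").mean()
        assert ou_called > 0.5
        assert bm_called < 0.2


class TestDeByRegime:
    def test_planted_shift_is_detected_with_direction(self, primate):
        alpha = 3.0 / primate.depth
        sigma2 = 2 * alpha * 0.25
        painting = RegimePainting.focal_clade(primate, list(px.HOMINOIDS))
        theta_shift = {"background": 5.0, "focal": 7.0}
        specs = ([px.GeneSimSpec(f"s{i}", "OU", sigma2=sigma2, alpha=alpha,
                                 theta=theta_shift, x0=5.0, painting_id="p")
                  for i in range(20)]
                 + [px.GeneSimSpec(f"n{i}", "BM", sigma2=sigma2, x0=5.0)
                    for i in range(40)])
        _, truth = px.simulate_expression(primate, specs, 1, seed=30,
                                          paintings={"p": painting})
        de = de_by_regime(primate, truth.species_means, painting).set_index("gene")
        planted = de.loc[[f"s{i}" for i in range(20)]]
        assert planted["significant"].mean() >= 0.8
        assert (planted.loc[planted["significant"], "direction"] == "up").all()
        sets = de_gene_sets(de.reset_index())
        assert sets["up"] | sets["down"] == sets["all"]

    def test_single_regime_painting_rejected(self, primate, rng):
        expr = pd.DataFrame(rng.normal(5, 1, (3, 18)),
                            index=list("abc"), columns=primate.tip_labels)
        with pytest.raises(ValueError, match="single regime"):
            de_by_regime(primate, expr, RegimePainting.single(primate))


class TestMsdVsDistance:
    def test_hand_example(self, small_tree):
        expr = pd.DataFrame(
            {"A": [0.0, 0.0], "B": [1.0, 3.0], "C": [2.0, 2.0],
             "D": [0.0, 0.0], "E": [0.0, 0.0]}, index=["g1", "g2"])
        out = msd_vs_distance(expr, small_tree, "A").set_index("species")
        assert out.loc["B", "msd"] == pytest.approx(5.0)  # (1+9)/2
        assert out.loc["B", "distance"] == pytest.approx(2.0)
        assert out.loc["A", "msd"] == 0.0

    def test_bm_divergence_tracks_distance(self, primate):
        """Under BM, E[MSD] = sigma2 * distance: the empirical curve over many
        genes is strongly rank-correlated with patristic distance."""
        specs = [px.GeneSimSpec(f"g{i}", "BM", sigma2=0.2, x0=5.0)
                 for i in range(500)]
        _, truth = px.simulate_expression(primate, specs, 1, seed=33)
        out = msd_vs_distance(truth.species_means, primate, "Human")
        sub = out[out["species"] != "Human"]
        rho = sps.spearmanr(sub["distance"], sub["msd"]).statistic
        assert rho >= 0.9

    def test_unknown_reference_errors(self, primate, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 18)),
                            columns=primate.tip_labels)
        with pytest.raises(ValueError, match="absent"):
            msd_vs_distance(expr, primate, "Martian")
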